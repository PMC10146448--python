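"""First-level GLM machinery for ROI time series with PE parametric modulators.

Designs follow the standard event-related convention: each condition is a
boxcar (3 s reinforcement events by default) convolved with a canonical
double-gamma haemodynamic response function; each modulated condition adds a
column whose boxcar amplitudes are the mean-centred trial-wise modulator values
(here the affective-frame prediction errors); slow drifts are absorbed by a
discrete-cosine basis up to a 128 s cutoff; estimation is ordinary least
squares.  Designs are built on a microtime grid of TR/16 and sampled at the
first microtime bin of each TR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scanner timing parameters of one run."""

    tr: float = 1.5
    n_scans: int = 405
    event_duration: float = 3.0
    highpass_cutoff: float = 128.0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_scans <= 0:
            raise ValueError("n_scans must be positive")
        if self.highpass_cutoff <= 2 * self.tr:
            raise ValueError("highpass_cutoff must exceed 2 * tr")

    @property
    def run_duration(self) -> float:
        return self.tr * self.n_scans


@dataclass
class GLMFit:
    """OLS estimates for one ROI series."""

    coefficients: pd.Series
    residual_variance: float
    df: int
    residuals: np.ndarray


def double_gamma_hrf(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, peak-normalised.

    Response gamma peaks near 5 s, the undershoot near 15 s with 1/6 relative
    amplitude; support truncated at ``duration`` (default 32 s).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration, dt)
    peak = scipy.stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = scipy.stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def _sample_convolved(stick: np.ndarray, hrf: np.ndarray, acq: AcquisitionConfig) -> np.ndarray:
    conv = np.convolve(stick, hrf)[: len(stick)]
    # sample at the first microtime bin of each TR
    return conv[:: acq.microtime_bins][: acq.n_scans]


def dct_drift_basis(acq: AcquisitionConfig) -> pd.DataFrame:
    """Discrete-cosine drift regressors with periods >= the high-pass cutoff."""
    n = acq.n_scans
    total = n * acq.tr
    order = int(np.floor(2.0 * total / acq.highpass_cutoff))
    t = np.arange(n)
    cols = {}
    for k in range(1, order + 1):
        cols[f"drift_{k}"] = np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * k / (2 * n))
    return pd.DataFrame(cols, dtype=float)


def build_design(
    events: pd.DataFrame,
    acq: AcquisitionConfig,
    modulator_column: str = "modulator",
) -> pd.DataFrame:
    """HRF-convolved design matrix from a BIDS-style events table.

    ``events`` needs columns ``onset``, ``duration``, ``trial_type`` and
    optionally a modulator column; rows with a non-null modulator produce an
    extra ``<trial_type>_pm`` column whose boxcar heights are the modulator
    values mean-centred *within condition* (no serial orthogonalisation beyond
    that centering).  Drift and constant columns are appended.
    """
    required = {"onset", "duration", "trial_type"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if len(events) and events["onset"].max() >= acq.run_duration:
        raise ValueError("event onset beyond end of run")

    dt = acq.tr / acq.microtime_bins
    n_fine = acq.n_scans * acq.microtime_bins
    hrf = double_gamma_hrf(dt)

    def stick(sub: pd.DataFrame, amplitudes: np.ndarray) -> np.ndarray:
        s = np.zeros(n_fine)
        for (onset, dur), amp in zip(sub[["onset", "duration"]].to_numpy(), amplitudes):
            i0 = int(round(onset / dt))
            i1 = max(i0 + 1, int(round((onset + dur) / dt)))
            s[i0: min(i1, n_fine)] += amp
        return s

    cols: dict[str, np.ndarray] = {}
    for cond in pd.unique(events["trial_type"]):
        sub = events[events["trial_type"] == cond]
        if len(sub) == 0:
            warnings.warn(f"condition {cond!r} has no events; column omitted")
            continue
        cols[str(cond)] = _sample_convolved(stick(sub, np.ones(len(sub))), hrf, acq)
        if modulator_column in sub.columns:
            mod = sub[modulator_column].to_numpy(dtype=float)
            if np.all(np.isnan(mod)):
                continue
            valid = sub[~np.isnan(mod)]
            centred = valid[modulator_column].to_numpy(dtype=float)
            centred = centred - centred.mean()
            cols[f"{cond}_pm"] = _sample_convolved(stick(valid, centred), hrf, acq)

    design = pd.DataFrame(cols, dtype=float)
    design = pd.concat([design, dct_drift_basis(acq)], axis=1)
    design["constant"] = 1.0
    return design


def simulate_roi_bold(
    design: pd.DataFrame,
    true_betas: dict[str, float] | np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    ar1: float = 0.0,
) -> np.ndarray:
    """Synthesize an ROI series as design @ betas + white (or AR(1)) noise.

    ``true_betas`` may be a dict keyed by design columns (missing columns get
    beta 0) or a full coefficient vector.
    """
    if isinstance(true_betas, dict):
        unknown = set(true_betas) - set(design.columns)
        if unknown:
            raise ValueError(f"betas refer to unknown columns: {sorted(unknown)}")
        beta = np.array([true_betas.get(c, 0.0) for c in design.columns])
    else:
        beta = np.asarray(true_betas, dtype=float)
        if beta.shape[0] != design.shape[1]:
            raise ValueError("beta vector length does not match design columns")
    n = len(design)
    eps = rng.normal(0.0, noise_sd, size=n)
    if ar1 != 0.0:
        for i in range(1, n):
            eps[i] += ar1 * eps[i - 1]
        eps *= np.sqrt(1.0 - ar1**2)  # keep marginal variance ~ noise_sd^2
    return design.to_numpy() @ beta + eps


def fit_glm(series: np.ndarray, design: pd.DataFrame) -> GLMFit:
    """Ordinary least squares fit of one ROI series on a design matrix."""
    X = design.to_numpy(dtype=float)
    y = np.asarray(series, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("series length does not match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by pivoted QR
        _, r = np.linalg.qr(X)
        bad = [design.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"suspect columns: {bad}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - rank
    sigma2 = float(resid @ resid / df) if df > 0 else float("nan")
    return GLMFit(
        coefficients=pd.Series(beta, index=design.columns),
        residual_variance=sigma2,
        df=df,
        residuals=resid,
    )
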