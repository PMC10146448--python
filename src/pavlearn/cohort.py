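"""Synthetic cohorts for end-to-end pipeline testing without any real data.

A cohort emulates the study design this package analyses: each subject
completes 4 sessions (2 appetitive, 2 aversive) of the 40-trial probabilistic
reversal task, responding as a Rescorla–Wagner agent with a subject-specific
learning rate and response precision; subjects carry NEO-FFI-style neuroticism
and extraversion scores and a BMI; ROI beta tables embed known condition means
and known trait-activity couplings; and 3-node path-model samples can be drawn
with known standardized coefficients.

Default calibrations (documented, not claims of reproduction):

* 37 subjects, the analysed sample size of the study design being emulated;
* trait couplings -0.36 (neuroticism) and +0.48 (extraversion) on the
  left-CMA negative-aversive-PE beta only;
* positive mean betas (Cohen's d = 0.8 against unit noise) in the three
  CMA cells where the emulated design shows effects;
* path coefficients (0.29, 0.66) for the right-hemisphere appetitive chain.

Reproducibility: the master seed spawns one child stream per subject via
``numpy.random.SeedSequence.spawn``, so any subject subset regenerates
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .models import RWAgent
from .stats import CONDITIONS, ROIS
from .task import SessionRecord, TaskConfig, simulate_session

DEFAULT_EFFECT_CELLS = {
    "L_CMA:negPE_app": 0.8,
    "R_CMA:negPE_app": 0.8,
    "L_CMA:negPE_av": 0.8,
}

DEFAULT_COUPLINGS = {
    ("L_CMA", "negPE_av", "neuroticism"): -0.36,
    ("L_CMA", "negPE_av", "extraversion"): 0.48,
}

DEFAULT_SEM_PATHS = (0.29, 0.66)


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of a synthetic cohort."""

    n_subjects: int = 37
    n_sessions_per_valence: int = 2
    task: TaskConfig = field(default_factory=TaskConfig)
    # subject-level learning parameters
    alpha_beta_shapes: tuple[float, float] = (3.0, 7.0)   # Beta(3,7): mean 0.3
    zeta_lognorm: tuple[float, float] = (np.log(5.0), 0.3)  # median 5
    # trait model (NEO-FFI scale range 0..48; BMI in kg/m^2)
    neuroticism_mean_sd: tuple[float, float] = (20.0, 8.0)
    extraversion_mean_sd: tuple[float, float] = (28.0, 6.0)
    trait_range: tuple[float, float] = (0.0, 48.0)
    bmi_mean_sd: tuple[float, float] = (23.25, 3.13)
    bmi_range: tuple[float, float] = (14.0, 45.0)
    # ROI beta model: cell means in units of the unit-variance beta noise
    effect_cells: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_CELLS))
    couplings: dict = field(default_factory=lambda: dict(DEFAULT_COUPLINGS))
    # fMRI simulation
    glm_pm_beta: float = 0.5
    glm_noise_sd: float = 1.0
    # path model
    sem_paths: tuple[float, float] = DEFAULT_SEM_PATHS
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need n_subjects >= 3")
        for (roi, cond, trait), r in self.couplings.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"coupling {(roi, cond, trait)} = {r} outside (-1, 1)")
        # couplings on one cell must leave positive residual variance
        by_cell: dict[tuple[str, str], float] = {}
        for (roi, cond, trait), r in self.couplings.items():
            by_cell[(roi, cond)] = by_cell.get((roi, cond), 0.0) + r**2
        for cell, ss in by_cell.items():
            if ss >= 1.0:
                raise ValueError(
                    f"couplings on cell {cell} imply non-positive residual variance"
                )


@dataclass
class SyntheticSubject:
    subject_id: str
    alpha: float
    zeta: float
    sessions: list[SessionRecord]  # empty when behaviour generation is off

    @property
    def sessions_by_valence(self) -> dict[str, list[SessionRecord]]:
        out: dict[str, list[SessionRecord]] = {"appetitive": [], "aversive": []}
        for s in self.sessions:
            out[s.config.session_valence].append(s)
        return out


@dataclass
class SyntheticCohort:
    config: CohortConfig
    subjects: list[SyntheticSubject]
    covariates: pd.DataFrame   # index subject_id; neuroticism, extraversion, bmi
    betas: pd.DataFrame        # index subject_id; columns "<roi>:<condition>"


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds far in the tails by design)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    config: CohortConfig, behavior: bool = True
) -> SyntheticCohort:
    """Generate a full synthetic cohort from the stored seed.

    With ``behavior=False`` only covariates and ROI betas are produced (useful
    for large-n calibration checks where simulating sessions would be wasted
    work).
    """
    ss = np.random.SeedSequence(config.master_seed)
    subject_seeds = ss.spawn(config.n_subjects + 1)
    cohort_rng = np.random.default_rng(subject_seeds[-1])

    n = config.n_subjects
    a, b = config.alpha_beta_shapes
    mu_z, sd_z = config.zeta_lognorm

    subjects: list[SyntheticSubject] = []
    for i in range(n):
        rng = np.random.default_rng(subject_seeds[i])
        alpha = float(rng.beta(a, b))
        zeta = float(rng.lognormal(mu_z, sd_z))
        sessions: list[SessionRecord] = []
        if behavior:
            for valence in ("appetitive", "aversive"):
                cfg = TaskConfig(
                    n_trials=config.task.n_trials,
                    p_affective_hp=config.task.p_affective_hp,
                    reversal_criterion=config.task.reversal_criterion,
                    reversal_window=config.task.reversal_window,
                    session_valence=valence,
                    iti_range_s=config.task.iti_range_s,
                )
                for _ in range(config.n_sessions_per_valence):
                    agent = RWAgent(alpha=alpha, zeta=zeta, rng=rng)
                    sessions.append(simulate_session(agent, cfg, rng))
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:03d}", alpha=alpha, zeta=zeta, sessions=sessions
            )
        )

    ids = [s.subject_id for s in subjects]
    nm, nsd = config.neuroticism_mean_sd
    em, esd = config.extraversion_mean_sd
    lo, hi = config.trait_range
    neuro = _truncated_normal(nm, nsd, lo, hi, n, cohort_rng)
    extra = _truncated_normal(em, esd, lo, hi, n, cohort_rng)
    blo, bhi = config.bmi_range
    bm, bsd = config.bmi_mean_sd
    bmi = _truncated_normal(bm, bsd, blo, bhi, n, cohort_rng)
    covariates = pd.DataFrame(
        {"neuroticism": neuro, "extraversion": extra, "bmi": bmi}, index=ids
    )

    betas = _generate_betas(config, covariates, cohort_rng)
    return SyntheticCohort(
        config=config, subjects=subjects, covariates=covariates, betas=betas
    )


def _generate_betas(
    config: CohortConfig, covariates: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """ROI betas = cell mean + sum(coupling * z-trait) + scaled Gaussian noise.

    With independent unit-variance trait scores and residual variance
    1 - sum(r^2), each coupling r is the population correlation between the
    trait and the cell's beta.
    """
    n = len(covariates)
    z = {
        trait: (covariates[trait] - covariates[trait].mean()) / covariates[trait].std(ddof=0)
        for trait in ("neuroticism", "extraversion")
    }
    cols: dict[str, np.ndarray] = {}
    for roi in ROIS:
        for cond in CONDITIONS:
            cell = f"{roi}:{cond}"
            mean = config.effect_cells.get(cell, 0.0)
            signal = np.zeros(n)
            ss = 0.0
            for (c_roi, c_cond, trait), r in config.couplings.items():
                if c_roi == roi and c_cond == cond:
                    signal += r * z[trait].to_numpy()
                    ss += r**2
            noise = np.sqrt(max(1.0 - ss, 0.0)) * rng.standard_normal(n)
            cols[cell] = mean + signal + noise
    return pd.DataFrame(cols, index=covariates.index)
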