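"""Trial-wise latent-value models of reversal learning and their ML fitting.

Three model families are implemented:

* ``rw`` — the Rescorla–Wagner delta rule.  The latent value ``V`` is the
  expectation that the outcome *matches the outcome initially linked with the
  presented cue* (the "concurrence" frame): the match is coded ``R = 1`` and a
  violation ``R = 0``, so a single V serves both cues and survives reversals as
  a drop in V.  Updates: ``delta_t = R_t - V_t``; ``V_{t+1} = V_t + alpha *
  delta_t`` with ``V_1 = v0`` (default 0.5).
* ``td`` — a two-time-step temporal-difference extension: the cue state
  bootstraps, with discount ``gamma``, on the learned value of the post-outcome
  state, and reduces exactly to RW at ``gamma = 0``.
* ``hgf`` — a three-level Hierarchical Gaussian Filter for binary inputs
  (Mathys-style Bayesian learner), with evolution log-volatilities ``omega2``
  and ``omega3`` free and the coupling ``kappa`` fixed at 1.

For reporting and for the response model, values are re-expressed in the
*affective frame*: ``V'`` is the anticipated probability of the non-neutral
(affective) outcome under the presented cue (``V' = V`` when the cue was
initially affective-linked, else ``1 - V``), with ``R' = 1`` on affective
outcomes and ``delta' = R' - V'``.  Responses are modelled as Bernoulli with a
unit-square-sigmoid read-out of ``V'`` governed by a precision ``zeta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .task import (
    AFFECTIVE,
    HP_AFFECTIVE,
    MISSED,
    NEUTRAL,
    SessionRecord,
    Trial,
)

_EPS = 1e-12

MODEL_N_PARAMS = {"rw": 2, "td": 3, "hgf": 3}


class FitDivergenceError(RuntimeError):
    """Raised when a belief update produces an invalid (non-PD) posterior."""


@dataclass(frozen=True)
class RWParams:
    alpha: float
    v0: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.v0 <= 1.0:
            raise ValueError(f"v0 must be in [0, 1], got {self.v0}")


@dataclass(frozen=True)
class TDParams:
    alpha: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class HGFParams:
    """Three-level binary HGF parameters (kappa fixed at 1 for identifiability)."""

    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    mu2_init: float = 0.0
    sigma2_init: float = 1.0
    mu3_init: float = 1.0
    sigma3_init: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_init <= 0 or self.sigma3_init <= 0:
            raise ValueError("initial belief variances must be positive")


@dataclass(frozen=True)
class ObservationParams:
    """Unit-square-sigmoid response precision."""

    zeta: float = 1.0

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")


@dataclass
class Trajectory:
    """Per-trial model quantities for one session under one model.

    All arrays have one entry per trial.  On missed trials ``delta`` (and
    ``delta_prime``) are NaN and the value carries over unchanged.
    """

    model_name: str
    v: np.ndarray
    delta: np.ndarray
    v_prime: np.ndarray
    delta_prime: np.ndarray
    r: np.ndarray
    r_prime: np.ndarray

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class FitResult:
    model_name: str
    params: dict[str, float]
    log_likelihood: float
    n_params: int
    n_trials_used: int
    converged: bool
    message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


def code_outcome(trial: Trial, initial_mapping: dict[str, str]) -> tuple[int, int]:
    """Concurrence coding R and affective coding R' for one trial.

    R = 1 iff the outcome matches the outcome *initially* linked with the
    presented cue; R' = 1 iff the outcome is the affective (non-neutral) one.
    """
    try:
        initial_role = initial_mapping[trial.cue_id]
    except KeyError:
        raise ValueError(f"unknown cue id {trial.cue_id!r}") from None
    outcome_affective = trial.outcome == AFFECTIVE
    initially_affective = initial_role == HP_AFFECTIVE
    r = int(outcome_affective == initially_affective)
    r_prime = int(outcome_affective)
    return r, r_prime


def affective_frame(v: float, cue_initially_affective: bool) -> float:
    """Map the concurrence-frame value to the affective-outcome probability."""
    return v if cue_initially_affective else 1.0 - v


def _session_codes(session: SessionRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(r, r_prime, initially_affective flags, missed flags) as arrays."""
    n = len(session)
    r = np.empty(n, dtype=float)
    rp = np.empty(n, dtype=float)
    flags = np.empty(n, dtype=bool)
    missed = np.empty(n, dtype=bool)
    for i, t in enumerate(session.trials):
        r[i], rp[i] = code_outcome(t, session.initial_mapping)
        flags[i] = session.initial_mapping[t.cue_id] == HP_AFFECTIVE
        missed[i] = t.response == MISSED
    return r, rp, flags, missed


def _to_frame(
    model_name: str,
    v: np.ndarray,
    r: np.ndarray,
    rp: np.ndarray,
    flags: np.ndarray,
    missed: np.ndarray,
) -> Trajectory:
    delta = np.where(missed, np.nan, r - v)
    v_prime = np.where(flags, v, 1.0 - v)
    delta_prime = np.where(missed, np.nan, rp - v_prime)
    return Trajectory(
        model_name=model_name,
        v=v,
        delta=delta,
        v_prime=v_prime,
        delta_prime=delta_prime,
        r=r,
        r_prime=rp,
    )


def rw_trajectory(session: SessionRecord, params: RWParams) -> Trajectory:
    """Rescorla–Wagner value/PE sequences for one session.

    Missed trials are skipped by the update (no outcome is assumed to be
    experienced) and carry NaN prediction errors.
    """
    if len(session) == 0:
        raise ValueError("session is empty")
    r, rp, flags, missed = _session_codes(session)
    n = len(session)
    v = np.empty(n)
    value = params.v0
    for i in range(n):
        v[i] = value
        if not missed[i]:
            value = value + params.alpha * (r[i] - value)
    return _to_frame("rw", v, r, rp, flags, missed)


def td_trajectory(session: SessionRecord, params: TDParams) -> Trajectory:
    """Two-time-step TD(0) value/PE sequences.

    Each trial is a two-state episode: the cue state transitions to a
    post-outcome (terminal-anticipation) state whose value W is itself learned
    by a delta rule from the received reinforcement.  The cue-state error is

        delta_t = R_t + gamma * W_t - V_t

    so at ``gamma = 0`` the model collapses exactly onto Rescorla–Wagner.
    """
    if len(session) == 0:
        raise ValueError("session is empty")
    r, rp, flags, missed = _session_codes(session)
    n = len(session)
    v = np.empty(n)
    value = 0.5
    w = 0.0
    for i in range(n):
        v[i] = value
        if not missed[i]:
            delta = r[i] + params.gamma * w - value
            value = value + params.alpha * delta
            w = w + params.alpha * (r[i] - w)
    # the read-out probability must stay in [0, 1]; gamma > 0 can push V above 1
    v = np.clip(v, 0.0, 1.0)
    # recompute the reported (clipped-frame) deltas from the clipped values
    delta = np.where(missed, np.nan, r - v)
    v_prime = np.where(flags, v, 1.0 - v)
    delta_prime = np.where(missed, np.nan, rp - v_prime)
    return Trajectory("td", v, delta, v_prime, delta_prime, r, rp)


def hgf_trajectory(session: SessionRecord, params: HGFParams) -> Trajectory:
    """Three-level binary HGF belief trajectory.

    The trial-wise value is the *predictive* outcome probability
    ``v_t = sigmoid(mu2)`` before seeing the trial's input, so ``delta_t =
    R_t - v_t`` is the precision-independent first-level prediction error.

    Raises
    ------
    FitDivergenceError
        If a level-3 posterior precision becomes non-positive (the standard
        divergence signal of this filter).
    """
    if len(session) == 0:
        raise ValueError("session is empty")
    r, rp, flags, missed = _session_codes(session)
    n = len(session)
    v = np.empty(n)

    mu2 = params.mu2_init
    sigma2 = params.sigma2_init
    mu3 = params.mu3_init
    sigma3 = params.sigma3_init
    k = params.kappa

    for i in range(n):
        muhat1 = expit(mu2)
        v[i] = muhat1
        if missed[i]:
            continue
        u = r[i]
        # level-2 prediction: random walk with volatility from level 3
        log_nu2 = k * mu3 + params.omega2
        if not math.isfinite(log_nu2) or log_nu2 > 15.0:
            raise FitDivergenceError(
                f"level-2 volatility diverged at trial {i + 1} (log nu2 = {log_nu2:.3g})"
            )
        nu2 = math.exp(log_nu2)
        sigmahat2 = sigma2 + nu2
        # level-1 precision-weighted update of level 2
        da1 = u - muhat1
        pihat1 = muhat1 * (1.0 - muhat1)  # predictive precision of the binary input
        pi2 = 1.0 / sigmahat2 + pihat1
        sigma2_new = 1.0 / pi2
        mu2_new = mu2 + sigma2_new * da1
        # level-3 update (volatility PE on level 2)
        w2 = nu2 / sigmahat2
        da2 = (sigma2_new + (mu2_new - mu2) ** 2) / sigmahat2 - 1.0
        sigmahat3 = sigma3 + math.exp(params.omega3)
        pi3 = 1.0 / sigmahat3 + (k**2 / 2.0) * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
        if pi3 <= 0.0:
            raise FitDivergenceError(
                f"level-3 posterior precision non-positive at trial {i + 1}"
            )
        sigma3 = 1.0 / pi3
        mu3 = mu3 + sigma3 * (k / 2.0) * w2 * da2
        mu2, sigma2 = mu2_new, sigma2_new

    return _to_frame("hgf", v, r, rp, flags, missed)


def response_probability(v_prime: float | np.ndarray, obs: ObservationParams) -> float | np.ndarray:
    """Probability of predicting the affective outcome: unit-square sigmoid.

    ``p = v'^zeta / (v'^zeta + (1 - v')^zeta)``; zeta = 1 is probability
    matching, zeta -> inf approaches a hard argmax, zeta = 0 is indifference.
    """
    vp = np.clip(np.asarray(v_prime, dtype=float), _EPS, 1.0 - _EPS)
    # v^z / (v^z + (1-v)^z) == expit(z * logit(v)), which is overflow-safe
    p = expit(obs.zeta * (np.log(vp) - np.log1p(-vp)))
    if np.isscalar(v_prime):
        return float(p)
    return p


def response_loglik(
    traj: Trajectory, responses: Sequence[str], obs: ObservationParams
) -> float:
    """Bernoulli log likelihood (nats) of the responses under the trajectory.

    Missed trials contribute zero.
    """
    if len(responses) != len(traj):
        raise ValueError(
            f"responses length {len(responses)} != trajectory length {len(traj)}"
        )
    p_aff = np.asarray(response_probability(traj.v_prime, obs))
    ll = 0.0
    for i, resp in enumerate(responses):
        if resp == MISSED:
            continue
        p = p_aff[i] if resp == AFFECTIVE else 1.0 - p_aff[i]
        ll += math.log(max(p, _EPS))
    return ll


def sample_responses(
    traj: Trajectory, obs: ObservationParams, rng: np.random.Generator
) -> list[str]:
    """Draw responses from the model's own response distribution."""
    p_aff = np.asarray(response_probability(traj.v_prime, obs))
    return [AFFECTIVE if rng.random() < p else NEUTRAL for p in p_aff]


# ---------------------------------------------------------------------------
# RW agent: simulates responses online during a session (for synthetic cohorts)
# ---------------------------------------------------------------------------


class RWAgent:
    """Online Rescorla–Wagner responder with unit-square-sigmoid choice noise.

    Maintains a single concurrence-frame value anchored to the *first cue it
    encounters* (it cannot know the session's design labels); this is
    observationally equivalent to the analysis frame because the two frames
    differ only by the V -> 1 - V reflection.
    """

    def __init__(
        self, alpha: float, zeta: float, rng: np.random.Generator, v0: float = 0.5
    ) -> None:
        self.params = RWParams(alpha=alpha, v0=v0)
        self.obs = ObservationParams(zeta=zeta)
        self.rng = rng
        self._value = v0
        self._anchor: str | None = None  # cue treated as "affective-linked"

    def __call__(self, cue: str, history: Sequence[Trial]) -> str:
        # learn from the outcome of the previous trial before responding
        if history:
            last = history[-1]
            if last.response != MISSED:
                r = self._concurrence(last.cue_id, last.outcome)
                self._value += self.params.alpha * (r - self._value)
        if self._anchor is None:
            self._anchor = cue
        v_prime = self._value if cue == self._anchor else 1.0 - self._value
        p = response_probability(v_prime, self.obs)
        return AFFECTIVE if self.rng.random() < p else NEUTRAL

    def _concurrence(self, cue: str, outcome: str) -> int:
        if self._anchor is None:
            self._anchor = cue
        affective = outcome == AFFECTIVE
        return int(affective == (cue == self._anchor))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _make_objective(session: SessionRecord, responses: Sequence[str], model_name: str):
    """Return (negative-log-likelihood over unconstrained params, unpack fn)."""

    if model_name == "rw":

        def unpack(x: np.ndarray) -> tuple[dict[str, float], Trajectory]:
            alpha = float(expit(x[0]))
            zeta = float(math.exp(min(x[1], 20.0)))
            traj = rw_trajectory(session, RWParams(alpha=alpha))
            return {"alpha": alpha, "zeta": zeta}, traj

    elif model_name == "td":

        def unpack(x: np.ndarray) -> tuple[dict[str, float], Trajectory]:
            alpha = float(expit(x[0]))
            gamma = float(expit(x[1]))
            zeta = float(math.exp(min(x[2], 20.0)))
            traj = td_trajectory(session, TDParams(alpha=alpha, gamma=gamma))
            return {"alpha": alpha, "gamma": gamma, "zeta": zeta}, traj

    elif model_name == "hgf":

        def unpack(x: np.ndarray) -> tuple[dict[str, float], Trajectory]:
            omega2 = float(np.clip(x[0], -12.0, 2.0))
            omega3 = float(np.clip(x[1], -12.0, 2.0))
            zeta = float(math.exp(min(x[2], 20.0)))
            traj = hgf_trajectory(session, HGFParams(omega2=omega2, omega3=omega3))
            return {"omega2": omega2, "omega3": omega3, "zeta": zeta}, traj

    else:
        raise ValueError(f"unknown model {model_name!r}")

    def nll(x: np.ndarray) -> float:
        try:
            params, traj = unpack(x)
        except FitDivergenceError:
            return 1e6
        zeta = params["zeta"]
        return -response_loglik(traj, responses, ObservationParams(zeta=zeta))

    return nll, unpack


def fit_model(
    session: SessionRecord,
    responses: Sequence[str] | None = None,
    model_name: str = "rw",
    n_starts: int = 10,
    seed: int = 0,
    min_trials: int = 10,
) -> FitResult:
    """Fit one model to one session's responses by multi-start ML.

    Parameters are optimised on unconstrained scales (logit for rates, log for
    the response precision) with Nelder–Mead restarts from ``n_starts`` seeded
    draws; the best converged solution is returned.

    ``responses`` defaults to the responses stored in the session record.
    """
    if responses is None:
        responses = session.responses
    n_used = sum(r != MISSED for r in responses)
    if n_used < min_trials:
        raise ValueError(
            f"need >= {min_trials} non-missed trials to fit, got {n_used}"
        )
    nll, unpack = _make_objective(session, responses, model_name)
    rng = np.random.default_rng(seed)
    k = MODEL_N_PARAMS[model_name]

    best_x = None
    best_fun = np.inf
    any_converged = False
    for s in range(n_starts):
        if model_name == "rw":
            x0 = np.array([_logit(rng.uniform(0.05, 0.95)), math.log(rng.uniform(0.3, 8.0))])
        elif model_name == "td":
            x0 = np.array(
                [
                    _logit(rng.uniform(0.05, 0.95)),
                    _logit(rng.uniform(0.05, 0.95)),
                    math.log(rng.uniform(0.3, 8.0)),
                ]
            )
        else:
            x0 = np.array(
                [rng.uniform(-8.0, 0.0), rng.uniform(-8.0, 0.0), math.log(rng.uniform(0.3, 8.0))]
            )
        res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
        if res.fun < best_fun:
            best_fun = res.fun
            best_x = res.x
            any_converged = any_converged or bool(res.success)
        elif res.success:
            any_converged = True

    if best_x is None or not np.isfinite(best_fun):
        return FitResult(
            model_name=model_name,
            params={},
            log_likelihood=-np.inf,
            n_params=k,
            n_trials_used=n_used,
            converged=False,
            message="all starts failed",
        )
    params, _ = unpack(best_x)
    return FitResult(
        model_name=model_name,
        params=params,
        log_likelihood=-best_fun,
        n_params=k,
        n_trials_used=n_used,
        converged=any_converged,
        message="ok" if any_converged else "no start reported convergence",
    )
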