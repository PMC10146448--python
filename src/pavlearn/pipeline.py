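"""Stage-to-stage glue: trajectories to event tables, cohort-level fitting,
AIC tables, and the consolidated synthetic-cohort analysis report.

These functions are the library behind the command-line entry points; each one
consumes and returns the containers of the stage modules (``task``, ``models``,
``selection``, ``glm``, ``stats``, ``sem``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import selection, sem, stats
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .models import FitResult, ObservationParams, RWParams, Trajectory, fit_model, rw_trajectory
from .task import HP_AFFECTIVE, SessionRecord


def events_from_session(
    session: SessionRecord, traj: Trajectory | None = None
) -> pd.DataFrame:
    """BIDS-style events table of the reinforcement phase, with PE modulators.

    One row per trial; ``trial_type`` distinguishes reinforcing events preceded
    by the currently high-probability-affective cue from those preceded by the
    high-probability-neutral cue; ``modulator`` carries the affective-frame
    prediction error delta' when a trajectory is supplied.
    """
    rows = []
    for i, t in enumerate(session.trials):
        cond = (
            "reinf_HP_affective" if t.cue_role == HP_AFFECTIVE else "reinf_HP_neutral"
        )
        row = {
            "onset": t.onset_s,
            "duration": t.duration_s,
            "trial_type": cond,
            "modulator": np.nan if traj is None else float(traj.delta_prime[i]),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def fit_subject_sessions(
    sessions: list[SessionRecord],
    models: tuple[str, ...] = ("rw", "td", "hgf"),
    seed: int = 0,
    n_starts: int = 5,
) -> dict[str, list[FitResult]]:
    """Fit each candidate model to each session; returns model -> fits."""
    out: dict[str, list[FitResult]] = {}
    for m in models:
        out[m] = [
            fit_model(s, model_name=m, seed=seed + j, n_starts=n_starts)
            for j, s in enumerate(sessions)
        ]
    return out


def aic_table(
    cohort: SyntheticCohort,
    valence: str,
    models: tuple[str, ...] = ("rw", "td", "hgf"),
    seed: int = 0,
    n_starts: int = 5,
) -> pd.DataFrame:
    """Subjects x models table of AICs summed over the sessions of one valence."""
    rows = {}
    for k, subj in enumerate(cohort.subjects):
        sessions = subj.sessions_by_valence[valence]
        fits = fit_subject_sessions(
            sessions, models=models, seed=seed + 1000 * k, n_starts=n_starts
        )
        rows[subj.subject_id] = {m: sum(f.aic for f in fits[m]) for m in models}
    return pd.DataFrame.from_dict(rows, orient="index")[list(models)]


def recovered_alphas(
    cohort: SyntheticCohort, seed: int = 0, n_starts: int = 5
) -> pd.DataFrame:
    """Fit the RW model per subject and return generating vs recovered alpha.

    The recovered alpha is the mean of the per-session ML estimates over all
    four sessions of a subject.
    """
    rows = []
    for k, subj in enumerate(cohort.subjects):
        fits = [
            fit_model(s, model_name="rw", seed=seed + 1000 * k + j, n_starts=n_starts)
            for j, s in enumerate(subj.sessions)
        ]
        rows.append(
            {
                "subject_id": subj.subject_id,
                "alpha_true": subj.alpha,
                "alpha_hat": float(np.mean([f.params["alpha"] for f in fits])),
                "zeta_true": subj.zeta,
                "zeta_hat": float(np.median([f.params["zeta"] for f in fits])),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def simulate_subject_bold(
    session: SessionRecord,
    alpha: float,
    pm_beta: float,
    noise_sd: float,
    rng: np.random.Generator,
    acq: glm_mod.AcquisitionConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """ROI BOLD for one session with a known PE-modulation amplitude.

    The generating PE series is the RW trajectory at the subject's true
    learning rate.  Returns (series, design).
    """
    if acq is None:
        acq = glm_mod.AcquisitionConfig()
    traj = rw_trajectory(session, RWParams(alpha=alpha))
    events = events_from_session(session, traj)
    design = glm_mod.build_design(events, acq)
    betas = {c: 0.0 for c in design.columns}
    for c in design.columns:
        if c.endswith("_pm"):
            betas[c] = pm_beta
        elif c.startswith("reinf"):
            betas[c] = 1.0
    series = glm_mod.simulate_roi_bold(design, betas, noise_sd, rng)
    return series, design


@dataclass
class PipelineReport:
    """Consolidated results of the end-to-end synthetic-cohort analysis."""

    model_comparison: dict[str, pd.DataFrame]
    alpha_recovery: pd.DataFrame
    accuracy: pd.DataFrame
    roi_tests: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    correlations: pd.DataFrame
    sem_fit: pd.DataFrame


def run_pipeline(
    config: CohortConfig | None = None,
    seed: int = 0,
    models: tuple[str, ...] = ("rw", "td", "hgf"),
    sem_n: int = 5000,
    fit_starts: int = 5,
) -> PipelineReport:
    """Generate a cohort and run every analysis stage on it.

    This is the `run-pipeline` CLI body; stages mirror the analysis of a real
    cohort: model fitting and comparison, behavioural accuracy, ROI t tests,
    the 2x2 repeated-measures ANOVA, trait correlations and the path analysis.
    """
    if config is None:
        config = CohortConfig(master_seed=seed)
    cohort = generate_cohort(config)

    comparison = {}
    for valence in ("appetitive", "aversive"):
        table = aic_table(cohort, valence, models=models, seed=seed, n_starts=fit_starts)
        comparison[valence] = selection.compare_models(table, reference="rw")

    recovery = recovered_alphas(cohort, seed=seed, n_starts=fit_starts)

    sessions_by_cond = {
        "appetitive": [s.sessions_by_valence["appetitive"] for s in cohort.subjects],
        "aversive": [s.sessions_by_valence["aversive"] for s in cohort.subjects],
    }
    accuracy = stats.accuracy_vs_chance(sessions_by_cond)

    roi_tests = stats.roi_ttests(cohort.betas)

    anova = {}
    for roi in ("L_CMA", "R_CMA"):
        cells = cohort.betas[
            [f"{roi}:negPE_app", f"{roi}:negPE_av", f"{roi}:posPE_app", f"{roi}:posPE_av"]
        ]
        anova[roi] = stats.rm_anova_2x2(cells)

    correlations = stats.trait_correlation_report(
        cohort.betas, cohort.covariates, beta_columns=["L_CMA:negPE_av", "L_CMA:negPE_app"]
    )

    rng = np.random.default_rng(seed + 77)
    theta = sem.standardized_chain_theta(*config.sem_paths)
    data = sem.generate_sem_samples(theta, sem_n, rng)
    fit = sem.fit_sem(data)
    sem_fit = fit.to_frame()
    sem_fit.loc[len(sem_fit)] = {
        "path": "fit", "estimate": fit.chi2, "se": float(fit.df), "p": fit.p
    }

    return PipelineReport(
        model_comparison=comparison,
        alpha_recovery=recovery,
        accuracy=accuracy,
        roi_tests=roi_tests,
        anova=anova,
        correlations=correlations,
        sem_fit=sem_fit,
    )
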