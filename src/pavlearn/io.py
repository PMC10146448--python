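"""Readers/writers for the TSV dialects used across the pipeline, plus run
manifests.

All numeric output is TSV with fixed column orders and floats at 10
significant digits, so reruns with the same seed diff byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import Trajectory
from .task import HP_AFFECTIVE, HP_NEUTRAL, SessionRecord, TaskConfig, Trial

SESSION_COLUMNS = [
    "index", "onset_s", "duration_s", "cue_id", "cue_role",
    "response", "outcome", "correct", "reversal",
]

TRAJECTORY_COLUMNS = ["trial", "r", "r_prime", "v", "v_prime", "delta", "delta_prime"]


class SchemaError(ValueError):
    """A table is missing required columns."""


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tsv(path: str | Path, required: list[str] | None = None, **kw) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", **kw)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def session_to_frame(session: SessionRecord) -> pd.DataFrame:
    rows = [
        {
            "index": t.index,
            "onset_s": t.onset_s,
            "duration_s": t.duration_s,
            "cue_id": t.cue_id,
            "cue_role": t.cue_role,
            "response": t.response,
            "outcome": t.outcome,
            "correct": int(t.correct),
            "reversal": int(t.reversal_applied_here),
        }
        for t in session.trials
    ]
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session(session: SessionRecord, path: str | Path) -> None:
    write_tsv(session_to_frame(session), path)


def read_session(path: str | Path, config: TaskConfig | None = None) -> SessionRecord:
    """Rebuild a SessionRecord from a per-trial TSV.

    The initial cue-role mapping is reconstructed by unwinding recorded
    reversals back to the first trial.  Unknown extra columns are ignored
    (kept only in the raw frame, retrievable with :func:`read_tsv`).
    """
    df = read_tsv(path, required=SESSION_COLUMNS)
    trials = [
        Trial(
            index=int(r["index"]),
            onset_s=float(r["onset_s"]),
            duration_s=float(r["duration_s"]),
            cue_id=str(r["cue_id"]),
            cue_role=str(r["cue_role"]),
            response=str(r["response"]),
            outcome=str(r["outcome"]),
            correct=bool(int(r["correct"])),
            reversal_applied_here=bool(int(r["reversal"])),
        )
        for _, r in df.iterrows()
    ]
    reversal_indices = [t.index for t in trials if t.reversal_applied_here]
    # roles at trial 1 equal the initial mapping (no reversal can precede trial 1)
    initial_mapping: dict[str, str] = {}
    n_flips = 0
    for t in trials:
        if t.reversal_applied_here:
            n_flips += 1
        if t.cue_id not in initial_mapping:
            role = t.cue_role
            if n_flips % 2 == 1:
                role = HP_AFFECTIVE if role == HP_NEUTRAL else HP_NEUTRAL
            initial_mapping[t.cue_id] = role
    if config is None:
        config = TaskConfig(n_trials=len(trials) if len(trials) % 2 == 0 else len(trials) + 1)
    return SessionRecord(
        config=config,
        trials=trials,
        reversal_indices=reversal_indices,
        initial_mapping=initial_mapping,
    )


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": np.arange(1, len(traj) + 1),
            "r": traj.r,
            "r_prime": traj.r_prime,
            "v": traj.v,
            "v_prime": traj.v_prime,
            "delta": traj.delta,
            "delta_prime": traj.delta_prime,
        },
        columns=TRAJECTORY_COLUMNS,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    write_tsv(trajectory_to_frame(traj), path)


def read_events(path: str | Path) -> pd.DataFrame:
    """BIDS-style events TSV; requires onset/duration/trial_type, keeps extras."""
    return read_tsv(path, required=["onset", "duration", "trial_type"])


def write_manifest(
    path: str | Path,
    command: str,
    seed: int | None,
    inputs: list[str] | None = None,
    outputs: list[str] | None = None,
    config: dict | None = None,
) -> None:
    """Record command, seed, config hash and paths for one CLI invocation."""
    cfg_text = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "master_seed": seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "inputs": inputs or [],
        "outputs": outputs or [],
        "package_version": _package_version(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("pavlearn")
    except Exception:
        return "unknown"


def load_config(path: str | Path) -> dict:
    """YAML (or JSON — a YAML subset) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
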