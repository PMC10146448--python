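"""Probabilistic serial-reversal Pavlovian task: schedule generation and agent simulation.

The task presents one of two cues on each trial; the subject predicts whether the
cue will be followed by an affective (appetitive/aversive) or a neutral outcome.
One cue carries a high probability (default 75%) of the affective outcome, the
other the complementary contingency.  The cue-outcome mapping reverses every time
the subject responds correctly on a criterion number of consecutive trials
(default 5); the reversal is applied on one of the next ``reversal_window``
trials (default 3), drawn uniformly, so its onset is not fully predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

CUE_IDS = ("A", "B")
HP_AFFECTIVE = "HP_AFFECTIVE"
HP_NEUTRAL = "HP_NEUTRAL"

AFFECTIVE = "affective"
NEUTRAL = "neutral"
MISSED = "missed"

VALID_RESPONSES = (AFFECTIVE, NEUTRAL, MISSED)


class ConfigurationError(ValueError):
    """Raised for task configurations that violate the design invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one session.

    Parameters
    ----------
    n_trials:
        Trials per session (must be even so the two cues can appear equally often).
    p_affective_hp:
        Probability of the affective outcome given the currently
        high-probability-affective cue.  The other cue uses ``1 - p``.
    reversal_criterion:
        Number of consecutive correct responses that triggers a reversal.
    reversal_window:
        The reversal is applied 1..reversal_window trials after the criterion.
    session_valence:
        ``"appetitive"`` or ``"aversive"``; labels only, the schedule is identical.
    iti_range_s:
        Uniform inter-trial-interval range in seconds (fixation between trials).
    reinforcement_delay_s:
        Seconds from trial start (cue pair onset) to the reinforcing event.
    event_duration_s:
        Duration of the reinforcing event (video + liquid), in seconds.
    """

    n_trials: int = 40
    p_affective_hp: float = 0.75
    reversal_criterion: int = 5
    reversal_window: int = 3
    session_valence: str = "appetitive"
    iti_range_s: tuple[float, float] = (5.0, 7.0)
    reinforcement_delay_s: float = 4.0
    event_duration_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_trials % 2 != 0:
            raise ConfigurationError(
                f"n_trials must be a positive even number, got {self.n_trials}"
            )
        if not (0.5 < self.p_affective_hp <= 1.0):
            raise ConfigurationError(
                f"p_affective_hp must lie in (0.5, 1], got {self.p_affective_hp}"
            )
        if self.reversal_criterion < 1:
            raise ConfigurationError("reversal_criterion must be >= 1")
        if self.reversal_window < 1:
            raise ConfigurationError("reversal_window must be >= 1")
        if self.session_valence not in ("appetitive", "aversive"):
            raise ConfigurationError(
                f"session_valence must be 'appetitive' or 'aversive', got "
                f"{self.session_valence!r}"
            )


@dataclass
class Trial:
    """One trial of a session.

    ``cue_role`` is the role of the remaining cue *at this trial* (after any
    reversal applied here).  ``correct`` is True when the response matches the
    current role; it is stored False for missed trials.
    """

    index: int  # 1-based
    onset_s: float
    duration_s: float
    cue_id: str
    cue_role: str
    response: str
    outcome: str
    correct: bool
    reversal_applied_here: bool


@dataclass
class SessionRecord:
    """A complete simulated (or observed) session."""

    config: TaskConfig
    trials: list[Trial]
    reversal_indices: list[int]
    initial_mapping: dict[str, str]

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def responses(self) -> list[str]:
        return [t.response for t in self.trials]

    @property
    def n_correct(self) -> int:
        return sum(t.correct for t in self.trials)

    def accuracy(self) -> float:
        """Ratio of correct responses over non-missed trials."""
        n_valid = sum(t.response != MISSED for t in self.trials)
        if n_valid == 0:
            return float("nan")
        return self.n_correct / n_valid


def generate_cue_sequence(config: TaskConfig, rng: np.random.Generator) -> list[str]:
    """Balanced random order of cue identities: n_trials/2 of each cue."""
    half = config.n_trials // 2
    seq = np.array([CUE_IDS[0]] * half + [CUE_IDS[1]] * half)
    rng.shuffle(seq)
    return seq.tolist()


def draw_outcome(cue_role: str, config: TaskConfig, rng: np.random.Generator) -> str:
    """Bernoulli outcome draw under the current contingency."""
    if cue_role == HP_AFFECTIVE:
        p = config.p_affective_hp
    elif cue_role == HP_NEUTRAL:
        p = 1.0 - config.p_affective_hp
    else:
        raise ValueError(f"unknown cue role {cue_role!r}")
    return AFFECTIVE if rng.random() < p else NEUTRAL


@dataclass
class ReversalState:
    """Consecutive-correct counter plus an optional pending reversal delay.

    The criterion is edge-triggered: runs of correct responses that occur while
    a reversal is already pending do not schedule a second one.
    """

    streak: int = 0
    pending: int | None = None  # trials until the reversal is applied


def update_reversal_state(
    state: ReversalState, correct: bool | None, config: TaskConfig,
    rng: np.random.Generator,
) -> ReversalState:
    """Advance the reversal machinery after a trial's response.

    ``correct=None`` marks a missed trial: it neither advances nor resets the
    consecutive-correct counter.
    """
    streak = state.streak
    if correct is None:
        pass
    elif correct:
        streak += 1
    else:
        streak = 0
    pending = state.pending
    if streak >= config.reversal_criterion and pending is None:
        pending = int(rng.integers(1, config.reversal_window + 1))
        streak = 0
    return ReversalState(streak=streak, pending=pending)


def _flip(mapping: dict[str, str]) -> dict[str, str]:
    swap = {HP_AFFECTIVE: HP_NEUTRAL, HP_NEUTRAL: HP_AFFECTIVE}
    return {cue: swap[role] for cue, role in mapping.items()}


# An agent maps (cue_id, trial history) -> response label; history is the list
# of completed Trial records, in order.
Agent = Callable[[str, Sequence[Trial]], str]


def simulate_session(
    agent: Agent,
    config: TaskConfig,
    rng: np.random.Generator,
    initial_affective_cue: str | None = None,
) -> SessionRecord:
    """Run one session of agent-task interaction.

    All randomness (cue order, the initial mapping if not given, outcome draws,
    reversal delays, agent noise via the same stream) comes from ``rng``, so a
    seeded generator reproduces the session bit-exactly.
    """
    if initial_affective_cue is None:
        initial_affective_cue = CUE_IDS[int(rng.integers(2))]
    other = CUE_IDS[1] if initial_affective_cue == CUE_IDS[0] else CUE_IDS[0]
    initial_mapping = {initial_affective_cue: HP_AFFECTIVE, other: HP_NEUTRAL}
    mapping = dict(initial_mapping)

    cue_seq = generate_cue_sequence(config, rng)
    state = ReversalState()
    trials: list[Trial] = []
    reversal_indices: list[int] = []
    t_clock = 0.0
    lo, hi = config.iti_range_s

    for i, cue in enumerate(cue_seq, start=1):
        reversal_here = False
        if state.pending is not None:
            state.pending -= 1
            if state.pending == 0:
                mapping = _flip(mapping)
                reversal_here = True
                reversal_indices.append(i)
                state = ReversalState()

        role = mapping[cue]
        response = agent(cue, trials)
        if response not in VALID_RESPONSES:
            raise ValueError(f"agent returned invalid response {response!r}")

        # outcomes are drawn under the mapping in force at this trial (a pending
        # reversal uses the old mapping until it is applied)
        outcome = draw_outcome(role, config, rng)
        if response == MISSED:
            correct: bool | None = None
        else:
            correct = (response == AFFECTIVE) == (role == HP_AFFECTIVE)
        state = ReversalState(state.streak, state.pending)
        state = update_reversal_state(state, correct, config, rng)

        onset = t_clock + config.reinforcement_delay_s
        trials.append(
            Trial(
                index=i,
                onset_s=onset,
                duration_s=config.event_duration_s,
                cue_id=cue,
                cue_role=role,
                response=response,
                outcome=outcome,
                correct=bool(correct) if correct is not None else False,
                reversal_applied_here=reversal_here,
            )
        )
        iti = lo + (hi - lo) * rng.random()
        t_clock = onset + config.event_duration_s + iti

    return SessionRecord(
        config=config,
        trials=trials,
        reversal_indices=reversal_indices,
        initial_mapping=initial_mapping,
    )


def make_oracle_agent() -> Agent:
    """Agent that always responds correctly given the current cue-outcome mapping.

    It tracks the mapping exactly: the first trial of each cue reveals its role
    (recorded on the Trial), and every recorded reversal flips the tracked roles.
    Because ``reversal_applied_here`` is set on the trial where the flip takes
    effect, replaying the history yields the mapping in force *before* the
    upcoming trial; a reversal applied on the upcoming trial itself cannot be
    anticipated, so the oracle is wrong exactly on reversal trials — which is
    the intended "always responds correctly under the pre-reversal mapping"
    behaviour that drives criterion-triggered reversals at the maximal rate.
    """

    def agent(cue: str, history: Sequence[Trial]) -> str:
        role: str | None = None
        last_seen = -1
        for j, t in enumerate(history):
            if t.cue_id == cue:
                role = t.cue_role
                last_seen = j
        if role is None:
            # unseen cue: infer from the other cue's role if available
            for j, t in enumerate(history):
                role = HP_AFFECTIVE if t.cue_role == HP_NEUTRAL else HP_NEUTRAL
                last_seen = j
                break
            if role is None:
                return AFFECTIVE
            # reversals after the inference point flip the inferred role
            for t in history[last_seen + 1:]:
                if t.reversal_applied_here:
                    role = HP_AFFECTIVE if role == HP_NEUTRAL else HP_NEUTRAL
            return AFFECTIVE if role == HP_AFFECTIVE else NEUTRAL
        for t in history[last_seen + 1:]:
            if t.reversal_applied_here:
                role = HP_AFFECTIVE if role == HP_NEUTRAL else HP_NEUTRAL
        return AFFECTIVE if role == HP_AFFECTIVE else NEUTRAL

    return agent


def constant_agent(response: str) -> Agent:
    """Agent that always gives the same response."""

    def agent(cue: str, history: Sequence[Trial]) -> str:
        return response

    return agent
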