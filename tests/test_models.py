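"""Latent-value model checks: coding, trajectories, response model, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavlearn.models import (
    FitResult,
    HGFParams,
    ObservationParams,
    RWAgent,
    RWParams,
    TDParams,
    affective_frame,
    code_outcome,
    fit_model,
    hgf_trajectory,
    response_loglik,
    response_probability,
    rw_trajectory,
    sample_responses,
    td_trajectory,
)
from pavlearn.task import (
    AFFECTIVE,
    HP_AFFECTIVE,
    HP_NEUTRAL,
    MISSED,
    NEUTRAL,
    SessionRecord,
    TaskConfig,
    Trial,
    make_oracle_agent,
    simulate_session,
)


def make_session(outcomes, cues=None, responses=None, initial_affective="A"):
    """Hand-built session: outcomes is a list of 'affective'/'neutral'."""
    n = len(outcomes)
    cues = cues or ["A"] * n
    responses = responses or [AFFECTIVE] * n
    other = "B" if initial_affective == "A" else "A"
    mapping = {initial_affective: HP_AFFECTIVE, other: HP_NEUTRAL}
    trials = [
        Trial(
            index=i + 1,
            onset_s=10.0 * i,
            duration_s=3.0,
            cue_id=cues[i],
            cue_role=mapping[cues[i]],  # no reversals in hand-built sessions
            response=responses[i],
            outcome=outcomes[i],
            correct=True,
            reversal_applied_here=False,
        )
        for i in range(n)
    ]
    cfg = TaskConfig(n_trials=n if n % 2 == 0 else n + 1)
    return SessionRecord(cfg, trials, [], mapping)


class TestOutcomeCoding:
    def test_affective_cue_affective_outcome(self):
        s = make_session([AFFECTIVE], cues=["A"])
        assert code_outcome(s.trials[0], s.initial_mapping) == (1, 1)

    def test_neutral_cue_affective_outcome(self):
        s = make_session([AFFECTIVE], cues=["B"])
        assert code_outcome(s.trials[0], s.initial_mapping) == (0, 1)

    def test_neutral_cue_neutral_outcome(self):
        s = make_session([NEUTRAL], cues=["B"])
        assert code_outcome(s.trials[0], s.initial_mapping) == (1, 0)

    def test_unknown_cue(self):
        s = make_session([AFFECTIVE])
        with pytest.raises(ValueError, match="unknown cue"):
            code_outcome(s.trials[0], {"X": HP_AFFECTIVE})


class TestRWTrajectory:
    def test_first_update_arithmetic(self):
        """V starts at 0.5; R=1 with alpha=0.2 gives delta 0.5 and next V 0.6."""
        s = make_session([AFFECTIVE, AFFECTIVE])
        traj = rw_trajectory(s, RWParams(alpha=0.2))
        assert traj.v[0] == 0.5
        assert traj.delta[0] == 0.5
        assert traj.v[1] == pytest.approx(0.6)

    def test_zero_alpha_constant_value(self):
        s = make_session([AFFECTIVE, NEUTRAL, AFFECTIVE, NEUTRAL])
        traj = rw_trajectory(s, RWParams(alpha=0.0))
        assert np.all(traj.v == 0.5)
        assert set(np.round(traj.delta, 10)) <= {-0.5, 0.5}

    def test_zero_error_fixed_point(self):
        s = make_session([AFFECTIVE, AFFECTIVE])
        traj = rw_trajectory(s, RWParams(alpha=0.5, v0=1.0))
        assert traj.delta[0] == 0.0
        assert traj.v[1] == 1.0

    def test_missed_trials_skip_update(self):
        s = make_session(
            [AFFECTIVE, AFFECTIVE, AFFECTIVE],
            responses=[AFFECTIVE, MISSED, AFFECTIVE],
        )
        traj = rw_trajectory(s, RWParams(alpha=0.4))
        assert traj.v[1] == traj.v[2]  # no update on the missed trial
        assert np.isnan(traj.delta[1])

    @settings(max_examples=50, deadline=None)
    @given(
        alpha=st.floats(0.0, 1.0),
        v0=st.floats(0.0, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_boundedness_and_frame_identity(self, alpha, v0, seed):
        rng = np.random.default_rng(seed)
        s = simulate_session(make_oracle_agent(), TaskConfig(), rng)
        traj = rw_trajectory(s, RWParams(alpha=alpha, v0=v0))
        assert np.all((traj.v >= 0) & (traj.v <= 1))
        assert np.all(np.abs(np.abs(traj.delta_prime) - np.abs(traj.delta)) < 1e-12)
        # sign: delta' = delta on initially-affective-cue trials, -delta otherwise
        for i, t in enumerate(s.trials):
            sign = 1.0 if s.initial_mapping[t.cue_id] == HP_AFFECTIVE else -1.0
            assert traj.delta_prime[i] == pytest.approx(sign * traj.delta[i])


class TestAffectiveFrame:
    @pytest.mark.parametrize(
        "v,flag,expected", [(0.7, True, 0.7), (0.7, False, 0.3), (0.5, True, 0.5), (0.5, False, 0.5)]
    )
    def test_examples(self, v, flag, expected):
        assert affective_frame(v, flag) == pytest.approx(expected)


class TestTDTrajectory:
    def test_gamma_zero_reduces_to_rw(self):
        rng = np.random.default_rng(21)
        s = simulate_session(make_oracle_agent(), TaskConfig(), rng)
        td = td_trajectory(s, TDParams(alpha=0.37, gamma=0.0))
        rw = rw_trajectory(s, RWParams(alpha=0.37))
        np.testing.assert_allclose(td.v, rw.v, atol=1e-14)
        np.testing.assert_allclose(td.delta, rw.delta, atol=1e-14)

    def test_hand_recursion_five_trials(self):
        """Generic (alpha, gamma) against an explicit step-by-step recursion."""
        outcomes = [AFFECTIVE, NEUTRAL, AFFECTIVE, AFFECTIVE, NEUTRAL]
        cues = ["A", "B", "A", "B", "A"]
        s = make_session(outcomes, cues=cues)
        alpha, gamma = 0.3, 0.6
        traj = td_trajectory(s, TDParams(alpha=alpha, gamma=gamma))
        # independent recursion
        r = [code_outcome(t, s.initial_mapping)[0] for t in s.trials]
        v, w = 0.5, 0.0
        expected_v = []
        for ri in r:
            expected_v.append(v)
            delta = ri + gamma * w - v
            v = v + alpha * delta
            w = w + alpha * (ri - w)
        np.testing.assert_allclose(traj.v, np.clip(expected_v, 0, 1), atol=1e-12)

    def test_zero_alpha_constant(self):
        s = make_session([AFFECTIVE, NEUTRAL, AFFECTIVE, NEUTRAL])
        traj = td_trajectory(s, TDParams(alpha=0.0, gamma=0.9))
        assert np.all(traj.v == 0.5)


class TestHGFTrajectory:
    def test_rigid_beliefs_near_constant(self):
        s = make_session([AFFECTIVE, NEUTRAL] * 10)
        traj = hgf_trajectory(s, HGFParams(omega2=-12.0, omega3=-12.0, sigma2_init=1e-4))
        assert np.ptp(traj.v) < 0.01

    def test_constant_input_monotone_belief(self):
        """Repeated R=1 input pushes the outcome probability monotonically up."""
        s = make_session([AFFECTIVE] * 20)
        traj = hgf_trajectory(s, HGFParams(omega2=-2.0, omega3=-6.0))
        assert np.all(np.diff(traj.v) > 0)
        # cross-check first step against the hand-applied update equations
        sigmahat2 = 1.0 + math.exp(1.0 * 1.0 + (-2.0))
        pi2 = 1.0 / sigmahat2 + 0.25
        mu2_1 = 0.0 + (1.0 / pi2) * (1 - 0.5)
        assert traj.v[1] == pytest.approx(1.0 / (1.0 + math.exp(-mu2_1)))

    def test_complement_inputs_mirror(self):
        outcomes = [AFFECTIVE, AFFECTIVE, NEUTRAL, AFFECTIVE, NEUTRAL, NEUTRAL]
        comp = [NEUTRAL if o == AFFECTIVE else AFFECTIVE for o in outcomes]
        p = HGFParams(omega2=-2.5, omega3=-6.0)
        t1 = hgf_trajectory(make_session(outcomes), p)
        t2 = hgf_trajectory(make_session(comp), p)
        np.testing.assert_allclose(t1.v, 1.0 - t2.v, atol=1e-12)


class TestResponseModel:
    def test_probability_matching_at_unit_zeta(self):
        obs = ObservationParams(zeta=1.0)
        for v in (0.1, 0.35, 0.5, 0.82):
            assert response_probability(v, obs) == pytest.approx(v, abs=1e-9)

    def test_indifference_point(self):
        for z in (0.0, 1.0, 4.0, 50.0):
            assert response_probability(0.5, ObservationParams(zeta=z)) == pytest.approx(0.5)

    def test_large_zeta_deterministic(self):
        assert response_probability(0.7, ObservationParams(zeta=200.0)) > 0.999

    def test_loglik_closed_form(self):
        s = make_session([AFFECTIVE] * 10)
        traj = rw_trajectory(s, RWParams(alpha=0.0))  # v' = 0.5 throughout
        ll = response_loglik(traj, [AFFECTIVE] * 10, ObservationParams(zeta=1.0))
        assert ll == pytest.approx(10 * math.log(0.5))

    def test_loglik_all_missed_is_zero(self):
        s = make_session([AFFECTIVE] * 4, responses=[MISSED] * 4)
        traj = rw_trajectory(s, RWParams(alpha=0.3))
        assert response_loglik(traj, [MISSED] * 4, ObservationParams()) == 0.0

    def test_loglik_matches_naive_product(self):
        """Independent per-trial product oracle agrees to 1e-10."""
        rng = np.random.default_rng(4)
        s = simulate_session(make_oracle_agent(), TaskConfig(), rng)
        traj = rw_trajectory(s, RWParams(alpha=0.25))
        obs = ObservationParams(zeta=3.0)
        responses = sample_responses(traj, obs, rng)
        prod = 1.0
        for vp, resp in zip(traj.v_prime, responses):
            p = vp**3.0 / (vp**3.0 + (1 - vp) ** 3.0)
            prod *= p if resp == AFFECTIVE else 1 - p
        assert response_loglik(traj, responses, obs) == pytest.approx(
            math.log(prod), abs=1e-10
        )

    def test_loglik_length_mismatch(self):
        s = make_session([AFFECTIVE] * 4)
        traj = rw_trajectory(s, RWParams(alpha=0.3))
        with pytest.raises(ValueError, match="length"):
            response_loglik(traj, [AFFECTIVE] * 3, ObservationParams())

    def test_model_entropy_rate(self, rng):
        """Average log likelihood of self-generated responses approaches the
        negative entropy of the response distribution (Monte-Carlo oracle)."""
        s = make_session([AFFECTIVE, NEUTRAL] * 10)
        traj = rw_trajectory(s, RWParams(alpha=0.2))
        obs = ObservationParams(zeta=2.0)
        p = np.asarray(response_probability(traj.v_prime, obs))
        entropy = -np.sum(p * np.log(p) + (1 - p) * np.log(1 - p))
        lls = [
            response_loglik(traj, sample_responses(traj, obs, rng), obs)
            for _ in range(300)
        ]
        assert np.mean(lls) == pytest.approx(-entropy, abs=3 * np.std(lls) / np.sqrt(300))


class TestFitting:
    def test_aic_arithmetic(self):
        fit = FitResult("rw", {}, log_likelihood=-10.0, n_params=1, n_trials_used=40, converged=True)
        assert fit.aic == 22.0

    def test_too_few_trials_rejected(self):
        s = make_session([AFFECTIVE] * 4)
        with pytest.raises(ValueError, match="non-missed"):
            fit_model(s, model_name="rw")

    def test_rw_fit_recovers_strong_signal(self):
        """Fitting the generating model to low-noise data lands near the truth."""
        rng = np.random.default_rng(8)
        sessions = []
        for _ in range(4):
            agent = RWAgent(alpha=0.3, zeta=8.0, rng=rng)
            sessions.append(simulate_session(agent, TaskConfig(), rng))
        alphas = [
            fit_model(s, model_name="rw", seed=1, n_starts=5).params["alpha"]
            for s in sessions
        ]
        assert abs(np.mean(alphas) - 0.3) < 0.15

    def test_invalid_model_name(self):
        s = make_session([AFFECTIVE] * 12)
        with pytest.raises(ValueError, match="unknown model"):
            fit_model(s, model_name="qlearn")
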