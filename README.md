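# pavlearn

Simulation and model-based analysis of probabilistic serial-reversal
Pavlovian learning, for computational cognitive neuroscientists who want a
fully testable, download-free version of the classic PE-fMRI analysis stack.

In the modelled experiment a subject repeatedly sees one of two cues and
predicts whether it will be followed by an affective (appetitive/aversive) or
a neutral outcome. One cue delivers the affective outcome on 75% of trials,
the other on 25%; after five consecutive correct predictions the mapping
reverses, one to three trials later. Learning is driven by the prediction
error (PE) — the mismatch between outcome and expectation — and the package
follows that signal end to end:

- **task**: schedule generation and agent-in-the-loop simulation of
  40-trial sessions with criterion-triggered reversals;
- **models**: Rescorla–Wagner learning, δt = Rt − Vt, Vt+1 = Vt + α·δt with
  V1 = 0.5, in a concurrence coding (R = 1 when the outcome matches the
  cue's *initial* association) plus the affective-frame transformation
  (V′, δ′); TD and 3-level binary HGF comparators; unit-square-sigmoid
  response model p = V′^ζ/(V′^ζ + (1−V′)^ζ); multi-start ML fitting;
- **selection**: AIC (2k − 2 lnL) tables compared by Friedman's rank test
  and Bonferroni-corrected Wilcoxon signed-rank post hocs;
- **glm**: double-gamma-HRF convolved designs with mean-centred PE
  parametric modulators, discrete-cosine high-pass (128 s), OLS estimation,
  and ROI-BOLD simulation with known modulation amplitudes;
- **stats**: accuracy vs chance, one-sample ROI t tests with Bonferroni over
  ROIs, 2×2 repeated-measures ANOVA (PE type × learning type), Pearson
  trait–activity correlations;
- **sem**: ML path analysis of the 3-node chain CMA → posterior mOFC → lOFC
  (implied covariance, χ² on df = 1, Wald SEs, standardized coefficients);
- **cohort**: synthetic cohorts — RW agents with known (α, ζ), trait scores,
  ROI betas with known trait couplings — so every stage is checked by
  parameter recovery.

See `docs/methods.md` for the full model account and the design choices.

## Worked example

```python
import numpy as np
from pavlearn import TaskConfig, RWParams, simulate_session, rw_trajectory, fit_model
from pavlearn.models import RWAgent

rng = np.random.default_rng(0)
agent = RWAgent(alpha=0.3, zeta=5.0, rng=rng)      # a learning responder
session = simulate_session(agent, TaskConfig(), rng)
print("reversals at trials:", session.reversal_indices)
print("accuracy:", round(session.accuracy(), 3))

traj = rw_trajectory(session, RWParams(alpha=0.3))
print("first five V values:", np.round(traj.v[:5], 3))
print("first five PEs (affective frame):", np.round(traj.delta_prime[:5], 3))

fit = fit_model(session, model_name="rw", seed=1)
print("ML estimates:", {k: round(v, 3) for k, v in fit.params.items()},
      "AIC:", round(fit.aic, 2))
```

prints

```
reversals at trials: [8, 16, 31]
accuracy: 0.575
first five V values: [0.5   0.65  0.755 0.828 0.88 ]
first five PEs (affective frame): [ 0.5    0.35  -0.245  0.172  0.12 ]
ML estimates: {'alpha': 0.212, 'zeta': 6.699} AIC: 15.99
```

The agent learned well enough to trigger three reversals; the value series
starts at maximal uncertainty (V1 = 0.5) and climbs as the contingency is
learned; the affective-frame PEs flip sign when the less-expected outcome
arrives. The ML fit recovers a learning rate in the neighbourhood of the
generating α = 0.3 from a single 40-trial session — single-session estimates
are noisy, which is why cohort-level recovery (bias, not per-subject error)
is the validated quantity.

The same stages are available from the shell:

```sh
pavlearn make-cohort --seed 1 --out cohort/
pavlearn fit-models --sessions cohort/ --model rw --seed 1 --out fits.tsv
pavlearn run-pipeline --seed 1 --subjects 8 --out report/
```

Every invocation records its seed and config hash in a `manifest.yaml`.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the pipeline's
design- and model-forced headline quantities: the long-run affective-outcome
percentage on high-probability-affective-cue trials in simulated schedules
(250 sessions); the mean recovered standardized path coefficients when the
3-node chain is simulated at coefficients (0.29, 0.66) with N = 5,000 and
refitted (20 replicates); and the empirical extraversion–ROI-beta correlation
in a 10,000-subject synthetic cohort at the generator's default coupling.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
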