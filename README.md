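# popglm

Poisson GLMs for coupled neural populations: how much of a neuron's
apparent tuning is really about the outside world, and how much is carried
by the other neurons recorded alongside it?

Multi-electrode recordings are conventionally summarised neuron by neuron
with tuning curves — firing rate as a function of reach direction, grating
orientation, tone frequency, or the animal's position. But neurons are not
independent: shared input and functional interactions induce trial-to-trial
(noise) correlations, and a neuron's spiking may be predicted more directly
from its neighbours' same-bin activity than from the stimulus. `popglm`
implements the model family and analysis pipeline for asking that question
with trial-binned spike counts, for systems neuroscientists and methods
developers working with population recordings.

## The model

Each neuron's count y_it in trial t is Poisson with rate

    lambda_it = exp( mu_i + alpha_i . f(x_t) + sum_{j != i} beta_ij y_jt )

where f(x_t) is a tuning basis on the external covariates (cosine tuning
for direction, Gaussian radial bases for place and log-frequency), and
beta_ij couples neuron i to the same-bin count of neuron j. Three nested
variants — tuning-only, coupling-only, and full — are fit per neuron by
maximum likelihood (IRLS) or MAP with an L1 penalty on the coupling
weights (proximal Newton + cyclical coordinate descent), the penalty
chosen by 10-fold cross-validated held-out log-likelihood.

On top of the fits the package computes the field's standard summaries
(spike-prediction accuracy in bits/s against a homogeneous Poisson null,
fraction of variance explained by tuning, tuning modulation / preference /
overlap, spike-count and noise correlations, coupling degree
distributions, hyperbolic scaling fits), Bayesian stimulus decoding under
conditional independence and under the full instantaneous-coupling model
(Gibbs sampling with ordered over-relaxation plus a chain-rule joint
probability estimator), and synthetic populations with known ground truth
— including the shuffle-within-condition and independent-resimulation
controls. See `docs/methods.md` for the complete account.

## Worked example: tuning explained away by coupling

Three simulated neurons form a chain: neuron 0 is direction-tuned, neurons
1 and 2 receive its output (coupling weight 0.25) but have no direct
stimulus drive. All three *look* tuned; the full model reveals which
tuning is real.

```python
import numpy as np
import popglm as pg

spec = pg.toy_chain_spec(n_trials=4000, beta=0.25, seed=0)
counts, cov = pg.simulate_tuned_population(spec)
basis = pg.BasisSpec("cosine_direction")

tuning = pg.fit_population(counts, cov, basis, "tuning", penalty=0.0)
full = pg.fit_population(counts, cov, basis, "full", seed=0, penalty="cv")

for tc, fl in zip(tuning, full):
    design = pg.build_design(counts, cov, basis, fl.neuron, None)
    fve = pg.fraction_variance_tuning(fl, design)
    mod_tc = pg.tuning_modulation(tc, basis, counts.bin_duration)
    mod_fl = pg.tuning_modulation(fl, basis, counts.bin_duration)
    beta = dict(zip(fl.coupling_sources.tolist(),
                    np.round(fl.coupling_weights, 3).tolist()))
    print(f"neuron {fl.neuron}: FVE={fve:.2f}  "
          f"modulation {mod_tc:.1f} -> {mod_fl:.1f} Hz  coupling {beta}")
```

Output:

```
neuron 0: FVE=0.98  modulation 30.0 -> 23.2 Hz  coupling {1: 0.024, 2: 0.014}
neuron 1: FVE=0.03  modulation 23.2 -> 1.6 Hz  coupling {0: 0.212, 2: 0.005}
neuron 2: FVE=0.03  modulation 22.8 -> 1.6 Hz  coupling {0: 0.204, 1: 0.011}
```

Read: under the tuning-only model all three neurons show ~23–30 Hz of
direction modulation. Once coupling is modelled, neurons 1 and 2 keep
essentially none of it (modulation collapses to ~1.6 Hz, fraction of
variance explained by tuning 0.03) while recovering the true coupling
weight from neuron 0 (~0.21 after L1 shrinkage); neuron 0's tuning
survives (FVE 0.98). The apparent tuning of 1 and 2 has been explained
away.

The same pipeline is available from a shell:

```bash
popglm simulate tuned --n-neurons 40 --n-trials 2400 --rho 0.3 -o sim/pop
popglm scaling --data sim/pop --basis cosine --sizes 1,2,4,8,16,40 -o run/
popglm report run/
```

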