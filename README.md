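# marstab

Stochastic stability and persistence analysis of microbial community time
series with multivariate autoregressive (MAR) Gompertz models.

`marstab` is aimed at microbial ecologists working with longitudinal
community profiles — for example daily vaginal-microbiome samples where 16S
rRNA gene sequencing gives per-taxon relative abundances and a pan-bacterial
qPCR assay (run in replicate) gives total 16S copy counts.  Instead of
describing such data with snapshots or summary diversity indices, the
package fits an explicit stochastic population-dynamics model and asks
process-level questions: how strongly do taxa interact, how stable is the
community under environmental noise, and what is the probability that a
focal group (say, pooled *Lactobacillus*) stays dominant over the coming
weeks?

## The model

Log abundances **X**ₜ of *p* taxa follow the MAR(1) (stochastic multispecies
Gompertz) recursion

    X_t = A + B X_{t-1} + E_t,      E_t ~ N(0, Σ)

* **A** — intrinsic growth rates (natural-log units per day);
* **B** — interaction matrix: *b*ᵢⱼ is the effect of taxon *j*'s log
  abundance on taxon *i*'s growth; diagonals measure density dependence
  (near 1 = weak);
* **Σ** — covariance of shared environmental growth-rate shocks.

When the spectral radius of **B** is below one the process is stationary
with mean (I − B)⁻¹A and covariance solving V = B V Bᵀ + Σ (in one dimension
the familiar σ²/(1 − b²)).

Estimation is two-stage.  Stage 1 removes sampling error: each taxon's
series is fitted with a univariate Gompertz state-space model (latent AR(1)
plus replicated Gaussian observation error) by exact Kalman maximum
likelihood, handling missing days, and smoothed states replace the raw
observations.  Stage 2 estimates (A, B, Σ) from the denoised matrix by
conditional least squares — the conditional-ML solution for a Gaussian
MAR — with design feasibility checked first: a *p*-taxon fit has 2p² + p
free parameters against (n − 1)mp observed transitions, so a single
replicate needs at least n = 2(p + 1) days.  Stage-1 uncertainty is
propagated by a parametric bootstrap that re-simulates the full generative
chain.

From a fitted model the package computes four stochastic-stability metrics
(variance proportion det(B)^(2/p), mean/variance return rates, and two
reactivity variants; lower = more stable), classifies many communities by
PCA + k-means on those metrics, and estimates persistence probabilities by
Monte Carlo: the prospective RPM tool (probability a focal group's relative
abundance stays above a threshold on each forecast day) and the
retrospective VPM procedure (rolling refit-and-project crash risks).
Counterfactual operations — flipping an interaction sign pair or boosting a
growth rate — show which coefficients drive a persistence trend.

Fitting proportions directly ("compositional" data) biases interaction
estimates; `marstab` anchors relative abundances to absolute scale with the
qPCR totals before fitting, and ships a simulation experiment
(`compositional_bias_experiment`) demonstrating the bias.

## Worked example

Simulate a 3-species community (70 daily samples, triplicate observation
error, 5% missing days), denoise, fit, and inspect stability:

```python
import numpy as np
from marstab import (MARModel, PersistenceSpec, denoise_community,
                     generate_dataset, pool_taxa, rpm_curve, scenario_preset)

preset = scenario_preset(1)                     # all interactions weak
data = generate_dataset(preset.params, n=70, m=3, obs_var=0.1,
                        missing_rate=0.05, seed=42)
denoised, fits = denoise_community(data.to_series())
res = MARModel(denoised).fit()
print(res.summary())
```

```
MAR(1) Gompertz community model — conditional least squares
================================================================
taxa: 3   days: 70   transitions: 69
parameters: 21   data points: 207   feasible: True
conditional log-likelihood: 93.4667

growth rates A and interaction matrix B (rows: response taxon)
                         A    species1    species2    species3
species1            0.9086      0.8291     -0.0375      0.1557
species2            4.3851      0.0531      0.8580     -0.1497
species3            4.2025      0.0253     -0.0200      0.7669
...
```

The diagonal estimates (0.83, 0.86, 0.77) recover the generating weak
density dependence (0.85), and `res.stability()` summarises the fitted
dynamics (variance proportion 0.664, mean return rate 0.870, …).

Persistence of a focal group versus everything else, and the effect of an
interaction sign flip, using a two-group interaction matrix with weak
density dependence in both groups (0.86 and 0.76), a −0.39 effect of the
second group on the focal group and a 0.001 reciprocal effect (growth rates
chosen so both groups are stationary at ln 3.5×10⁸ copies, Σ = 0.01·I):

```python
from marstab import MARParameters, flip_interactions

B = np.array([[0.86, -0.39], [0.001, 0.76]])
mu = np.full(2, np.log(3.5e8))
params = MARParameters((np.eye(2) - B) @ mu, B, 0.01 * np.eye(2),
                       taxa=("Lactobacillus", "other"))
spec = PersistenceSpec(threshold=0.45, horizon=20, n_traj=10_000)
orig = rpm_curve(params, spec, seed=1)
flip = rpm_curve(flip_interactions(params, 0, 1), spec, seed=1, x0=mu)
```

With both groups started at a 50/50 split, the original asymmetric
interactions erode persistence (days 1/5/10/20: 0.920, 0.744, 0.707,
0.684) while the sign-flipped community persists with probability 1.000 on
every forecast day — the negative effect of the second group on the focal
group is what drives the decay.

The same pipeline is scriptable from the shell:

```sh
marstab simulate --scenario 1 -n 70 -m 3 --obs-var 0.1 --seed 5 --out sim.csv
marstab denoise --data sim.csv --out den.csv
marstab fit --data den.csv --out fit.json
marstab stability --params fit.json
marstab rpm --params fit.json --fast --seed 1 --out rpm.csv
```

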