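# hbggm — hierarchical Bayesian Gaussian graphical models

`hbggm` estimates sparse functional-connectivity networks jointly across
many subjects.  Given one multivariate time series per subject (regions ×
time points, e.g. fMRI ROI activations or MEG power envelopes), it infers
each subject's precision (inverse covariance) matrix together with the
group-level network, reporting connectivity as partial correlations
`P_ij = -ω_ij / √(ω_ii ω_jj)`.  It is aimed at researchers who need
single-subject network estimates that borrow strength from the whole
cohort — the regime where per-subject estimation alone is noisy.

## The model

Each subject's data are modelled as `Y_s ~ N(0, Ω_s⁻¹)` with the precision
matrices tied together by a hierarchical spike-and-slab prior on every
off-diagonal element:

```
ω_ijs | z_ij = 1  ~  N(μ_ij, σ_ij²)        (slab: edge present in all subjects)
ω_ijs | z_ij = 0  =  0                      (spike: edge absent in all subjects)
μ_ij  ~ N(0, χ²),   χ ~ C⁺(0, A)            (group means, shrunk toward zero)
log σ_ij ~ N(log m_σ, s_σ²)                 (between-subject spread)
z_ij ~ Bernoulli(a),   a ~ Beta(a_π, b_π)   (shared network structure)
ω_iis ~ Exp(λ_s/2),    λ_s ~ Ga(1/3, 0)     (diagonals)
```

with defaults `m_σ = 0.5, s_σ = 1, A = 0.7, a_π = b_π = 6` appropriate for
variance-scaled data.  Inference is a block-Gibbs sampler that draws one
column of every subject's precision matrix at a time: after the
substitution `(u, ν) = (ω_12, ω_22 − ω_12ᵀΩ_11⁻¹ω_12)` the column
conditional is a linear regression (Gaussian on `u`, Gamma on `ν > 0`), so
every update provably stays inside the positive-definite cone.  Edge
indicators are sampled by Metropolis–Hastings on the column's model
evidence with the strengths and group means integrated out analytically.

Five variants share the machinery: `strong` (full spike-and-slab),
`weak` (full graph, continuous shrinkage only), `single_subject`
(concatenated data, central slab), `bayesian_glasso` (per-subject Laplace
prior) and `ssvs` (per-subject two-component normal mixture).  Baselines
with closed forms — naive inversion, Tikhonov `(Σ + λI)⁻¹`, graphical
lasso, Wishart posterior mean, and a hierarchical-Wishart Gibbs sampler —
are provided for comparison, along with simulators for the standard circle,
random-edge and G-Wishart-structured benchmark designs and RMS/ROC-AUC
evaluation utilities.

## Worked example

Fit the strongly sparse model to a simulated cohort of 5 subjects sharing a
6-node ring network (precision 1 on the diagonal, 0.5 between neighbours,
0.4 closing the ring), 18 samples per subject:

```python
import numpy as np
from hbggm import SamplerConfig, run_sampler, generate
from hbggm.baselines import naive_partial_correlation
from hbggm.evaluate import rms_errors, normalise_rms

panel, truth = generate("sim1", 7)        # 5 subjects, p=6, n_s=18
cfg = SamplerConfig(model="strong", n_warmup=1000, n_samples=4000, thin=10, seed=1)
draws = run_sampler(panel, cfg)

print(np.round(draws.group_partial_corr_mean(), 2))
print(np.round(draws.edge_probabilities(), 2))

_, naive_pc = naive_partial_correlation(panel)
ratio = normalise_rms(
    rms_errors(list(draws.subject_partial_corr_mean()), truth.precisions),
    rms_errors(naive_pc, truth.precisions),
)
print(round(float(ratio.mean()), 2))
```

prints

```
[[ 1.   -0.52  0.09 -0.02  0.11 -0.28]
 [-0.52  1.   -0.35  0.01 -0.01 -0.03]
 [ 0.09 -0.35  1.   -0.51  0.    0.  ]
 [-0.02  0.01 -0.51  1.   -0.41  0.01]
 [ 0.11 -0.01  0.   -0.41  1.   -0.54]
 [-0.28 -0.03  0.    0.01 -0.54  1.  ]]
[[0.   1.   0.58 0.33 0.72 0.99]
 [1.   0.   1.   0.19 0.21 0.36]
 [0.58 1.   0.   1.   0.18 0.25]
 [0.33 0.19 1.   0.   1.   0.33]
 [0.72 0.21 0.18 1.   0.   1.  ]
 [0.99 0.36 0.25 0.33 1.   0.  ]]
0.37
```

The group partial correlations recover the ring (true values −0.5 on the
neighbour edges, −0.4 on the wrap-around edge, 0 elsewhere); the ring edges
carry edge-inclusion probabilities near 1 while most absent edges sit well
below; and the posterior-mean estimates cut the reconstruction error to
0.37 of what naive per-subject inversion achieves on the same data — with
only 18 samples per subject, pooling across subjects matters.

The same pipeline is available from the shell:

```
hbggm simulate --preset sim1 --seed 7 --out sim/
hbggm fit      --manifest sim/manifest.json --model strong --seed 1 --out fit/
hbggm baseline --manifest sim/manifest.json --method pcorr --out naive/
hbggm evaluate --estimates fit/ --truth sim/truth --naive naive/ --out eval.json
hbggm report   eval.json
```

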