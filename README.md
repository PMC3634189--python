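# txswitch — a temporal switch model of transcription

`txswitch` estimates *when* a gene's transcriptional activity changes from
time-series expression data (microarray, RT-PCR, NanoString, RNA-seq counts
proportional to concentration), and decouples those changes from mRNA
degradation.  It is aimed at people analysing time-course experiments —
circadian biology being the motivating case — who want mechanistic quantities
(switch times, synthesis rates, half-lives) rather than smoothed profiles.

## The model

mRNA concentration X(t) on an observation window [0, L] follows a
piecewise-linear ODE,

    dX/dt = β_j − δ X(t)        for  t ∈ [s_{j−1}, s_j),

with unknown switch times 0 < s_1 < … < s_k < L at which the transcription
rate β jumps, a shared first-order degradation rate δ (half-life ln 2/δ), and
an unknown number of switches k.  A rate increase is an *on-switch*, a
decrease an *off-switch*.  The closed-form solution is linear in
(X₀, β_1…β_{k+1}), so these coefficients are computed by least squares at any
(δ, s) rather than sampled.

Inference over (k, s, δ, τ) — τ the residual precision of the i.i.d. Gaussian
observation noise — runs by reversible-jump MCMC: position / birth / death
moves on switches under a truncated Poisson(λ) prior on k, random-walk
Metropolis on log δ, and a conjugate Gibbs step for τ.  Posterior switch
times, pooled over all visited models, are summarized by a kernel density
whose local maxima are fitted with a Gaussian mixture: each component's mean
± two-sigma band is one reported switch.

Downstream, the package clusters genes by the symmetric Kullback–Leibler
distance between their switch-time densities (whole, or on/off separately),
optionally combined with promoter-motif co-occurrence or expression-profile
similarity, via affinity propagation; cluster motif enrichment uses the
hypergeometric test with Benjamini–Hochberg FDR control.  A Bayesian
hierarchy pools one gene's degradation rate across experiments through a
Gamma hyperdistribution parameterized by mean and CV.

## Worked example

```python
import txswitch as tx

# simulate one gene: two switches at 8 h and 20 h, delta = 0.5/h,
# two replicates sampled every 4 h over two circadian cycles
series, truth = tx.simulate_gene(
    tx.e1_like_design(s=(8.0, 20.0), delta=0.5, noise="medium"), seed=5)

res = tx.SwitchModel(series).fit(n_iter=20_000, burn_in=5_000, seed=7)
print(res.summary())
```

Output:

```
Temporal switch model — RJMCMC posterior summary
====================================================
gene: sim_gene   experiment: E1-like
iterations: 20000  (burn-in 5000)
posterior mode k: 2   mixture components: 2
degradation rate delta: 0.7372 /h  (90% CI 0.2677-1.8531)
half-life: 0.94 h  (stability group 0-1)
on/off switch samples: 16019/16235

switches (mean ± two-sigma band):
  s1:   8.95 h   band [  6.08,  11.83]   weight 0.472
  s2:  21.25 h   band [ 18.55,  23.96]   weight 0.467

acceptance rates: position=0.18, birth=0.04, death=0.02, delta=0.82
```

The sampler identifies both switches (truth 8 h and 20 h) to within about an
hour; the degradation-rate interval covers the generating value 0.5/h —
coarse 4-hourly sampling genuinely limits how sharply δ can be pinned down,
which is exactly what the interval communicates.  Clustering, enrichment and
multi-experiment pooling are available as library calls
(`sd_distance_matrix`, `cluster_affinity_propagation`, `motif_enrichment`,
`HierarchicalSwitchModel`) or through the CLI:

```bash
txswitch simulate --n-genes 10 --seed 1 --out expr.csv
txswitch fit --expression expr.csv --fast --seed 1 --out-dir fits/
txswitch cluster --sd-dir fits/ --motifs motifs.csv --out-dir clusters/
txswitch pool --expression multi_experiment.csv --gene AT1G01060 --out pool.json
```

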