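# Methods

## Model

mRNA concentration on an observation window [0, L] follows
dX/dt = β_j − δX for t ∈ [s_{j−1}, s_j), with regime boundaries
s_0 = 0 < s_1 < … < s_k < s_{k+1} = L.  Solving each linear regime and
chaining final states gives the closed form

    X(t) = X0 e^{−δt} + Σ_i (β_i/δ) (e^{−δ max(0, t−s_i)} − e^{−δ(t−s_{i−1})}),

where regimes the trajectory has not entered contribute zero.  The
(1 − e^{−δu})/δ quotients are evaluated through `expm1`; when δL < 1e−8
the linear Taylor limit (the regime's overlap with [0, t]) is used, so the
small-δ regime never divides by a vanishing quantity.  X(t) is linear in
(X0, β_1…β_{k+1}), giving a design matrix with column e^{−δt} for X0 and
one basis column per regime; observations are the stacked non-missing
cells of all replicates, assumed i.i.d. Gaussian around the trajectory
with precision τ.

Expression values are fitted on the scale supplied (assumed proportional
to concentration); no internal log transform is applied.  Coefficients,
including X0, are unconstrained in sign: the data scale is arbitrary and
the least-squares values are only interpretable up to it.

## Sampler

One sweep = one dimension move (position / birth / death), one random-walk
Metropolis update of log δ, one Gibbs draw of τ.  Moves are accepted by
the Green rule α = min(1, exp(Δloglik + Δlogprior + Δlogproposal)).

* Priors: k ~ Poisson(λ=2) truncated at k_max=10; switch positions
  ordered-uniform on [0, L]; τ ~ Gamma(0.01, 0.01); log δ ~
  Normal(log 0.2, 1.5²).  A minimum separation s_min (default: the median
  observation spacing) keeps switches apart and away from the boundaries,
  since switches without an observation between them are unidentifiable.
* Move probabilities: b_k = c·min(1, λ/(k+1)), d_k = c·min(1, k/λ),
  c = 0.4, with b_{k_max} = d_0 = 0; the position move takes the rest, so
  every move type keeps ≥ 0.2 probability.
* Birth: the new time is uniform on the admissible set A (the window minus
  s_min-neighbourhoods of existing switches and boundaries); prior ratio
  p(k+1)(k+1)/(p(k)L), proposal ratio d_{k+1}|A|/((k+1) b_k).  The
  1/(k+1) factor is the reverse death's uniform choice of which switch to
  delete; omitting it breaks detailed balance (the chain then fails the
  likelihood-off prior-recovery check, the canonical reversible-jump
  correctness oracle, which is part of the test suite).  Death ratios are
  the exact inverses.
* Coefficients are never sampled.  By default the dimension and δ moves
  compare models by the likelihood with the regression coefficients
  integrated out under a Zellner g-prior β ~ N(0, (g/τ)(XᵀX)^{−1}):

      log p(y | k, s, δ, τ) = −(n/2) log(2π/τ)
                              − (τ/2)(SSE + ‖Xβ̂‖²/(1+g))
                              − (p/2) log(1+g),

  p = k+2, computable from least-squares quantities alone.  The
  (p/2)·log(1+g) term is the Occam factor that makes k identifiable: a
  plain profiled likelihood (available via
  `PriorSpec(coefficient_likelihood="profiled")`) always improves with
  extra switches, and because the Gibbs-updated τ tracks the shrinking
  SSE, the chain then drifts to k_max even on noise-free data, dragging δ
  into a degenerate step-function regime.  A flat-prior marginalization is
  no better — it rewards shrinking design columns (δ → ∞) through the
  |XᵀX|^{−1/2} factor — whereas the g-prior marginal is invariant to
  column scaling.  Default g = max(n, (k_max+2)²), a benchmark-prior
  choice; its square-root penalty per parameter sits between unit
  information (g = n) and risk-inflation choices and is deliberately not
  data-dependent beyond n.
* τ update: Gibbs from Gamma(a + n/2, b + SSE/2), the usual normal
  regression conditional at the fitted coefficients.
* δ update: random walk on log δ (sd 0.15).  Working on the log scale
  against a prior specified on log δ requires no Jacobian; in the
  hierarchical model, where the prior is a Gamma density on δ itself, the
  +log δ Jacobian is included.

The weakly-informative prior sd 1.5 on log δ (≈ half-lives from minutes
to days) matters: with samples every Δt hours the likelihood is flat in δ
above ~1/Δt, because every regime re-equilibrates between consecutive
observations.  A much wider prior places substantial posterior mass in
that degenerate tail and destroys interval coverage of δ; the chosen
scale keeps the posterior honest about the uncertainty while excluding
rates the sampling design cannot distinguish anyway.

Chains start at k = 0 with δ at the prior centre.  Defaults are 100 000
iterations with 25 000 burn-in; convergence on two-cycle designs is
typically reached within a few thousand sweeps, and 20 000/5 000 (the
CLI `--fast` profile) is adequate for simulation work.

## Switch-time summaries

Post-burn-in switch times, pooled over all visited models, are smoothed
with a Gaussian KDE (Silverman bandwidth on the pooled sample) evaluated
on a 512-point grid and renormalized on [0, L].  Each switch occurrence
is labelled *on* if the following regime's fitted rate exceeds the
preceding one's, else *off* (ties → off); on- and off-densities use the
same bandwidth so their sample-share-weighted sum reproduces the whole
density exactly.  Local maxima of the whole density above 5% of its peak
(suppressing Monte-Carlo ripple) seed a Gaussian mixture fitted by least
squares to the density curve; component count is capped by the maximum k
the chain visited.  Each component's mean ± 2σ band is one reported
switch.  Time is treated as an interval, not a circle: circadian users
should note that densities are not wrapped at the window edges.

## Clustering and enrichment

Pairwise gene dissimilarity is the symmetric KL distance
∫(p−q)(log p − log q) between switch-time densities on a common grid,
with a floor ε = 1e−10 added before the logs (KDE densities vanish at the
window edges).  Similarity = −distance.  Heterogeneous similarity sources
(switch-time, on+off split, expression-profile SSE on z-scored replicate
means, Jaccard motif co-occurrence) are standardized to zero median / unit
MAD off-diagonal before weighted linear combination, since their natural
scales are incommensurable.  Clustering is affinity propagation
(scikit-learn, precomputed similarities; damping 0.9, preference
defaulting to the median similarity — the cluster count emerges from it).
Enrichment of each (cluster, motif) pair uses the hypergeometric upper
tail against the analysed gene set as the population, with
Benjamini–Hochberg control at 5% across all pairs.

## Hierarchical pooling

For one gene in N experiments, per-experiment rates δ_i share a Gamma
hyperdistribution parameterized by mean μ and coefficient of variation
cv (shape = 1/cv², rate = 1/(cv²μ)); the CV parameterization is used
because degradation-rate means are near zero and the CV is the stabler
sampling coordinate.  Hyperpriors: μ ~ Gamma(2, 5) (mean 0.4/h,
half-life ≈ 1.7 h), cv ~ Exponential(3); an informative pathway
(`hyperpriors_from_rate_table`) centres the μ prior on a user-supplied
population rate table and sets the cv prior from its 95th percentile.
Each sweep runs every experiment's reversible-jump sweep with the δ prior
replaced by the current Gamma(μ, cv) density, then updates log μ and
log cv by random-walk Metropolis (sd 0.2) against the product of the
hyperdensity over the δ_i and the hyperpriors.  Switch structures remain
experiment-specific throughout — circadian phase may legitimately differ
between experiments — so only δ is pooled.  Half-lives are reported in
the five standard stability groups (0–1, 1–3, 3–6, 6–12, >12 h;
left-closed bins, so a half-life of exactly 1 h falls in 1–3).

## Synthetic data

The generator draws noiseless trajectories from the closed form at a
sampling protocol and adds i.i.d. Gaussian noise per replicate and
timepoint.  Three presets emulate experiments of decreasing span:
E1-like (48 h = two light–dark cycles, samples every 4 h, R = 2, with a
16:8 light–dark annotation whose dark phases start at 10 h and 34 h,
metadata only), E2-like (17.5 h, every 2.5 h) and E3-like (6 h, hourly).
These are labelled emulations: the real experiments' grids and residual
distributions are not public.  Named noise levels low/medium/high map to
(0.05, 0.15, 0.4) × the noiseless signal range — chosen to bracket what
two-colour microarray time courses typically show — with medium as the
default study condition.  An oscillatory preset places three switches
per 24 h cycle with unequal on/off spans, producing the asymmetric
oscillations characteristic of clock genes.  What the generator does
*not* emulate: probe effects, normalization artefacts, heteroscedastic or
correlated noise, and cell-population desynchronization; passing
recovery tests on these data therefore demonstrates correctness of the
inference machinery, not robustness to every real-data pathology.

`simulation_study` scores each fitted dataset by posterior-mode k against
truth, the absolute error of the nearest mixture mean per true switch,
and the relative error and central-interval coverage of δ.

## Verification runs and problem sizes

The test suite and `scripts/acceptance.py` recompute, from freshly
simulated data: ODE closed form vs an independent fixed-step RK4 oracle
(step 1e−3, steps aligned to switch boundaries, per-regime recurrence
composed in closed form; 100 random instances); the design-matrix
identity (100 instances); the τ Gibbs draw against its analytic Gamma
conditional (10⁴ draws, KS); prior recovery with the likelihood disabled
(200 000 iterations; χ² on the thinned k-marginal against the truncated
Poisson, KS of pooled positions against uniform — thinning is used
because the nominal calibration of both tests assumes independent draws,
and s_min = 0 there because the uniform marginal only holds without a
separation constraint); two-switch recovery at the E1-like design and
medium noise (20 genes; 20 000 iterations in the test suite, 8 000 in
the acceptance script to keep its end-to-end runtime moderate); on/off
mirror invariance (20 paired datasets, 6 000 iterations, Wilcoxon);
symmetric-KL and affinity-propagation oracles; the exact hypergeometric
toy value and the BH false-flag rate over 200 null motif tables; and
hierarchical recovery/shrinkage (3 experiments spanning 48/17.5/6 h,
6 000 sweeps).

## Known limitations

* δ is only weakly identified when sampling is coarse relative to 1/δ;
  the posterior interval, not the point estimate, is the meaningful
  output there.
* Exactly noise-free data make the chain effectively freeze once τ
  reaches the ceiling implied by b_τ; recovery experiments therefore use
  small positive noise.
* The g-prior marginalization is a deliberate departure from a plain
  profiled likelihood; with `coefficient_likelihood="profiled"` the
  sampler reproduces the simpler construction but overfits k.
* The mixture summary can split one broad posterior mode into two
  adjacent components on noisy genes; the component weights flag such
  cases (spurious components carry low weight).
* Affinity propagation is deterministic given seed and damping but can
  fail to converge on adversarial similarity matrices; the result object
  carries a convergence flag.
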