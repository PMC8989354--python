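# Methods

This note documents the models, conventions and numerical choices behind
`pathsurv`, and what the synthetic test-bed does and does not establish.

## Pathway activity by truncated SVD

Expression is first preprocessed per gene row: optional `log2(value +
offset)` (off by default — microarray releases are commonly already on a
log scale, and double-logging would distort the data), then z-scoring with
the **population** standard deviation (divide by *m*), matching the common
standard-scaler convention. Zero-variance rows are dropped with a warning;
they carry no covariance information and make the z-score undefined.

For a pathway, the submatrix **B** (measured member genes × samples, in
matrix row order) is factorized by a full deterministic SVD and the leading
triple (**U**, S, **V**) retained; with `k > 1`, further components are
returned in decreasing singular-value order. Pathway submatrices are small
(tens to hundreds of genes), so no randomized solver is needed and results
carry no solver seed.

**Sign convention.** The SVD orientation is arbitrary, so (**U**, **V**)
are flipped jointly to make the eigengene correlate non-negatively with
the pathway's mean expression profile. Because **B V** = S **U**, that
correlation has the sign of ΣⱼUⱼ, so the rule reduces to: flip iff
ΣⱼUⱼ < 0; on an exact zero sum, flip iff the first nonzero eigensample
element is negative. The convention affects the sign of the Cox β but not
its p-value; its purpose is bit-reproducible output across linear-algebra
backends.

**Minimum pathway size** defaults to 3 measured genes: a rank-1 summary of
fewer genes is degenerate. Pathways failing the bound (or emptied by ID
mapping/intersection) are flagged and reported, never silently dropped.
Unit-norm eigengenes are used as covariates without rescaling by S;
Cox p-values are invariant to linear rescaling, and β is reported on the
unit-norm scale.

## Cox regression

The hazard model is λ(t|X) = λ₀(t)·exp(X·β), fitted by maximizing the
partial likelihood — the baseline λ₀ is never estimated. The solver is
Newton–Raphson with step-halving (up to 30 halvings per step), convergence
at gradient sup-norm < 1e-7, at most 100 iterations. Ties are handled by
Efron's correction by default (Breslow available via `ties="breslow"`).
Per-coefficient significance is the Wald test. Exponentials are computed
after subtracting the per-fit maximum of the linear predictor, with the
shift restored exactly in the log terms, so near-separated designs do not
overflow. Constant covariates and zero-event designs raise a
non-identifiability error; non-converged fits are returned flagged, and the
scan excludes them (with an explicit status) from the q-value computation.

A batched single-covariate path solves thousands of independent fits that
share one outcome (the permutation-calibration workload) with
column-vectorized Newton steps; it is numerically identical to the general
path and is cross-checked against it in the tests, alongside an external
survival library and a grid-search oracle over the directly-coded partial
likelihood.

## Multiple testing

q-values follow Storey's procedure: π̂₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0, 0.05, …, 0.9, smoothed by a cubic spline and evaluated at λ = 0.9,
clipped to (0, 1]; q-values are the step-up–monotonized π̂₀·m·p(i)/i. With
fewer than 100 tests the smoother is unstable and π̂₀ is set to 1, which —
as with `method="bh"` — reduces the procedure exactly to
Benjamini–Hochberg.

## Concordance and cross-validation

Harrell's C counts ordered pairs: a pair with t_i < t_j is comparable iff
the **earlier** subject's event was observed; pairs tied in time are not
comparable; comparable pairs tied in the hazard score contribute ½.
C = 0.5 is a null prediction and 1 a perfect ranking. Out-of-sample C uses
seeded, shuffled k-fold splits (default 5) shared across pathways within a
run so distributions are comparable; each fold fits β on the training
samples and evaluates η = X·β on the holdout. Folds with no training
events, a degenerate training design, or no comparable holdout pairs are
skipped with a warning.

## Diagnostics

**Stability.** A pathway is decomposed on `n_rep` (default 100) random
subsamples of ⌊fraction·m⌋ samples (default 20%), and all pairwise
eigensample distances recorded with the sign-invariant cosine distance
1 − |cos|, which is immune to the arbitrary SVD sign. The background is
the same statistic for random directions drawn uniformly on the unit
sphere of the same dimension (normalized i.i.d. normals); for dimension p
its mean is ≈ 1 − √(2/(pπ)).

**Permutation calibration.** Pathways are selected without replacement by
sampling an exponent a ~ U[−5, 0] and taking the remaining pathway with
nominal p closest to 10^a, spreading the check log-uniformly over the
observed significance range. Each selected pathway's sample↔(time, event)
association is permuted N = min(⌈100/p⌉, max_perms) times (cap default
10⁵, logged when hit) and the empirical p is the plain fraction of
permutations whose refitted Wald p is ≤ the observed one (the (r+1)/(N+1)
estimator is available via `estimator="plus_one"`). "More extreme" is
judged on the permutation p-value, equivalently |Wald z|.

**Gene-set null.** Random gene sets of a given size are drawn uniformly
from the measured genes and pushed through the same decompose→Cox path,
giving a size-matched null against which a curated pathway's p can be
ranked. This separates "these particular genes carry signal" from "any set
of this size would".

## Synthetic data

The generator emulates the data-generating assumptions the method targets:
each pathway has a latent per-sample activity z ~ N(0,1); member genes load
on z with mixed-sign weights (|w| = loading_scale × U(0.5, 1.5), random
signs — mixed signs are the default because within real pathways
transcripts both correlate and anti-correlate with outcome) plus i.i.d.
N(0, noise_sd²) noise; background genes are pure noise. Survival follows
an exponential proportional-hazards law, hazard = baseline_rate ·
exp(Σβ_p z_p), sampled by inverse CDF, with independent exponential (or
administrative) censoring. Confounding is modelled by mixing one pathway's
latent activity into another's.

Defaults, chosen once as a realistic desk-scale analogue of a large breast
cancer cohort: pathway size 25 genes, loading_scale 1.0 and noise_sd 1.0
(per-gene correlation with z ≈ 0.7; the eigengene of a 15–25-gene pathway
then recovers z with |r| ≥ 0.9), baseline hazard 1e-3 per day (median
event time ≈ 700 days at z = 0), censoring rate 4.3e-4 per day (≈ 30%
censored under the null), cohort sizes 150–400 samples and 20–60 pathways
in the preset scenarios, 2000 samples where a tight Monte-Carlo anchor is
needed. The presets encode the canonical study conditions: `null`,
`planted` (one prognostic pathway), `confounded` (a correlated pathway
with no direct effect, which should lose significance once the driver is a
covariate), and `direct_plus_confounder` (a direct effect that should
survive adjustment).

What passing tests on this generator do **not** show: robustness to probe-
or batch-level artefacts, non-Gaussian expression noise, non-proportional
hazards, informative censoring, or the heavy inter-pathway overlap of real
annotation databases (simulated pathways are disjoint). Results on real
cohorts additionally depend on annotation quality and ID mapping.

## Visualization

Sunbursts require a tree, but pathway hierarchies are DAGs; a node with k
parents is duplicated under each (carrying identical statistics), and a
synthetic root joins the top-level pathways — mirroring how hierarchical
pathway browsers present multi-parent events. Angular weight is equal per
leaf by default (pathway-size weighting optional); sibling angles sum to
the parent's span and the first ring spans 360°. The fill encodes
sign(β)·min(−log₁₀ q, cap) with cap 10 on a diverging map centered at
zero; a significance-only mode drops the sign. The HTML is self-contained
SVG with hover tooltips and contains no timestamps, so output is
byte-deterministic given fixed inputs.

## Reproducibility

All randomness flows from explicit seeds; the CLI fans one global seed out
to per-task seeds via `numpy.random.SeedSequence` spawn keys, records them
in the run manifest, and identical config+seed reruns produce
byte-identical result tables.

## Known limitations

Rank-1 summaries can mix distinct regulatory programs inside very large
pathways; the multi-component extension exists but, as the joint-fit null
simulations show, extra components mostly buy extra degrees of freedom.
The Wald test can be conservative at very small event counts. Storey's
π̂₀ smoother needs on the order of hundreds of tests to help; below 100
tests the implementation deliberately falls back to BH. The permutation
cap bounds the resolution of empirical p-values at 1/max_perms.
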