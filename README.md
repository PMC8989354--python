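# pathsurv

Pathway-level survival analysis for transcriptomics cohorts: score every
pathway's activity in every sample by a rank-1 truncated SVD of its
standardized expression submatrix, regress censored survival on those
activities with Cox proportional-hazards models, correct the scan to
q-values, and explore the result on the pathway hierarchy as a sunburst.

## Who this is for

Biostatisticians and computational biologists who have (i) a normalized
gene-by-sample expression matrix, (ii) gene-set annotations such as a
Reactome GMT export plus (optionally) its parent–child relation file, and
(iii) per-sample right-censored survival, and who want per-pathway
prognostic statistics rather than per-gene ones. The package also ships a
full synthetic-data generator, so every part of the pipeline can be
exercised and validated without access-controlled patient data.

## The method

For the standardized expression matrix **A** (genes × samples, each row
z-scored) and a pathway *P*, let **B** be the submatrix of *P*'s measured
genes. The leading singular triple

&nbsp;&nbsp;&nbsp;&nbsp;**B** ≈ **U** S **V**ᵀ

defines the *eigensample* **U** (one weight per gene — the expression
pattern of a typical sample) and the *eigengene* **V** (one element per
sample). The eigengene elements are the per-sample pathway activity
scores: the linear combination of the pathway's genes, found without
supervision, that explains the most variance. Weights in **U** can be of
either sign, so transcripts that anti-correlate inside a pathway reinforce
rather than cancel.

Each pathway's activity is tested, one at a time, in the Cox model

&nbsp;&nbsp;&nbsp;&nbsp;λ(t | X) = λ₀(t) · exp(X·β)

fitted by Newton–Raphson maximization of the partial likelihood (Efron tie
handling; the baseline hazard λ₀ is never estimated). Adding a second,
*confounder* pathway's activity as a covariate yields the residual
association of the tested pathway — e.g. regressing out a proliferation
pathway. Wald p-values are corrected to Storey q-values, and out-of-sample
performance is measured by Harrell's concordance index under seeded 5-fold
cross-validation. Diagnostics cover eigensample stability under
subsampling, an adaptive permutation check of p-value calibration
(each pathway permuted ~100/p times), and a size-matched random-gene-set
null.

## Worked example

Simulate a cohort in which one pathway ("PLANTED", 25 genes) drives the
hazard and nineteen others are null, then scan it:

```bash
pathsurv simulate --scenario planted --samples 150 --seed 3 --out sim
cat > sim/config.yaml <<EOF
expression: sim/expression.tsv
gene_sets: sim/gene_sets.gmt
survival: sim/survival.tsv
folds: 3
EOF
pathsurv scan --config sim/config.yaml --out run --seed 5
head -4 run/results.tsv | cut -f1,4,6,7,8
```

which prints (columns: pathway, β, p, q, cross-validated C):

```
pathway_id	beta	p	q	c_index
PLANTED	12.66320308	2.737417275e-15	5.474834549e-14	0.7360840676
NULL19	2.510590323	0.04292547986	0.3459664236	0.5637210707
NULL02	-2.416863608	0.05189496354	0.3459664236	0.5386479524
```

The planted pathway is recovered with q ≈ 5·10⁻¹⁴ and a held-out
concordance of 0.74; the null pathways sit near q ≈ 0.3–1 and C ≈ 0.5 (a
null prediction). β is reported on the unit-norm eigengene scale, so its
magnitude grows with the cohort size; its sign follows the deterministic
eigengene orientation. `pathsurv validate` then writes stability, calibration
and gene-set-null diagnostics, and `pathsurv visualize` renders the
sunburst (given a hierarchy file) and the concordance histograms. Every
step is also available as a library call (`pathsurv.pathway_activity`,
`pathsurv.survival_stats`, `pathsurv.evaluation`, ...).

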