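# Methods

This note documents the models, conventions and numerical choices behind
`crpcpanel`, and what the synthetic generators do and do not emulate.

## Normalization and scaling

Counts are normalized to counts-per-million per cell/sample and
transformed as `log2(CPM + 1)`. The CPM denominator is the total count
over **all** genes present in the matrix as loaded; no gene filtering
happens before normalization. A raw zero maps to exactly 0, and CPM
columns sum to 10⁶ up to floating tolerance. Cells with zero total count
are a fatal error (they have no defined CPM).

Per-gene z-scores use the sample standard deviation (n−1 denominator),
recorded here because the choice is a convention rather than forced:
it matches the default of mainstream statistical software. Genes with
zero variance map to all-zero z-scores rather than NaN, so constant genes
contribute nothing to signature scores instead of poisoning them.
Z-scoring can be stratified (e.g. per dataset) via the `within` argument;
stratified scaling is the recommended default across single-cell datasets
from different platforms, since cross-dataset batch effects otherwise
dominate the z-scores. A stratum needs ≥ 2 cells.

Composition percentages are `100 · n_subgroup / n_lineage_total` rounded
half-up to two decimals, with the denominator always the annotated cells
of the requested lineage in the requested dataset.

## Signature (module / panel) scores

A score is the unweighted sum of per-gene z-scores over the signature,
making scores exactly additive over disjoint sets on the same z-matrix.
Genes absent from the matrix are skipped and reported; zero overlap is
fatal. For bulk panels, expression is taken to `log2(x + 1)` on the scale
provided (FPKM-like values are used directly; CPM from counts works the
same way) and z-scored across the full set of samples being compared —
the union of all contrast groups — because the score comparisons and
ROC curves span those groups. No per-gene weights or signs are applied.

## Moderated t and the DE screen

The two-group test shrinks the pooled per-gene variance s² (d degrees of
freedom) toward a prior s₀² with weight d₀:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),
    t = (x̄ − ȳ) / √(s̃²(1/n_x + 1/n_y)),  t ~ t(d₀ + d).

Defaults d₀ = 4 and s₀² = the median of gene-wise pooled variances — a
trend-free simplification of limma-style empirical Bayes; both are
configurable. With d₀ = 0 the statistic reduces exactly to the ordinary
pooled two-sample t (verified to 1e-10 against scipy). If the moderated
variance is zero the test returns p = 1 by convention and logs a flag.

The DE screen reports `log2FC = log2((CPM̄_A + 1)/(CPM̄_B + 1))` (the
pseudocount of 1 on the CPM scale keeps low-expression ratios bounded),
BH-adjusted p-values over all tested genes, and direction calls at
|log2FC| > 1, p_adj < 0.05. This screen deliberately is not a
negative-binomial count model: downstream use consumes only the
thresholded gene list, and a calibrated moderated t on log2(CPM+1) gives
a type-I rate of ~5% on null genes (checked in the acceptance suite).
Size factors, dispersion trends and independent filtering are out of
scope. Swapping the groups negates every log2FC and t exactly.

Cohort stratification: normals are exactly `sample_type == "Solid Tissue
Normal"`; every other sample is tumor (so normal/tumor partition the
cohort). Recurrence splits tumors by the "YES"/"NO" new-tumor-event flag;
samples with a missing flag drop out of the recurrence strata only. The
hormone-therapy strata match therapy descriptions by case-insensitive
substring ("Hormone Therapy" may co-occur with other therapies in the
free-text field); requiring exact equality is a stricter alternative the
field data do not support.

## Subgroup-featured genes

For each gene the candidate subgroup is the strict argmax of
per-subgroup mean normalized expression (ties are never called). The
candidate subgroup is tested against all remaining cells pooled
(one-vs-rest) with the moderated t; BH runs over all genes with a strict
argmax; calls additionally require detection — normalized value > 0,
equivalently raw count > 0 — in more than 20% of the candidate
subgroup's cells. Each gene can be featured for at most one subgroup by
construction. Note the argmax selection step means the one-vs-rest
p-values are not marginally calibrated for null genes; the BH threshold
set by genuine markers keeps the realized false-call rate well under 1%
in the planted-recovery checks, which is the regime the procedure is
used in.

## Ligand–receptor communication

Directed candidates are interaction pairs whose ligand member is
annotated "Secreted" and whose receptor member is annotated "Plasma
membrane" (only these two location tokens are honored; a gene annotated
both ways can serve on either side, and such a pair contributes both
directions). The intensity from subgroup A to subgroup B is
`Σ mean_A(ligand) · mean_B(receptor)` on the log2(CPM+1) scale; autocrine
(A = B) is allowed. Contributions are non-negative, the statistic is
invariant to cell and gene order, and scaling all of A's ligand values by
λ scales their contributions exactly by λ.

The permutation null shuffles subgroup labels across **all** annotated
cells, preserving every subgroup's size (a variant restricted to A∪B is
available). The p-value uses the add-one rank
`(1 + #{I_perm ≥ I_obs}) / (1 + N)` so that p can never be 0 and ties
count conservatively against significance. When the number of distinct
(source-set, target-set) arrangements is at most a cap (default 20,000)
sampling is replaced by exhaustive enumeration and the p-value is the
exact tail fraction, with the observed arrangement counting itself —
on the 4-cell toy with two source and two target cells this gives
exactly 1/6, and the degenerate single-arrangement case gives 1. The
sampled estimate converges to the exact value (|Δp| < 0.02 at 10⁴ draws
on the toy) and is super-uniform under the null. Pair rankings across
subgroup combinations sort by contribution descending with a
lexicographic (ligand, receptor, source, target) tie-break, so the
top-k table is deterministic.

## Evaluation

AUC is computed as the area under the empirical ROC (equal to the
Mann–Whitney probability with midrank tie handling; verified exactly
against brute-force pairwise counting), with the positive class scoring
higher: tumor vs normal, recurrent vs non-recurrent, HT-recurrent vs
HT-non-recurrent. The score–time association uses Pearson r with the
two-sided t-transform p-value (a permutation p is a reasonable
alternative; the t-based form was chosen as the common default). Median
splits use the standard interpolated sample median; "short time" means
time ≤ median and "high score" means score ≥ median, and the
between-half comparison is a Welch t. Welch (unequal variance) is used
everywhere a two-group score comparison is reported, since group
variances are never claimed equal; a pooled-t flag exists. The multiple
comparisons in an evaluation report are reported raw, without family-wise
correction, as is conventional for these descriptive panels. The report
is a plain dict serialized with sorted keys, so identical inputs give
byte-identical reports.

## Synthetic generators

Single-cell: counts are negative-binomial with variance
μ + φμ² and a dispersion φ shared across genes (the simplest
parameterization consistent with per-gene overdispersion; φ → 0 recovers
Poisson). Defaults: 3 subgroups × 200 cells, 1,000 genes, baseline mean
0.5, φ = 0.5, 20 disjoint marker genes per subgroup elevated by
2³ = 8-fold (marker log2FC = 3), per-cell library-size factors
log-normal with sd 0.3 so CPM normalization is non-trivial. An optional
ligand/receptor plant multiplies one gene's mean in a source subgroup
and another's in a target subgroup by a fold factor. One RNG stream is
seeded once per simulation with a fixed draw order (size factors, then
counts), so identical configs and seeds are byte-identical.

Bulk: expression is generated on the log2 scale as
`g = baseline + N(0, σ)` (baselines uniform on [2, 8], σ = 1) and stored
as `2^g − 1`, so the pipeline's `log2(x+1)` recovers the log scale
exactly. Default group sizes emulate a TCGA-PRAD-style cohort — 52
normals, 300/60 non-recurrent/recurrent tumors, and 53/14 hormone-treated
non-recurrent/recurrent samples, the last two matching the cohort the
panel targets. Panel genes get an additive shift (default 2σ) in the
recurrent groups; the planted true score is the summed standardized
panel deviation, and recurrence times follow
`max(1, 1200 + β·score + N(0, 200))` days with β = −50, giving a planted
score–time correlation around −0.5, comparable in magnitude to what such
panels report on real cohorts. Phenotype fields are populated so the
stratification rules reproduce the group sizes exactly.

What the generators do **not** emulate: doublets, ambient RNA,
platform/batch effects, gene–gene correlation structure, mean-variance
dispersion trends, censoring of recurrence times, and panel genes whose
effect signs differ. Passing the recovery tests therefore shows the
pipeline's statistics recover cleanly planted structure at realistic
sizes and noise levels — not that the panel itself generalizes to real
cohorts.

## Problem sizes and calibration conventions

The calibration and recovery studies use fixed, pre-chosen sizes:
2,000 genes for the DE type-I check; 500 structure-free datasets × 199
permutations for permutation-p super-uniformity; 100 seeds for the
null-AUC band and for planted recovery. The null-AUC band check runs at
100 samples per group because the sampling SD of a null AUC with
n₁ = n₂ = 100 is ≈ 0.041 (Mann–Whitney variance), so ~98% of null runs
fall in [0.4, 0.6] a priori; at 14-vs-53 the SD is ≈ 0.087 and no
correct implementation could keep 95% of runs inside that band.
Planted-effect recovery runs at 50 samples per group, where the planted
2σ × 6-gene shift separates the HT groups nearly completely.

## Known limitations

- The moderated-t prior is trend-free (single s₀²); strongly
  mean-dependent variance would favor a fitted trend.
- Gene identifiers are matched exactly and case-sensitively; no alias or
  ortholog resolution.
- Ligand–receptor scoring ignores multi-subunit receptor complexes and
  applies no per-pair expression threshold.
- The featured-gene test inherits argmax selection bias (see above); its
  p-values should be read as ranking scores, not calibrated marginal
  error rates.
- Exhaustive permutation enumeration is only attempted below the
  arrangement cap; above it the add-one sampled p has Monte-Carlo error
  ~1/√N.
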