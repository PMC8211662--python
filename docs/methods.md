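# Methods

This note documents the models, conventions and design choices behind
`embryoaxis`, in the spirit of a statistical methods appendix.

## QC and lineage annotation

A cell's mitochondrial fraction is the sum of counts over genes whose
symbol starts with `MT-` divided by its total counts (0 for empty cells);
"detected" means at least one count. The filters follow the stated
conventions exactly: a cell is removed iff its mitochondrial fraction is
*strictly greater* than 0.20 or its detected-gene count is *strictly
below* 1000, so a cell at exactly 20% / exactly 1000 genes is kept.
Filtering is idempotent and order-independent (both criteria are applied
jointly to the original QC values). Embryo inclusion requires at least
one epiblast cell, one hypoblast cell and one trophoblast cell
(cytotrophoblast and syncytiotrophoblast pooled); the minimum is
configurable because a stricter count is equally defensible.

Normalisation is `x -> log(1 + scale * x / total)` per cell with
`scale = 1e4`; empty cells stay zero. A lineage signature score is the
mean over the lineage's marker genes of gene-wise z-scored normalised
expression (z across cells); genes with zero variance contribute 0
rather than NaN. Cells take the argmax lineage; exact ties break by the
fixed order EPI < HYP < CTB < STB, and an optional margin below which a
cell is left `UNASSIGNED` defaults to 0. Signature scoring was chosen
over graph clustering because the four lineages are separable by
canonical markers and scoring is deterministic and dependency-light.

Marker ranking is one-vs-rest: per gene, a two-sided Wilcoxon rank-sum
test (normal approximation with continuity and tie correction, as
implemented in scipy) of the lineage's cells against all others, a log2
fold-change of mean `expm1` expression with pseudocount 1e-9, and BH
adjustment *within* each lineage, matching per-cluster marker reporting.
Genes constant across all cells get p = 1 by convention.

## Stage projection

The projection model is a multinomial (softmax) logistic regression with
an L2 penalty of strength λ (default 1.0; sklearn's `C = 1/λ`), fitted by
L-BFGS on the `n_feature_genes = 2000` most variable genes of the
reference. Feature selection uses the reference only, so the model is
query-agnostic. Query genes missing from the feature list are imputed as
0 after normalisation — a conservative choice that shrinks scores toward
the intercept rather than inventing signal. The objective is convex;
independent fits agree in probability outputs to ~1e-4 at tight
tolerances. Matching scores are arithmetic means of per-cell probability
vectors within query groups, so each row of the score table sums to 1.

## Angular asymmetry

The embryo frame is (c, d, r): c the epiblast centroid, d the unit
vector from c to the hypoblast centroid, r the lateral 0° reference.
Using the epiblast centroid rather than the "middle of the proximal
epiblast surface" is a deliberate simplification — extracting a surface
from point labels is ill-posed — and c is a single swappable argument of
`EmbryoAxis` if a different anchor is wanted. The angle is the full 3D
angle `arccos(unit(p - c) . r)`, collapsing azimuth about r; its
landmarks are 0° (marker-majority side), 90° (distal pole) and 180°
(opposite side). Histograms use 18 fixed 10° bins, right-open except the
last.

The localisation-bias statistic is reference-free: the mean resultant
length of the unit azimuthal projections (components orthogonal to d) of
the marker-positive hypoblast cells. The null permutes marker labels
among the hypoblast cells (equivalently: redraws the positive set
uniformly at the observed size), with the add-one p-value
`(1 + #{T_perm >= T_obs}) / (n_perm + 1)`, ties counted as extreme, and a
mandatory seed. Setting r toward the observed majority side and testing
the mean angle against 90° would bias the test toward rejection; the
permutation design removes that circularity. When every hypoblast cell
is positive there is a single distinct relabelling and p = 1. Cells that
project exactly onto the axis carry no azimuthal information and are
dropped from the statistic. An exhaustive-enumeration variant exists for
small hypoblasts and agrees with the Monte-Carlo p to < 0.02.

Measured behaviour (recomputed by the test suite and
`scripts/acceptance.py`, never hard-coded): the type-I error at
α = 0.05 is within 0.05 ± 0.02 over 400 uniform embryos, and power
against κ = 4 concentration with 30% positives of 60 hypoblast cells
exceeds 0.8.

## Synthetic data

**Counts.** Genes x cells negative-binomial (gamma–Poisson) counts with
per-lineage mean vectors: baseline mean 1.0 per gene, lineage marker
genes boosted by +20 (canonical lineage markers such as *POU5F1*, *GATA6*
or *CGA* are among the most abundant transcripts in their lineages, and
this strength reproduces the clean block structure marker heatmaps show),
dispersion θ = 2 (variance μ + μ²/θ), 2000 genes including the 13
`MT-` genes whose means are tuned so the expected mitochondrial fraction
is 5% (50% for low-quality cells). Default lineage sizes are 166 EPI,
136 HYP, 2182 CTB and 2336 STB cells over 16 embryos (half 9, half
11 d.p.f.), mirroring the reference dataset's cluster sizes. Low-quality
cells (default 300, ~6%) are injected explicitly — non-mitochondrial
depth scaled by 0.1 and mitochondrial fraction centred at 50% — so the
QC filters have guaranteed positive and negative cases; at these
settings good cells detect ~1100 genes and low-quality cells ~190, well
clear of the 1000-gene threshold on both sides. θ → ∞ gives the Poisson
limit. All randomness flows through an explicit seed; no global RNG
state.

**Stage matrix.** Four epiblast stage classes carry a declining naive
program, a rising primed program, a monotonically increasing core
program, and five unique marker genes each (real stages have unique
markers; gradient programs alone leave adjacent stages statistically
inseparable at realistic noise).

**Geometry.** Hypoblast cells are uniform on the distal hemisphere of
radius 50 μm (z ≥ 0, area-uniform); epiblast cells fill a ball centred
at −0.8 R on the axis with radius 0.5 R, entirely proximal of the
equator. Exactly `round(marker_fraction * n)` hypoblast cells are marked
positive, chosen *without replacement* with weights
`exp(kappa * cos(angle to the anterior direction))` — a von
Mises–Fisher-style kernel whose single parameter spans uniform (κ = 0)
to point mass. Conditioning on the count rather than drawing independent
Bernoullis keeps the marginal positive fraction exactly on target at any
κ (the permutation test conditions on the count anyway, so its
calibration is unaffected); with ~25-cell hypoblasts, independent
Bernoulli noise alone would spread per-embryo fractions across nearly
the whole empirically reported interquartile band, leaving no room for
real between-embryo variation.

**Cohorts.** Per-embryo true fractions are Beta-distributed:
7 d.p.f. mean 0.755, sd 0.04, κ = 0 (widespread, symmetric domain);
9 d.p.f. mean 0.30, sd 0.07, κ = 4 (restricted domain concentrated to
one side). The means sit at the midpoints of the reported 69–82% and
17–43% interquartile bands; the spreads were chosen once so the cohort
quartiles (including counting noise at 25 cells/embryo) fall inside
those bands, as verified by the fidelity tests. κ = 4 gives ~95% bias
power at 25 cells and ~100% at 60 cells, consistent with a clearly
detectable 9 d.p.f. asymmetry. Hypoblast size defaults to 25 cells per
embryo — a plausible scale for cells in contact with the epiblast, but
not anchored to a published count. Fidelity checks use 40-embryo
cohorts: larger than the reported cohorts (10 and 19 embryos) because
the aim is a stable estimate of the generator's marginal distribution,
not a re-enactment of the cohort size.

**What passing tests do and do not show.** The generators emulate
marker-separable lineages, explicit QC failures and hemispherical
geometry with controllable asymmetry. They do not model doublets,
ambient RNA, batch effects, spatial coupling of expression to position,
segmentation error, or non-spherical embryo shapes. Tests passing on
synthetic data therefore validate the pipeline's statistical machinery
and conventions, not its performance on any real dataset.

## Co-expression, partitioning, regulons

Co-expression uses Spearman rank correlation (robust for sparse counts;
Pearson available), two-sided p, BH across the tested panel. A constant
target or panel gene yields NaN rho and q = 1 rather than an error. The
default panel is the ten BMP/NODAL/WNT antagonists of the anterior
program (*LEFTY1/2*, *HHEX*, *NOG*, *DKK4/1*, *SFRP1*, *NCLN*, *CHRD*,
*SOSTDC1*).

Sub-clustering is centred PCA (top 10 components) followed by k-means
(k-means++ with 50 restarts, fixed seed), with the highest-mean-*CER1*
sub-cluster reported as the putative anterior one. This deliberately
replaces graph clustering: it is deterministic and dependency-free, and
is not claimed to replicate any particular clustering stack.

Regulon activity is the AUCell construction: per cell, genes are ranked
by expression descending with lexicographic tie-break for
bit-reproducibility; the recovery curve counts regulon genes within the
top x ranks for x up to `ceil(top_fraction * n_genes)`
(`top_fraction = 0.05`, the conventional window); the area under the
curve divided by its maximum achievable value gives a score in [0, 1],
equal to 1 only when the regulon occupies the best possible ranks and 0
when no target enters the window. The score is invariant to any
monotone rescaling of expression.

BH adjustment is the step-up rule implemented directly (sorted
`p * m / rank`, reverse cumulative minimum, clip at 1) and is checked
exhaustively against the definition on small inputs and against an
independent implementation.

## Group comparisons

Kruskal–Wallis uses the tie-corrected H with a chi-square reference
(k − 1 df); all-identical data returns H = 0, p = 1 by convention.
Dunn's post-hoc z uses pooled mean ranks with the tie term
`sum(t^3 - t) / (12 (N - 1))`, two-sided normal p, and Holm adjustment
across the tested pairs by default (Bonferroni and unadjusted are
options, and the family can be restricted to control-versus-treatment
comparisons) — the named "Dunn's correction" in common software varies
by version, so the method is explicit and configurable rather than
claimed to match any one of them. Quantiles are type-7 (linear
interpolation), the most common software default, stated for
reproducibility.

## Problem sizes

The test suite and acceptance script size their simulations to run on a
single CPU in minutes: the full default count matrix (2000 x 5120) once;
400 null and 200 alternative embryos at 1000–2000 permutations for
calibration and power; 1000 random configurations for the geometry
oracles; 40-embryo cohorts for generator fidelity. These sizes were
chosen so Monte-Carlo error is small relative to every tolerance tested.

## Known limitations

- The bias test is one particular choice of asymmetry statistic; tests
  against a von Mises alternative on the azimuth could be more powerful
  for tightly concentrated domains.
- The epiblast-centroid origin compresses angles near the equator
  relative to an anchor on the proximal epiblast surface; comparisons
  between embryos measured with different anchors are not meaningful.
- The projection model assumes shared normalisation between reference
  and query; no batch correction is attempted.
- Marker-signature annotation requires the canonical markers to be
  present in the matrix; it does not discover novel lineages.
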