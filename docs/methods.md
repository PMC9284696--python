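# Methods

This note documents the statistical model, the sequence-analysis
components, the synthetic benchmark and the numerical choices behind
`cernet`.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Differential-expression screen

Expression values are assumed already normalised and log2-scaled
(features × samples, two groups).  For feature *g* with group sizes
n₁ (case) and n₂ (control), the log2 fold change is the difference of
group means, and the pooled residual variance s²_g has d = n₁+n₂−2
degrees of freedom.  With only five samples per group, per-feature
variances are noisy; we therefore shrink them with the standard
empirical-Bayes hierarchy in which d·s²_g/σ²_g is chi-squared and σ²_g
follows a scaled inverse chi-squared prior (d₀, s₀²).  The prior is
fitted by the method of moments on z_g = log s²_g: after removing the
known chi-squared bias digamma(d/2) − log(d/2), the mean of z identifies
s₀² and the excess of its variance over trigamma(d/2) identifies d₀
through a Newton inversion of the trigamma function.  The posterior
variance s̃²_g = (d₀s₀² + d·s²_g)/(d₀+d) replaces s²_g in the t
statistic, which is referred to a t distribution with d+d₀ df.  Two
degenerate cases are handled explicitly: if the observed log-variance
spread does not exceed trigamma(d/2), the prior is taken as degenerate
(d₀ = ∞) at the geometric mean of the s², which makes the moderated
statistic coincide with the ordinary t when all sample variances are
equal; if some features have exactly zero residual variance they are
floored at the smallest positive observed variance (with a log message),
while an all-zero-variance matrix is an error.  The implementation is
cross-checked in the tests against R/limma's `eBayes` on a shared
fixture (agreement ≈ 1e-14) and against the plain t under equal
variances.

Multiple testing uses Benjamini–Hochberg step-up adjustment (the
conventional FDR procedure of this screening literature), implemented
directly as p·m/rank with a reverse cumulative minimum and verified
against both the textbook formula and `statsmodels`.  Features are
retained iff FDR < 0.05 **and** |log₂FC| > 1, both strict inequalities
read literally from the stated thresholds; retained features carry an
`up`/`down` direction.  Heatmap ordering uses complete-linkage
agglomerative clustering on Euclidean distances over both axes (the
distance is the stated choice; the linkage is ours, with scipy's
deterministic tie rule).

## Co-expression network

All retained circRNA × mRNA pairs are scored with the Pearson
product-moment correlation across all samples pooled (both groups, the
extraction the screen prescribes), and an edge is kept when r > 0.9 —
signed and strict.  A signed threshold discards strongly anti-correlated
pairs; because a case could be made for |r|, an `absolute=True` mode is
provided, but the default follows the literal "r > 0.9" reading.  No
p-value filter is applied at this stage.  The co-expression network is a
separate deliverable and is *not* a required filter for ceRNA triplets;
`require_coexpression=True` intersects the two if desired.

## Binding prediction

The binding stage reimplements the complementarity-scanner family of
miRNA target predictors as a transparent, parameter-complete local
alignment:

* the miRNA is reversed (3′→5′) and aligned against the target (5′→3′),
  so that an alignment column is a putative base pair;
* pair scores: Watson–Crick +5, G:U wobble +1, mismatch −3; affine gaps
  at −8 for the first column of a run and −2 for each further column
  (gap_open/gap_extend as stated for the emulated tool);
* pair scores (never gaps) are multiplied by 2.0 when the miRNA base
  lies in the seed region, positions 2–8 from the 5′ end, reflecting the
  dominant contribution of seed pairing;
* the dynamic programme is the Gotoh three-state local recursion; ties
  break toward the leftmost target interval and, in the traceback,
  toward pair columns.

The per-pair substitution constants and the seed weighting are the
published convention of the emulated scanner (they are not part of the
four stated parameters) and are configurable; every test states the
constants it assumes.  "Score threshold = 80%" is interpreted as 80% of
the miRNA-specific maximal attainable score — the score of a gap-free
perfect complement of the full miRNA under the same weighting — because
the percent sign rules out absolute score units; an absolute-score mode
(`absolute_score_min`) covers the other reading.

Duplex stability is scored with a stacking-only nearest-neighbour model:
the sum, over adjacent paired columns, of RNA/RNA dinucleotide stack
free energies (ΔG°37, kcal/mol) from the Watson–Crick table of Xia et
al. (1998), shipped as a versioned data file and keyed by the
target-strand dinucleotide.  Gaps and mismatches break stacks; an
isolated pair contributes zero; wobble-containing stacks reuse the
Watson–Crick lookup (an acknowledged approximation — the model needs to
be monotone in duplex extent and reproducible, not thermodynamically
complete; loop, initiation and dangling-end terms are deliberately
omitted).  A site is retained when score ≥ 0.8 × max attainable AND
energy ≤ −20 kcal/mol ("−20" is unitless in the source convention;
kcal/mol is the delegated tool's unit).  Multiple sites per pair are
found by re-aligning with previously reported intervals masked; the
pair-level score for network edges is the best site's.

Coordinates are 0-based half-open on the target sense strand; miRNA
positions are 1-based from the 5′ end.

## Network assembly

circRNA–miRNA edges require a retained binding site and opposite DE
directions (a sponge and its miRNA should move oppositely between case
and control).  miRNA–mRNA edges come from an interaction-evidence table
with one boolean flag per source database (five sources, emulating the
aggregated target-prediction databases); a record is usable when at
least one flag is set, and an edge additionally requires both members DE
and in opposite directions.  Triplets are the join of the two layers on
the shared miRNA; by construction every triplet satisfies
circ_direction = mrna_direction ≠ mir_direction, and the `CeRNATriplet`
type enforces the invariant at construction.  Feature ids shared across
RNA classes are rejected rather than guessed.  Exports are SIF and
GraphML with RNA class, direction, log2FC, edge type and score/evidence
attributes, plus a provenance line (version, config hash, seed).

## Enrichment and disease filtering

Network mRNAs are tested per gene set with the one-sided hypergeometric
upper tail P(X ≥ k), computed in log space (gammaln + logsumexp) and
verified against exact rational summation to 1e-10.  The background is
the union of all genes annotated in the collection and all DE-tested
mRNAs — the enrichment population of the emulated web service is
undocumented, and this union is the most defensible desk-scale choice.
Significance is raw p < 0.05, strict, with no multiple-testing
correction at this stage (matching the emulated procedure); the EASE
variant (tail at k−1) is available but off by default because the
service's variant is not stated.  Significant sets are intersected with
a flat disease-pathway id list (the file stands in for a disease-keyword
database query; its schema lets users paste real exports), and triplets
whose mRNA belongs to a flagged set form the disease subnetwork,
exported together with the pathway↔mRNA memberships (the quadripartite
view).

## Validation

Network miRNAs and mRNAs are re-tested in an independent cohort with the
equal-variance Student t (the stated test; Welch is not used), two-sided
(sidedness was unstated; two-sided is the conservative default).  A
feature is *consistent* when the sign of its validation log2FC matches
its training direction and *significant* at p < 0.05.  Features absent
from the validation platform are reported as untested rather than
dropped, so coverage gaps stay visible.  circRNAs receive no validation
profile, mirroring the absence of suitable public circRNA cohorts in the
emulated design.

## Synthetic benchmark

The generator emulates the statistical structure of a matched
three-profile microarray study: 60 circRNAs, 40 miRNAs and 150 mRNAs
over 10 shared samples (5 case, 5 control), log2-scale values with
feature baselines N(8, 2²) and i.i.d. Gaussian noise (sd 0.5 by
default), and 3-vs-3 validation cohorts for miRNA and mRNA regenerated
from the same truth with fresh noise and an independent seed.  Twenty
sponge triplets are planted: the circRNA and mRNA shift by ±3 log2 units
between groups and the miRNA by the same amount oppositely; each triplet
gets an exact reverse-complement 22-nt binding site embedded at a
recorded interval on both its circRNA and its mRNA (120-nt targets), and
an evidence-table record with ≥1 flag.  Five additional independent DE
features per profile, evidence-flagged distractor pairs (30) and
zero-flag distractor pairs (20) make every filter discard something;
gene sets include one disease-flagged set containing the planted mRNAs
and sets absent from the disease list.  Expression is generated directly
on the log2 scale (the pipeline consumes normalised data; no raw
intensity or probe-level simulation), with no batch effects or
correlation structure beyond the planted shifts — so passing benchmarks
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to the dependence structure, outliers or
annotation noise of real microarray data.

miRNA pools are drawn with moderate base composition (G+U within
30–60%, G+C within 25–75%, by rejection sampling).  Real mature miRNAs
sit well inside both bands, and the bounds matter structurally: G and U
each pair two of the four bases, so a G/U-rich miRNA would pair half of
any random sequence and make the decoy cap unenforceable, while an
A-rich miRNA's perfect-complement duplex stacks so weakly that it could
miss the −20 kcal/mol filter.

Decoy control: outside planted intervals, every (target, miRNA) window
is kept at ≤60% pairable positions (well under the 80% weighted score
threshold).  Enforcement mutates matched positions to random non-pairing
bases and drives each violating window a few matches *below* the cap —
clipping exactly to the cap leaves windows at the boundary and
oscillates, because a mutation for one miRNA can re-raise a neighbouring
window for another.  Windows overlapping a planted site are exempt
(their bases are immutable); on fully-decoy targets every window is
enforced, and the binding module is run against decoys in the tests to
confirm that no site survives the score and energy filters.

Effect size and noise were not reported for the emulated datasets; 3.0
log2 units at sd 0.5 represents the strong, clearly separable signals
such small-n microarray screens are powered to find, and is stated here
as the package's study condition, fixed once.

## Problem sizes and determinism

All benchmarks run at the defaults above: ten seeds of the full pipeline
for recovery and validation statistics, 200-feature null matrices for
FDR calibration, and ≤8×10-nt instances for exhaustive alignment
enumeration.  Every random draw flows from a single `numpy` Generator
seeded from the configuration, so identical configs produce
byte-identical artifacts; `scripts/acceptance.py` derives its ten study
seeds from `--seed` via `SeedSequence`.

## Known limitations

* The energy model ignores loops, bulge asymmetry, initiation and
  dangling ends; scores are comparable between sites, not physical
  folding energies.
* The moderated-t hierarchy assumes independent features; planted
  triplet members are in fact correlated with their group labels only,
  so this matches the generator but not necessarily real co-regulation.
* Signed-vs-absolute correlation thresholds and the enrichment
  background are documented choices among defensible alternatives; both
  have config switches.
* The pipeline evaluates circRNA binding sequences only; mRNA-side
  binding is planted by the generator but, as in the emulated procedure,
  the mRNA layer is filtered through the evidence table rather than
  realigned.
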