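# Methods

This note documents the statistical models behind each stage, the
simulation that exercises them, the default parameters and why they were
chosen, and the numerical corner cases. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The generative model

The synthetic cohort mirrors a three-group repeated-sampling design:
6 healthy controls, 9 patients sampled in the acute phase (Sepsis) and
the same 9 patients sampled at recovery, paired one-to-one with their
acute-phase samples.

**Abundances.** Each protein draws a baseline relative abundance from a
lognormal(0, 1) law, shared by all groups and normalised to the simplex.
Effects are planted *before* renormalisation: a fraction (default 10%) of
proteins is multiplied (half) or divided (half) by the fold effect
(default 4) in the disease group, and a further fraction (default 2%) is
zeroed in all but one group (group-exclusive proteins, assigned
round-robin). Renormalisation then slightly perturbs every non-differential
protein — deliberate, because spectral counting is compositional and real
fold-change estimates suffer exactly this distortion.

**Counts.** A sample's spectral counts are one multinomial draw of fixed
depth (default 20,000) with per-protein probability proportional to
abundance × length. Longer proteins yield more peptides and hence more
spectra; dividing by length during NSAF normalisation therefore recovers
the abundance simplex in expectation. Multinomial rather than Poisson
sampling keeps column totals exactly equal to the depth, which makes
conservation testable.

**PSMs.** Every counted spectrum yields one correct-match PSM whose
peptide is a random substring (8–20 residues) of its protein. Incorrect
PSMs are planted on top (default 10% of the final table; the acceptance
benchmarks use 50%) and assigned uniformly over the concatenated
target+decoy database — the target-decoy exchangeability assumption that
incorrect matches hit either half equally. Scores (XCorr, DeltaCN, ZScore)
come from two trivariate normals — correct mean (3.5, 0.35, 8), incorrect
mean (1.5, 0.05, 2), unit covariance — giving visible but imperfect
separation so the discriminant has real work to do; XCorr is floored at 0
and DeltaCN clipped to [0, 1] to keep records in their legal ranges.
Correct-match mass errors are N(0, 1.5 ppm) with a 2% outlier rate
(uniform magnitude in (5, 40] ppm); incorrect matches draw uniform
±40 ppm. A configurable fraction (default 10%) of PSMs is semi-tryptic
(one enzymatic terminus). These score laws are placeholders — the real
distributions depend on instrument and search engine — and are fully
configurable through `ScoreModelConfig`.

**Gene sets.** Collections of (default) 20 sets of 30 members over the
protein universe; planted sets draw half their members from the true
differential proteins, the rest uniformly.

What the generator does *not* emulate: spectra, retention times, isotope
envelopes, peptide-level modifications, shared peptides between homologous
proteins (random sequences make peptides essentially proteotypic), batch
effects, or missing-value structure beyond sampling zeros. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artefact of real LC–MS/MS data.

## Identification

PSMs are split by the number of enzymatically cleaved termini (1 vs 2) and
each subgroup is handled independently end to end; the final list is the
union. The discriminant is a two-class linear discriminant (decoys =
negative class) on the standardized score triple — the Bayes rule under
shared-covariance Gaussian classes — fitted per subgroup with at least 20
PSMs per class (a pooled fallback is opt-in); the model class is pluggable.
The FDR estimate for a score cutoff is (#decoys ≥ cutoff)/(#targets ≥
cutoff); the filter accepts the largest target set whose estimate stays at
or below α (default 1%), handling tied scores as a block. A PSM mapping to
both a target and a decoy protein counts as target. After FDR filtering:
|mass error| must be < 5 ppm; a protein needs ≥ 2 distinct spectra, or a
single spectrum with XCorr ≥ 2. The 5 ppm cut is applied *after* FDR
thresholding (the two orders differ only marginally; the choice is
exposed by calling the operations in either order).

Known property, measured honestly by the acceptance benchmark: the
*uncorrected* decoys/targets estimator combined with maximal-set selection
is slightly anti-conservative — the realized FDP of the accepted set runs
a few percent (relative) above the nominal level, because the chosen
threshold sits at a locally lucky decoy deficit. The +1-corrected
estimator ((decoys+1)/targets) would remove this at the cost of a small
loss of acceptances; the uncorrected form is kept as the default because
it matches the common decoy-counting definition used in this workflow's
lineage.

## Quantification

Parsimony is greedy minimal set cover: repeatedly pick the protein
explaining the most uncovered peptides (ties: more total observed
peptides, then lexicographically smaller accession — deterministic and
order-invariant). Proteins whose peptides are all explained by a chosen
leader join that leader's group; a protein covered only by the *union* of
several leaders joins none (its peptides remain covered). Greedy set cover
can exceed the true minimum; on random instances with realistic sparse
peptide sharing (60% proteotypic, 25%/10%/5% shared by 2/3/4 proteins,
≤ 12 proteins) the discrepancy rate is checked to stay below 5%.

Counting: a PSM contributes one count to the group owning its peptide;
peptides claimed by two or more final groups are excluded from
quantification (and counted in the report) rather than razor-assigned —
the conservative choice. NSAF divides counts by leader length and
renormalises each sample column to 1. Detection uses raw counts: a protein
is detected in a group when it has non-zero counts in ≥ 2 of the group's
samples; *exclusive* additionally requires strictly zero counts in every
sample of all other groups.

## Differential abundance

For proteins detected in both groups: log2FC = log2((mean NSAF_B +
pseudo)/(mean NSAF_A + pseudo)); p from a two-sample t-test on
log2(NSAF + pseudo) per sample — Welch by default (safer under unequal
variances; Student available); q by Benjamini–Hochberg. The pseudo-count
defaults to half the smallest non-zero NSAF in the tested submatrix —
scale-adaptive, and used only to keep logs finite (missing proteins are
handled by the ≥2-replicate inclusion rule, not imputation). Classes:
red (|log2FC| < 1), green (fold change only), orange (both cutoffs but
pooled counts < 6 — the low-abundance stringency filter), blue (all
filters; selected). The original TFold rank-dependent variable fold-change
cutoff is simplified to this fixed cutoff + stringency floor; the fixed
cutoff of 1.0 (2-fold) and floor of 6 pooled spectra are implementer's
defaults, exposed in `TFoldConfig`. Exclusive proteins join the selected
set with a direction but no p-value. Both comparisons are tested unpaired,
mirroring the unpaired t-test lineage of this scheme; a paired mode is a
natural extension but is deliberately not the default.

Degenerate inputs: when both groups are constant, p = 1 if the means
agree and 0 otherwise (the t statistic is 0/0 there and is resolved
explicitly).

## Perturbation scoring

Per-protein z-scores use the control mean and SD (ddof = 1); SDs below
ε = 1e-6 × the median positive control SD are floored so every z is
finite. Rows are restricted to proteins quantified (non-zero) in ≥ 2
control samples — z-scores of proteins never seen in controls are
uninterpretable and would otherwise explode through the ε floor. A
sample's MDP is the mean of its top ⌈0.25·n⌉ absolute z-scores; |z| is
used because perturbation is directionless in this framework (a signed
mode exists). Control samples are scored leave-one-out against the other
controls to avoid an optimistic zero bias. Group comparison: Wilcoxon
signed-rank on the paired Sepsis/Recovery scores (zero differences
dropped; all-zero ⇒ p = 1), rank-sum for unpaired use; which pairs enter
the test is configurable because a three-group plot admits several
comparisons.

## Enrichment and clustering

ORA: p = P(X ≥ k) for X ~ Hypergeometric(N, K, n) with the universe set
to the proteins quantified in the comparison under test (tested ∪
exclusive) — the standard practice when the annotation tool's internal
universe is unknowable; sets are intersected with the universe first and
empty intersections skipped (reported). scipy's log-gamma-based tail is
used, checked against exhaustive enumeration. BH across all tested sets.

Clustering: rows optionally z-scored (zero-variance rows → 0), pairwise
Euclidean distances, agglomerative merging with average linkage (the
distance is fixed by the workflow; the linkage is a package default, with
single/complete available); output is leaf orders plus the merge trees,
JSON- and Newick-exportable.

## Pipeline, seeds and problem sizes

The master seed derives one seed per stage by hashing (seed, stage name),
so any stage can be re-run in isolation and a fixed (config, seed) pair
reproduces every artifact byte for byte; the report bundle carries
per-stage counts, internal-consistency checks (Venn cells sum to the
detected total; up + down = selected) and a SHA-256 manifest of all
written files.

Default study conditions: 1,000 proteins (mean length 300), depth 20,000,
6/9/9 design, 10% differential at 4-fold, 2% exclusive, 20 gene sets of
30 with 3 planted. The benchmark sizes — 200 tables of 5,000 PSMs for the
decoy-FDR check, 200 null replicates for the differential FDP check, 50
full-pipeline replicates for parameter recovery, 500 replicates for the
MDP separation checks — were chosen to put Monte-Carlo error well below
the margins being tested while keeping the whole suite comfortably
runnable on a laptop.

## Known limitations

- Random-sequence databases make peptides nearly proteotypic, so the
  parsimony and ambiguous-peptide machinery is exercised mainly by
  dedicated small fixtures rather than by the end-to-end simulation.
- Spectral counts at depth 20,000 leave low-abundance proteins with
  single-digit counts, where the t-test on log NSAF is conservative; the
  pooled-count stringency filter exists precisely for that regime.
- The decoy-FDR filter's small anti-conservative bias (see above) is a
  property of the uncorrected estimator, not of the implementation.
- MDP values depend on the control-group size through the leave-one-out
  reference; with very few controls the self-MDP is noticeably inflated.
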