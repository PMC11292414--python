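# Methods

## Karyotype parsing

The parser supports a pragmatic subset of ISCN notation — the feature
families that vendor and literature karyotypes actually report for cancer
cell lines: modal chromosome count or range, sex-chromosome complement,
per-chromosome gains (`+7`) and losses (`-22`), structural events
(`add`/`del`/`dup`/`i`/`der`/`t`, band annotations accepted and ignored),
marker chromosomes (`2~7mar`), double minutes (`8~100dmin`, bare `dmin`,
explicit `no dmin`), HSRs (`2hsr`, `no hsr`), percent polyploidy
(`12.5% polyploidy`) and composite-karyotype brackets (`[cp20]`, counted
but otherwise ignored). Full ISCN 2020 — band-level breakpoints,
multi-clone nomenclature, idic/ins/r/trc constructs — is out of scope;
such tokens are counted in `unparsed_token_count` and logged, never
silently dropped, so record completeness remains auditable.

Canonicalisation rules: count ranges are written `a~b` (or `a-b`); a bare
count `c` maps to the degenerate range `(c, c)`; token presence without a
count maps to `(1, 1)`. A range with high < low is a parse error naming the
token. Ploidy class, when not stated, is derived from the modal midpoint
with bands centred on multiples of 23: <35 near-haploid, 35–57 near-diploid,
58–80 near-triploid, 81–103 near-tetraploid, >103 hyperploid.

**Confidence scoring (0–3).** 3 whenever the record contains direct
dmin/HSR language, including explicit negation — a definitive "no dmin" is
as informative as a positive sighting; 2 for a detailed record without such
language (≥3 populated feature families, configurable); 1 for minimal
detail; 0 for no record. Labels follow from confidence: positive requires
the token; negative requires confidence ≥2 (detailed silence, or explicit
negation); everything else stays unknown, so low-detail records are never
treated as evidence of absence.

**Record precedence.** When one cell line has several records, any record
mentioning double minutes wins outright; otherwise the highest-confidence
record, with deterministic ties (literature > vendor > registry, then
lexicographic validation source). Multi-clone heterogeneity is not
resolved; the selected record represents the line.

**Metaphase pathology standard.** A sample is ecDNA+ iff ≥`min_count` (2)
ecDNA are seen in ≥`min_images` (2) of the metaphase images. The rule is
monotone in added evidence by construction.

## Feature engineering

Profiles expand into a fixed 237-column schema (versioned in
`src/karyoamp/data/feature_schema.yaml`): 45 scalar features — modal
number/range (min, max, midpoint, width), percent polyploidy, a six-class
ploidy one-hot, sex-complement encodings, marker and dmin range triplets,
HSR count, event-type totals, aggregate burden scores — plus eight
per-chromosome families (gain, loss, derivative, translocation, add, del,
dup, iso) over chromosomes 1–22, X, Y. Count ranges always expand to
(min, max, midpoint). Missing numerics (e.g. a record reporting only a
modal range leaves the point estimate empty) are imputed with the mean of
the sample's ploidy class, falling back to the global mean for empty
classes; a column missing everywhere is an error.

## Classifiers

Scaling is z-score standardisation fitted on training rows only (a
deliberate choice — "uniform scaling" admits several readings; this one is
recorded in the pipeline so results are reproducible; it is a no-op for the
tree ensembles, verified by an invariance test). Splits are 80/20,
stratified on the joint label to keep minority classes represented, and
seed-reproducible. Estimators are scikit-learn with library-default
hyperparameters and a fixed seed (overridable): decision tree, SVM, random
forest, gradient boosting, bagging and stacking for the binary ecDNA
target; multi-output random forest / gradient boosting for joint ecDNA+HSR
prediction. ROC-AUC is computed as the rank statistic over predicted
positive-class scores; F1 and AUC are reported per target, accuracy as
exact-match over targets, and MCC averaged over targets for multi-output
fits. Feature importances come from the tree ensembles, normalised to sum
to one. Were external registry records with "probable" positive labels
merged in, they would be used for training only and excluded from
evaluation, keeping held-out labels unambiguous.

Per-feature separation between label groups uses a two-sided Mann–Whitney
U test: exact null distribution for combined n ≤ 20 without ties, normal
approximation with tie correction otherwise; an all-constant input returns
p = 1 by convention.

## Quadrants and the Q statistic

Quadrants use strict thresholds (CNV > 3 log2 units relative to ploidy,
RNA > 7 log2(TPM+1)); boundary points fall to the lower quadrant, and the
Cartesian convention is I = high/high, II = low/high, III = low/low,
IV = high/low. An *island gene* has ≥`min_cells` (3) lines in quadrant I
while the population median of both axes sits in quadrant III.

Q^CNV contrasts a copy-number value against a high population percentile,
P_k = 99.9 (used for both the per-gene and per-cell variants; configurable),
computed with linear interpolation. The denominator counts entities at or
above that percentile — cell lines within the gene for Q^CNV(gene), genes
within the cell line for Q^CNV(cell) — and a zero denominator flags the
score as undefined (NaN) rather than zero-filling. Because the percentile
interpolates between the top two order statistics, a positive score singles
out the entity that is the unique extreme — precisely the signature of a
focal extrachromosomal amplification in one line.

**Integrative call.** A cell line is predicted ecDNA+ iff all four hold:
max Q^CNV(gene) over its genes > μ+1σ, max Q^CNV(cell) > μ+1σ, at least one
gene in quadrant I, and at least one external circular-DNA caller flags it
(AmpliconArchitect OR CircleHunter, consumed as a boolean table — the tools
themselves are never executed). μ and σ are computed over the defined
per-cell maxima by default (`stat_scope="pairs"` switches to all defined
(gene, cell) scores); the per-cell maximum is the right reduction because
the criterion asks whether a line harbours *any* extreme amplicon. Lines
without an external-flag entry are reported not-evaluable, never silently
negative. The combination is a strict conjunction; the predictor is monotone
in evidence.

Confusion metrics follow the standard formulas; MCC returns 0 when any
marginal is zero (common convention). The chromothripsis comparison is a
pure overlap: 100·|predicted ∩ aberrant|/|predicted| over chromosome sets.

## Power analysis

Cohen's h = |2·arcsin√p₁ − 2·arcsin√p₂| (symmetric; range [0, π]). The
per-group sample size solves the two-sided two-independent-sample normal
test on the arcsine scale: starting from ceil(2·(z₁₋α/₂ + z_power)²/h²)
and adjusting ±1 against the exact two-sided power function so the returned
n is minimal (achieved power ≥ requested at n, < requested at n−1). "Power"
here is 1−β = 0.80 at two-sided α = 0.05 in the reference configuration.

## Synthetic-data generators

All generators are driven by `numpy.random.default_rng(seed)` and return
ground truth constructed from the sampled parameters themselves — never by
calling the code under test — so every downstream operation can be scored
independently.

**Karyotypes.** Defaults: ecDNA prevalence 0.30, HSR prevalence 0.15, mean
aberration load 6 events/record (scaled ×1.6 for ecDNA+ lines), 10% of
records minimal (modal number only — these hide the dmin token from the
parser, making the underlying status deliberately unrecoverable from
direct language), 5% of negative records carrying an explicit "no dmin".
ecDNA+ lines skew toward ≥3N ploidy, mirroring the cytogenetic observation
that polyploidy accompanies extrachromosomal amplification. Records render
through the same grammar the parser supports, optionally salted with
realistic unsupported tokens (`r(7)`, `ins(...)`, `inc`, ...) at
`malformed_rate` to exercise the unparsed-token accounting; round-trip
tests require exact field recovery.

**Omics matrices.** 300 genes × 120 cell lines, 12 positives. Background
CNV ~ N(0, 0.5) with RNA = 2 + 1.5·CNV + N(0, 0.8) (linear coupling on the
log scales — the simplest model producing the island motif), clipped at 0.
Positive lines amplify a shared 5-gene recurrent amplicon
(CNV ~ N(5, 0.6)) plus one private passenger gene drawn 4 log2 units
hotter — real ecDNA+ lines co-amplify recurrent oncogenes with private
segments, and the private extreme is what the Q statistic's
top-order-percentile construction detects. Amplicon draws are truncated
above the quadrant thresholds (CNV > 3.2, RNA > 7.2), so planted points are
quadrant-I points by construction; island recovery and integrative
sensitivity are therefore properties of the analysis code, not of
threshold luck. What this generator does **not** emulate: segment-level
correlation along chromosomes, ploidy-driven baseline shifts, expression
saturation, HSR-vs-ecDNA disambiguation from omics alone — so passing
tests demonstrate correctness of the statistics and plumbing, not expected
performance on real CCLE/DepMap matrices.

**Metaphase panels.** Positive panels draw ≥2 images with counts ≥2 over a
0/1 background; negatives allow at most one high image. The classifier
recovers truth exactly because generator and classifier share the rule —
these panels test the rule's implementation, nothing more.

## Numerical and scale choices

Percentiles use numpy's linear interpolation (tests verify against an
explicit sort-and-interpolate oracle to 1e-9). Tree-ensemble determinism is
pinned by the seed threaded through every estimator. Test problem sizes —
800 synthetic karyotypes for classifier recovery, 50×50 matrices for the Q
oracle, 10,000 replicates for the Mann–Whitney type-I check — were chosen
to make sampling noise small relative to the margins being asserted while
keeping the default suite fast.

## Known limitations

Real vendor karyotypes deviate from the supported grammar more creatively
than the malformed-token pool does; the parser's unparsed count makes this
visible but does not fix it. The 237-column schema is this package's
reconstruction of the stated feature families, not a published standard.
The integrative predictor's strict conjunction is pluggable but the default;
a weighted combination may behave differently on real data. Counting
utilities (`karyoamp.io.summarize_annotations`) reproduce published cohort
tallies only when pointed at the externally distributed curated table,
which is not redistributable here.
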