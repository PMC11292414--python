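# karyoamp

Karyotype mining and multi-omic integration for classifying extrachromosomal
DNA (ecDNA) and homogeneously staining regions (HSRs) in cancer cell lines.

## The problem

ecDNA — circular DNA elements outside the chromosomes, visible in metaphase
spreads as *double minutes* (dmin) — carry amplified oncogenes and drive
tumour heterogeneity and drug resistance, yet only a small fraction of the
commonly used cancer cell lines have ever been tested for it. Decades of
cytogenetic observations sit in unstructured karyotype text (ISCN notation)
scattered across vendor catalogues and the literature. This package turns
that text, plus paired copy-number/expression matrices, into ecDNA/HSR calls:

1. **Karyotype mining** (`karyoamp.karyotype`) — parse ISCN-like strings
   (e.g. `"62~68,XXY,8~100dmin,2~7mar"`) into structured cytogenetic
   profiles; score record confidence 0–3 (3 = direct dmin/HSR language);
   assign positive / negative / unknown labels, with silence in a sketchy
   record never counted as absence; apply the metaphase pathology standard
   (ecDNA+ iff ≥2 ecDNA in ≥2 of 20 images).
2. **Feature engineering & prediction** (`karyoamp.features`,
   `karyoamp.model`) — expand profiles into a 237-column numeric feature
   table (ploidy one-hots, per-chromosome gain/loss/derivative/translocation
   families, marker and dmin/HSR summaries), impute by ploidy class, and fit
   random-forest / gradient-boosting classifiers (binary ecDNA, or joint
   ecDNA+HSR multi-output) with an 80/20 stratified split and ROC-AUC
   evaluation; Mann–Whitney U tests quantify per-feature separation.
3. **CNV × RNA integration** (`karyoamp.omics`) — quadrant clustering of
   per-gene copy number (log2 relative to ploidy, threshold > 3) versus
   expression (log2(TPM+1), threshold > 7); the island-motif search; the
   Q^CNV statistic

   Q^CNV(gene) = (CNV_i − CNV at the gene's P_k-th percentile across cell
   lines) / #cell lines at/above that percentile,  P_k = 99.9,

   with a mirrored per-cell variant across genes; and an integrative
   predictor that calls a line ecDNA+ iff both Q statistics exceed μ+1σ,
   it has a quadrant-I gene, and an external circular-DNA caller
   (AmpliconArchitect / CircleHunter, consumed as boolean flags) agrees.
4. **Power analysis** (`karyoamp.power`) — Cohen's h = |2·arcsin√p₁ −
   2·arcsin√p₂| and the two-sided two-sample n per group.
5. **Synthetic data** (`karyoamp.simulate`) — seeded generators for
   karyotype records, metaphase panels and island-motif omics matrices,
   each returning ground truth, so the whole pipeline is testable without
   external data.

## Worked example

```python
import karyoamp as ka
from karyoamp.simulate import KaryotypeSimConfig, gen_karyotype_records
from karyoamp.features import engineer_features, impute_by_ploidy
from karyoamp.model import KaryotypeAmplificationModel

records, truth, _ = gen_karyotype_records(KaryotypeSimConfig(n_samples=800, seed=7))
profiles = [ka.parse_karyotype(r.raw_text) for r in records]
table = impute_by_ploidy(engineer_features(
    profiles, [r.cell_line_id for r in records],
    ecdna=truth["ecdna_true"].tolist(), hsr=truth["hsr_true"].tolist()))
print(KaryotypeAmplificationModel(table, algorithm="random_forest").fit(seed=7).summary())
```

```
Karyotype amplification model
=============================
algorithm:        random_forest
targets:          ecdna
seed:             7
train / test n:   640 / 160
accuracy:         0.963
MCC:              0.915
AUC[ecdna]:        0.992   F1[ecdna]: 0.942
top features:
  dmin_present             0.2063
  dmin_min                 0.1475
  ...
```

The held-out AUC of 0.99 says the classifier ranks ecDNA+ lines above
ecDNA− lines almost perfectly on this synthetic cohort; the double-minute
feature family dominating the importances is the expected signature, since
dmin observations are the direct cytogenetic evidence of ecDNA. The
integrative omics route works the same way:

```python
from karyoamp.simulate import OmicsSimConfig, gen_omics
m, pos, _ = gen_omics(OmicsSimConfig(seed=5))
res = ka.IntegrativeEcdnaModel(m, {c: (c in pos) for c in m.cells}).fit()
print(res.summary())          # 12 of 120 lines predicted ecDNA+
print(res.positive_cells)     # exactly the planted positive lines here
```

A single karyotype string, and the power analysis:

```python
>>> p = ka.parse_karyotype("62~68,XXY,8~100dmin,2~7mar")
>>> p.modal_range, p.dmin_range, p.marker_range, p.ploidy_class
((62, 68), (8, 100), (2, 7), 'near-triploid')
>>> round(ka.cohens_h(0.4, 0.6), 3), ka.required_sample_size(0.403)
(0.403, 97)
```

So distinguishing a 40% from a 60% ecDNA-positive proportion (a medium
effect, h = 0.403) at α = 0.05 and 80% power needs 97 true-positive and 97
true-negative lines per group.

A `karyoamp` CLI wraps the same functionality (`parse`, `label`, `train`,
`qscore`, `quadrants`, `integrate`, `confusion`, `power`,
`simulate karyotypes|omics|metaphase`).

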