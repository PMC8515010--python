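# digitalmarker

Screening whole-transcriptome profiles into small "digital markers" —
short, cancer-type- and drug-specific gene lists whose joint expression
predicts chemo-drug sensitivity — and using them for rapid prediction
from either RNA-seq TPM or qRT-PCR ΔCq input.

Most chemotherapies are chosen empirically because tumors rarely carry
an actionable biomarker, yet transcription levels do carry predictive
signal.  RNA sequencing is too slow for treatment decisions made at
hospitalization; a panel of tens of genes, however, can be quantified by
qRT-PCR within hours of tumor sampling.  This package implements the
computational side of that workflow, for bioinformaticians building
drug-sensitivity panels from pharmacogenomic cohorts (GDSC/CCLE-style
cell lines with IC50 values, TCGA-style patients with treatment
outcomes) and for anyone who wants to score new samples against a
frozen marker.

## The model

For one cancer type and drug, genes are screened in up to three steps:

1. **Expression filter** — keep genes with mean log₁₀(1+TPM) > 1
   (cell lines) or mean log₁₀(TPM) > 0 (patients), strictly.
2. **Correlation filter** (cell lines) — keep genes with Pearson
   |r| > 0.25 between TPM and the Z-scores of log IC50.
3. **Score and rank** — cell lines: the univariate Fisher linear
   discriminant |μ₁−μ₂|/√(s₁²+s₂²) of log₁₀(1+TPM) between the lowest
   and highest 15% of IC50; patients: −log₁₀ p of a two-sided
   Mann–Whitney U test between outcome groups.  Paired cohorts are
   screened separately and their per-gene scores added.

The marker itself is a prefix of this ranking: its length m (≤ 30) and
the KNN neighbor count k are chosen jointly by stratified 5-fold
cross-validation, maximizing mean AUC.  Prediction is KNN regression of
the IC50 Z-score (cell-line training data) or KNN classification of
ineffectiveness probability (patient training data) in standardized
log₁₀(1+TPM) space.  qPCR input is converted through the calibration
log₁₀(TPM+1) = −0.3995·ΔCq + 5.6974 (refittable via ordinary least
squares), and per-drug calls use the relative Z of predicted log IC50:
below −1 sensitive, above +1 non-sensitive, otherwise neutral.

See `docs/methods.md` for assumptions, defaults, leakage control
(`nested_cv_auc`) and known limitations.

## Worked example

Everything runs offline: the `simulate` command generates a paired
cell-line cohort with 8 planted sensitivity-associated genes among 400.

```sh
digitalmarker simulate --out-dir . --seed 4 --n-genes 400 --n-signal-genes 8
digitalmarker screen --expr-a expression_a.tsv --resp-a response_a.tsv \
    --expr-b expression_b.tsv --resp-b response_b.tsv \
    --drug drugX --out scores.tsv
digitalmarker select --expr expression_a.tsv --resp response_a.tsv \
    --scores scores.tsv --drug drugX --seed 1 --out marker.json
digitalmarker predict --marker marker.json --input expression_a.tsv \
    --cohort-ic50 response_a.tsv --out-prefix pred
```

which prints

```
ranked 9 genes -> scores.tsv
selected m0=5, k0=28, cv_auc=1.000 -> marker.json
wrote pred.tsv and pred.json
```

Only 9 of 400 genes survive both datasets' filters — the screen is
aggressive by design — and the ranked table shows each gene's
per-dataset Fisher scores and their sum:

```
gene    score_a             score_b             score_combined      rank
G349    4.534626993939362   3.0365267183521234  7.571153712291485   1
G389    2.5767935553298136  3.8583086804432276  6.435102235773041   2
G372    2.497973662599385   3.5985679896796166  6.096541652279002   3
```

Cross-validation picks a 5-gene marker with 28 neighbors at CV AUC
1.000 (the planted signal is strong).  `pred.tsv` then scores samples:
the `predicted` column is the KNN-regressed IC50 Z-score, and `call`
is the relative-Z recommendation — here the first samples sit within
one SD of the cohort, so the drug is called neutral for them:

```
sample  predicted             relative_z            call     color
A001    -0.3207646396641564   -0.32076463966415647  neutral  black
A002    -0.573599338522718    -0.573599338522718    neutral  black
```

A qPCR readout is scored the same way with
`--input-kind cq` (the table must include the reference gene, GAPDH by
default); with noiseless Cq values the prediction is identical to the
TPM path.  The same API is available in Python:

```python
import digitalmarker as dm
pair, truth = dm.generate_cell_line_pair(dm.GeneratorConfig(seed=4))
table = dm.screen_cell_line_pair(pair)
marker = dm.select_digital_marker(list(table.index),
                                  pair.expression_a, pair.response_a, seed=1)
```

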