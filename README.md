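# lipidmrm

Flow-injection MRM-profiling lipidomics for two-group biomarker discovery:
scan design, total-ion-normalized targeted screening, exact-mass lipid
attribution, discriminant statistics, and ROC-validated biomarker panels —
with a seed-reproducible synthetic-data generator built around the study
design of a mouse dermatitis model (SHARPIN-deficient *cpdm* vs wild-type
epidermis).

## Who this is for

MRM-profiling screens hundreds of lipid transitions (Q1 → Q3 ion pairs) per
sample by flow injection on a triple-quadrupole instrument, without
chromatography: discovery runs class-supervised precursor-ion and
neutral-loss scans (e.g. Prec *m/z* 184 for phosphocholines, Prec *m/z*
264.3 for sphingosine ceramides, NL 141 for PE), and screening monitors the
detected transitions in two fast polarity-split methods. This package is
for analysts who want that workflow as tested, scriptable code: method
tables in, labeled feature matrices, attributions, statistics and panel
classifications out.

## The core quantities

* **Relative amounts.** Each transition intensity is divided by the total
  ion intensity of all transitions in its method for that sample, so a
  sample is a composition summing to 1.
* **Attribution by mass arithmetic.** A transition's Q3 names its class
  (sphingoid-base fragments at *m/z* 264.27 / 266.28 / 282.28,
  phosphocholine at 184.07, ...); candidate species are enumerated over a
  bounded chain grid and kept when the expected precursor m/z — for example
  Cer = base + fatty acid − H₂O, as [M+H]⁺ or the in-source dehydrated
  [M+H−H₂O]⁺ — matches the Q1 set-point within ±0.5 Da.
* **Discriminant statistics.** Per-transition unpaired t-tests with
  step-down Holm–Šidák control at α = 5 %, volcano selection (p ≤ 0.05 and
  ≥ 2-fold change), autoscaled PCA and Ward clustering.
* **Biomarker panels.** Univariate AUC from the Mann–Whitney rank
  statistic; PLS-DA (or random-forest) panels trained on the testing split,
  Monte-Carlo cross-validated, then applied blind to the validation split.

## Worked example

```python
from lipidmrm.scan_library import synthetic_screening_methods
from lipidmrm.synthetic_data import CohortConfig, generate_cohort
from lipidmrm.ingest import assemble_matrix, profiles_from_table
from lipidmrm.biomarker_roc import CvConfig, fit_panel, predict_validation
from lipidmrm.reference import CERAMIDE_PANEL

method_pos, _ = synthetic_screening_methods()          # 217 transitions (+)
table = generate_cohort(CohortConfig(seed=7), method_pos)
matrix = assemble_matrix(profiles_from_table(table, method_pos))

model, cv_auc, cv_acc = fit_panel(matrix, CERAMIDE_PANEL, cv=CvConfig(seed=7))
pred = predict_validation(model, matrix)
print(f"CV AUC {cv_auc:.2f}, CV accuracy {cv_acc:.2f}, "
      f"validation accuracy {pred.accuracy:.2f}")
```

prints

```
CV AUC 1.00, CV accuracy 1.00, validation accuracy 1.00
```

i.e. the three-ceramide panel (CerAS(d18:1/24:0)2OH, CerAS(d18:1/16:0)2OH,
CerNS(d18:1/16:0); transitions 666.35→264.1, 554.2→264.1, 538.3→264.1)
separates the groups perfectly on a cohort simulated at the study's design:
8 WT + 7 cpdm testing mice, 11 WT + 10 cpdm blind validation mice, the
published fold changes, 20 % within-group CV.

The same workflow is available from a shell:

```sh
lipids method build --out-dir methods/
lipids simulate cohort --seed 7 --out cohort.csv
lipids ingest cohort.csv --method methods/method_pos.tsv --out matrix.csv
lipids attribute --method methods/method_pos.tsv --out attributions.tsv
lipids run config.yaml         # full simulate→ingest→stats→ROC→quant bundle
```

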