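# lungstage

Rule-based clinical TNM (8th edition) staging of non-small cell lung
cancer (NSCLC) from structured radiology reports, with the evaluation
machinery needed to compare structured reporting (SR) against free-text
reporting (FTR) in multi-reader studies.

## Who this is for

Radiology and clinical-informatics groups building or validating
structured-reporting templates for NSCLC staging.  Instead of asking a
radiologist to synthesize a TNM code in their head, the reporter
itemizes findings — primary-tumor size and local invasion, lymph nodes
by IASLC station and side, distant disease by site — and a
deterministic rule engine derives the TNM categories and the UICC
stage group.  The package also ships the analysis layer for validating
such a tool against a reference standard: correctness scoring,
up-/down-staging, error-source attribution, inter-reader agreement,
and a mixed-effects comparison of reporting methods.

## What the engine computes

For a structured report with primary tumor, separate nodules, nodal
and metastatic findings:

* **T** — max rule over the size bin of the maximum multiplanar
  diameter (≤1 T1a, (1,2] T1b, (2,3] T1c, (3,4] T2a, (4,5] T2b,
  (5,7] T3, >7 cm T4), the floors attached to invasion descriptors
  (visceral pleura/main bronchus/atelectasis ⇒ at least T2a; chest
  wall, parietal pleura, phrenic nerve, parietal pericardium ⇒ T3;
  mediastinal/great-vessel/vertebral invasion ⇒ T4), T3 for a separate
  nodule in the same lobe and T4 for one in another ipsilateral lobe.
* **N** — max IASLC regionality over malignant nodes: ipsilateral
  stations 10–14 ⇒ N1, ipsilateral mediastinal stations and the
  subcarinal station 7 ⇒ N2, contralateral or station 1
  (supraclavicular zone) ⇒ N3.  Nodes outside the IASLC map
  (axillary, abdominal, …) are *not* regional: they route to M.
* **M** — M1a for intrathoracic dissemination (contralateral-lobe
  nodule, pleural/pericardial nodules or malignant effusion), M1b for
  a single extrathoracic lesion, M1c for more than one.
* **UICC stage group** — the 8th-edition grouping table (IA1 … IVB),
  with occult carcinoma for TX N0 M0 and an explicit `undefined` for
  ungroupable input (e.g. NX).

The evaluation layer scores documented TNM codes against a reference
(invalid codes such as `T2` — missing subcategory — or `M2` —
nonexistent — are data, flagged as documentation errors), tallies
staging direction on stage-group ordinals, computes Fleiss kappa, and
fits a logistic GLMM for per-category correctness with fixed effects
for method (SR vs FTR) and category (T/N vs M) and crossed random
intercepts for case and reader (Laplace maximum likelihood, validated
against lme4).  Latent-scale ICCs use the logistic residual variance
π²/3:  ICC_g = σ²_g / (Σ σ² + π²/3).

## Worked example

```python
from lungstage import (StructuredReport, PrimaryTumorFinding, NodalFinding,
                       LungLobe, Side, classify_report, uicc_stage, format_tnm)

report = StructuredReport(
    case_id="example-01",
    primary=PrimaryTumorFinding(lobe=LungLobe.RUL, diameter_cm=2.5),
    nodes=(NodalFinding(station="axillary", side=Side.RIGHT, judged_malignant=True),),
)
c = classify_report(report)
print(format_tnm(c), uicc_stage(c).value)
```

prints

```
T1c N0 M1b IVA
```

— a 2.5 cm right-upper-lobe tumor is T1c by size; the malignant right
axillary node is **not** in the IASLC nodal map, so it contributes
nothing to N (N0) and instead counts as a single extrathoracic
metastasis (M1b), giving stage IVA.  Misreading such a node as
regional (N3) is exactly the class of error the engine prevents.

The same flows are scriptable from the shell:

```sh
lungstage classify report.json          # report JSON -> TNM + stage JSON
lungstage validate "T2 N0 M0"           # exit 1: missing subcategory
lungstage simulate --seed 3 --out-dir sim/
lungstage evaluate sim/reader_study.csv
```

`lungstage simulate` generates a fully labeled synthetic cohort
(default: 20 cases split 4/3/6/7 over UICC groups I–IV) and a
nine-reader two-method study with configurable error channels (size
mismeasurement, infiltration-descriptor error, anatomic
mislocalization, documentation corruption); `lungstage evaluate`
scores any reader-study CSV and fits the correctness GLMM.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

exercises the full pipeline (simulate → score → summarize → GLMM) and
recomputes the latent-scale variance decomposition of classification
accuracy from the published random-intercept variance components
(patient/image and reader), writing the patient/image ICC and the
reader variance share to the JSON file given by `--out`.

## Layout

| module | contents |
| --- | --- |
| `lungstage.findings` | typed findings model (enums, reports, TNM, stages) |
| `lungstage.nodal_map` | IASLC station table (auditable TSV) + regionality resolution |
| `lungstage.engine` | T/N/M rules, stage grouping, code parsing, staging direction |
| `lungstage.evaluation` | scoring, summaries, error attribution, kappa, Sidak, ICC |
| `lungstage.glmm` | `ReaderCorrectnessModel` / `ReaderCorrectnessResults` (Laplace ML) |
| `lungstage.simulate` | synthetic cohorts and imperfect-reader simulation |
| `lungstage.io` | JSON report schema, reader-study CSV, text rendering |
| `lungstage.cli` | `lungstage` command-line tool |

See `docs/methods.md` for the model assumptions, numerical choices,
and what the synthetic world does and does not establish.
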