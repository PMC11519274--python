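# Methods

This note documents the scientific content of `lungstage`: the staging
rules it encodes, the statistical models in the evaluation layer, the
generative model behind the synthetic cohorts, and the numerical and
design choices made where more than one defensible option existed.

## 1. Staging rules

### T category

T is a *max rule* over independent contributing floors:

1. the size bin of the maximum multiplanar diameter in cm
   (left-open/right-closed: ≤1 → T1a, (1,2] → T1b, (2,3] → T1c,
   (3,4] → T2a, (4,5] → T2b, (5,7] → T3, >7 → T4);
2. descriptor floors — visceral pleural invasion, main-bronchus
   involvement, and atelectasis/obstructive pneumonitis floor T at
   T2a; chest wall, parietal pleura, phrenic nerve, and parietal
   pericardium at T3; mediastinal structures (heart, great vessels,
   trachea, carina, recurrent laryngeal nerve, esophagus, vertebral
   body, diaphragm) at T4;
3. separate tumor nodules: same lobe → T3, different ipsilateral lobe
   → T4; a contralateral nodule does not touch T at all — it routes to
   M1a.

Choices worth making explicit:

* **Diameter is the maximum over all reconstruction planes**, not the
  axial diameter.  Axial-only measurement systematically truncates
  oblique tumors (a 4.9 cm tumor read as 3.9 cm axially drops a full T
  subcategory, T2b → T2a).
* **The "at least T2" floor resolves to T2a, never T2b.**  Size alone
  separates T2a from T2b; a 0.9 cm tumor with main-bronchus
  involvement is T2a.
* **Pleural contact is not a descriptor.**  The reporter must assert
  visceral pleural *invasion*; the engine never infers invasion from
  contact, because that judgment is exactly the human part of the
  semi-automated contract.
* A non-measurable primary yields TX; Tis/T1mi are representable for
  completeness but no staging cohort path emits them.

### N category

Each malignant nodal finding is resolved against a versioned,
human-auditable station table (`data/iaslc_stations.tsv`):
ipsilateral stations 10–14 are N1; ipsilateral stations 2–4, 8, 9 and
the midline station 7 are N2; station 1 and all contralateral
involvement are N3.  Stations 5/6 are anatomically left-sided: they
count as ipsilateral mediastinal (N2) only for a left-sided primary.
N is the max rank over findings; benign-judged nodes are inert.
Tokens outside the map (axillary, abdominal, inguinal, internal
mammary, diaphragmatic, retroperitoneal, cervical) are *extrathoracic*:
excluded from N and routed to M.  Unknown tokens are rejected rather
than guessed.  Station 3 must be recorded left or right (midline
recording is rejected to force a choice); station 7 must be midline.

### M category

Ordered test: more than one extrathoracic lesion in total — any mix of
organs, lesion counts summed, each extrathoracic node counting one —
is M1c; exactly one extrathoracic lesion is M1b; otherwise any
intrathoracic distant event (contralateral-lobe nodule, pleural
nodule, malignant pleural/pericardial effusion) is M1a; else M0.
Two lesions in a *single* organ are deliberately M1c: "single
extrathoracic metastasis" is read as one lesion, not one organ.

### Stage grouping and staging direction

The 8th-edition grouping table maps every fully specified tuple
(T1a–T4 × N0–N3 × M0–M1c) to IA1 … IVB; M1c forces IVB and M1a/M1b
force IVA regardless of T and N.  TX N0 M0 is the occult-carcinoma
group; NX, or TX with nodal disease, cannot be grouped and yields an
explicit `undefined` (callers must not rank it).

Reader-vs-reference comparison works on stage-group ordinals:
`upstaged`/`downstaged` when the ordinals differ, `concordant` when
the tuples are identical, and `lateral` when the ordinals tie but the
tuples differ (an error without prognostic direction — counting it as
either direction would bias the tallies).

### TNM code parsing

Documented codes are parsed tolerantly (case-insensitive, separators
optional, `T2bN1M0` accepted) and validity is *data*, never an
exception: `T1`/`T2`/`M1` are flagged `missing_subcategory`,
`T5`/`N4`/`M2` `nonexistent_code`, anything else `unparseable`.  A
category letter embedded in a word ("reco**m**mended") is not a code.

## 2. Evaluation layer

**Scoring.**  Each reading is compared per category and in aggregate.
Invalid reported codes score incorrect for the offending categories
and are documentation errors; so are valid codes whose stage group is
undefined.  Neither has a staging direction, so the direction tally
carries five buckets (concordant / up / down / lateral / undefined)
that conserve the record count exactly.

**Percentages** round half-up to one decimal, matching how clinical
tables are conventionally printed (128/178 → 71.9).

**Error attribution** compares two structured reports and emits
non-exclusive tags: `size_measurement` when the recorded diameters
fall in different size bins, `local_infiltration` when the descriptor
sets differ, `anatomic_location` when any node/nodule/metastasis
location differs.

**Fleiss kappa** uses the standard formulation (observed agreement vs
chance agreement from marginal category proportions), computed through
`statsmodels.stats.inter_rater`.  An all-one-category matrix makes the
formula 0/0; the wrapper returns kappa 1 with a `degenerate` flag.

**Sidak adjustment** is `1 − (1 − p)^m`, monotone in both arguments.

**Latent-scale ICC.**  For a logistic mixed model the residual on the
latent scale is π²/3, so grouping g explains
`ICC_g = σ²_g / (Σ σ² + π²/3)` of the variance.  The ICCs therefore
sum to strictly less than 1.

## 3. The correctness GLMM

Per-category correctness (three rows per reading) is modelled as

    logit P(correct) = β₀ + β_SR·[SR] + β_N·[N] + β_T·[T] + u_case + v_reader

with crossed Gaussian random intercepts.  No method×category
interaction is fitted: with M correctness near ceiling the interaction
is empirically singular.

**Estimation.**  Maximum likelihood under the Laplace approximation:
an inner Newton solve profiles the random-effect mode (the penalized
problem is concave, so this is safe), and L-BFGS-B maximizes the
Laplace marginal likelihood over the four fixed effects and the two
log-SDs (bounded in [−6, 3]; the lower bound is the singular
boundary).  Wald covariance comes from the central-difference Hessian
of the Laplace log-likelihood in the fixed effects at the optimum,
with the variance parameters held fixed — the same conditional Wald
convention lme4 reports.  This was built in-package because no
pre-installed Python library fits crossed-random-effect binomial GLMMs
by ML; statsmodels' variational approximation systematically
understates the posterior SDs (breaking CI coverage) and its MAP
optimizer diverges on realistic study data.  The implementation is
validated in the test suite against `lme4::glmer` run through Rscript:
coefficients, SEs, and variance components agree to within a few
percent on a simulated study.

Degenerate outcomes (all correct / all incorrect) are flagged rather
than raised; a flagged fit refuses to produce contrasts.  Pairwise
category contrasts (M vs N, M vs T, N vs T) are linear contrasts on
the log-odds scale, exponentiated, with Sidak family-of-3 adjusted
intervals and p-values.

## 4. Synthetic world

The generator states one world and keeps it:

* **Cohort**: 20 cases, stage groups I/II/III/IV in counts 4/3/6/7 —
  the validation cohort's mix.  Ground truth is sampled at the
  TNM-tuple level (uniform over the tuples of the target group), then
  findings realizing exactly that tuple are constructed: diameter
  drawn inside the size bin (one-decimal, respecting the open/closed
  edges), T2a/T3/T4 realized half the time through a descriptor or
  nodule floor over a smaller tumor, N through in-map stations, M
  through metastasis findings.  `classify_report` reproduces the label
  by construction — the round-trip invariant the test suite checks on
  1000 cases.
* **Readers**: nine, full factorial over cases × {SR, FTR}.  A
  logistic correctness model with intercept OR 56.926, method OR
  1.707, category effects 0.203 (N) and 0.051 (T) versus M, case SD
  1.128 and reader SD 0.153 — the fitted values of the real
  validation's correctness model — decides *whether* each category is
  read correctly.
* **Error channels** decide *how* an intended error manifests: size
  mismeasurement (adjacent size bin) or infiltration-descriptor error
  for T; anatomic mislocalization (adjacent N/M level via re-realized
  findings) for N and M.  Default rates are the observed proportions:
  size 0.120, infiltration 0.176, mislocalization 0.134.  A disabled
  channel cannot realize an error, so zeroing all rates yields perfect
  readings and enabling only the size channel provably never touches N
  or M — the isolation property under test.
* **SR vs FTR asymmetry**: SR codes are always derived by the rule
  engine from the (possibly perturbed) report, so they are always
  complete and valid; FTR codes are written directly and additionally
  suffer documentation corruption (subcategory stripped, or `M2`) at
  rate 0.044 ≈ 8/180 — documentation errors occur only in free text.
* **Missingness**: `n_missing_sr=2` drops two SR readings of the first
  reader, reproducing the 178/180 record split.

What a green test does *not* establish: the synthetic readers have no
case-difficulty structure beyond a scalar random intercept, error
channels are conditionally independent across categories, mislocations
move exactly one level, and the cohort realizes findings from the
tuple rather than from imaging — so the simulation validates the
*machinery* (rules, scoring, model recovery), not human reading
behaviour.

**Parameter recovery.**  The acceptance property simulates 40 studies
at the stated world (documentation channel off, so the generative and
fitted models coincide — documentation corruption sits outside the
logistic model and would otherwise inflate the realized method effect),
fits the GLMM, and requires 95% CI coverage of the true method OR
within 3σ Monte-Carlo error and a centred mean log-OR.  Measured
during development: coverage 0.975, mean log-OR 0.558 vs true 0.535.

## 5. Known limitations

* Clinical (cTNM) staging only; no pathological staging, no
  9th-edition subclassifications (N2a/N2b, M1c split).
* Station 3 laterality handling (record left/right, classify like
  stations 2/4) is a convention; anatomic boundary geometry is out of
  scope.
* The GLMM's Wald intervals are conditional on the variance estimates;
  with only 20 cases the case-variance estimate is itself noisy.
* The tolerant TNM parser is aimed at short documented codes, not at
  free-prose extraction.
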