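"""Reader-study evaluation: correctness scoring, error attribution,
agreement, and variance-decomposition utilities.

A reader study consists of readings (reader x case x method) each
documenting a TNM code that is compared to a clean reference code.
Scoring yields per-category and aggregate correctness plus the staging
direction (up/down/lateral) on UICC stage ordinals; invalid documented
codes (missing subcategory, nonexistent code) are data, flagged as
documentation errors, and score incorrect for the offending categories.

The mixed-effects comparison of structured versus free-text reporting
lives in :mod:`lungstage.glmm`; this module provides the descriptive
summary, Fleiss kappa, the Sidak adjustment, and the latent-scale ICC
used to decompose a logistic mixed model's variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

from .engine import (
    compare_staging,
    parse_tnm_code,
    t_from_size,
    uicc_stage,
)
from .findings import StructuredReport, UICCStage

__all__ = [
    "ReaderRecord",
    "Method",
    "score_records",
    "summarize",
    "EvaluationSummary",
    "MethodSummary",
    "attribute_t_error",
    "fleiss_kappa",
    "AgreementResult",
    "sidak_adjust",
    "latent_icc",
    "round_pct",
]

VALID_METHODS = ("SR", "FTR")


@dataclass(frozen=True)
class ReaderRecord:
    """One reading event: a reader's documented TNM code for one case."""

    reader_id: str
    case_id: str
    method: str  # "SR" | "FTR"
    reported_code: str
    reference_code: str

    def __post_init__(self):
        if self.method not in VALID_METHODS:
            raise ValueError(f"method must be one of {VALID_METHODS}, got {self.method!r}")


def score_records(records: Sequence[ReaderRecord]) -> pd.DataFrame:
    """Score readings against their references.

    Returns a DataFrame with one row per record and columns
    ``t_correct``, ``n_correct``, ``m_correct``, ``aggregate_correct``,
    ``valid``, ``documentation_error`` and ``direction``.

    Reference codes must parse as valid TNM (``ValueError`` otherwise).
    An invalid reported code scores incorrect for each offending
    category and is a documentation error; so is a valid code whose
    stage group is undefined (e.g. NX) — no staging direction can be
    assigned to either, recorded as direction ``"undefined"``.
    """
    rows = []
    for rec in records:
        ref, ref_validity = parse_tnm_code(rec.reference_code)
        if not ref_validity.valid:
            raise ValueError(
                f"reference code {rec.reference_code!r} (case {rec.case_id}) is not a valid TNM code"
            )
        reported, validity = parse_tnm_code(rec.reported_code)
        bad_cats = {iss.category for iss in validity.issues}
        doc_error = not validity.valid
        if validity.valid:
            t_ok = reported.t is ref.t
            n_ok = reported.n is ref.n
            m_ok = reported.m is ref.m
            if uicc_stage(reported) is UICCStage.UNDEFINED or uicc_stage(ref) is UICCStage.UNDEFINED:
                direction = "undefined"
                doc_error = True
            else:
                direction = compare_staging(reported, ref).direction.value
        else:
            # offending categories are wrong by definition; others unscoreable -> wrong
            t_ok = "T" not in bad_cats and _cat_matches(rec.reported_code, ref.t.value)
            n_ok = "N" not in bad_cats and _cat_matches(rec.reported_code, ref.n.value)
            m_ok = "M" not in bad_cats and _cat_matches(rec.reported_code, ref.m.value)
            direction = "undefined"
        rows.append(
            {
                "reader_id": rec.reader_id,
                "case_id": rec.case_id,
                "method": rec.method,
                "reported_code": rec.reported_code,
                "reference_code": rec.reference_code,
                "t_correct": bool(t_ok),
                "n_correct": bool(n_ok),
                "m_correct": bool(m_ok),
                "aggregate_correct": bool(t_ok and n_ok and m_ok),
                "valid": validity.valid,
                "documentation_error": doc_error,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def _cat_matches(reported_code: str, ref_token: str) -> bool:
    """Category match for a partially-invalid code: salvage the cleanly
    parsed categories by substituting the reference for the broken ones
    and re-parsing."""
    from .engine import _M_VALID, _N_VALID, _T_VALID, _TOKEN_RE  # localized: parser internals

    import re

    cleaned = re.sub(r"[,/;|-]+", " ", reported_code)
    for m in _TOKEN_RE.finditer(cleaned):
        at_boundary = m.start() == 0 or not cleaned[m.start() - 1].isalnum()
        if not at_boundary:
            continue
        cat = m.group(1).upper()
        if cat != ref_token[0].upper():
            continue
        table = {"T": _T_VALID, "N": _N_VALID, "M": _M_VALID}[cat]
        c = table.get(m.group(2).lower())
        return c is not None and c.value == ref_token
    return False


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (matching how such
    study tables are conventionally printed)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MethodSummary:
    """Per-method correctness and staging-direction tallies."""

    n_records: int
    t_correct: int
    n_correct: int
    m_correct: int
    aggregate_correct: int
    upstaged: int
    downstaged: int
    lateral: int
    concordant: int
    undefined_direction: int
    documentation_errors: int

    @property
    def aggregate_pct(self) -> float:
        return round_pct(self.aggregate_correct, self.n_records)

    def category_pct(self, category: str) -> float:
        c = {"T": self.t_correct, "N": self.n_correct, "M": self.m_correct}[category.upper()]
        return round_pct(c, self.n_records)


@dataclass(frozen=True)
class EvaluationSummary:
    """Study-level summary over both reporting methods."""

    per_method: Mapping[str, MethodSummary]
    n_records: int
    category_errors: Mapping[str, int]  # pooled over methods
    documentation_errors: int

    def category_error_pct(self, category: str) -> float:
        return round_pct(self.category_errors[category.upper()], self.n_records)

    def to_dict(self) -> dict:
        out: dict = {"n_records": self.n_records, "documentation_errors": self.documentation_errors}
        out["category_errors"] = {
            k: {"count": v, "pct": self.category_error_pct(k)} for k, v in self.category_errors.items()
        }
        out["per_method"] = {}
        for method, ms in self.per_method.items():
            out["per_method"][method] = {
                "n_records": ms.n_records,
                "aggregate_correct": ms.aggregate_correct,
                "aggregate_pct": ms.aggregate_pct,
                "t_correct": ms.t_correct,
                "n_correct": ms.n_correct,
                "m_correct": ms.m_correct,
                "upstaged": ms.upstaged,
                "downstaged": ms.downstaged,
                "lateral": ms.lateral,
                "concordant": ms.concordant,
                "undefined_direction": ms.undefined_direction,
                "documentation_errors": ms.documentation_errors,
            }
        return out


def summarize(scored: pd.DataFrame) -> EvaluationSummary:
    """Summarize a scored reader-study table.

    Counts conserve: per method, concordant + upstaged + downstaged +
    lateral + undefined_direction equals the record count.
    """
    if scored is None or len(scored) == 0:
        raise ValueError("cannot summarize an empty scored table")
    per_method: dict[str, MethodSummary] = {}
    for method, grp in scored.groupby("method", sort=True):
        dirs = grp["direction"].value_counts().to_dict()
        per_method[str(method)] = MethodSummary(
            n_records=len(grp),
            t_correct=int(grp["t_correct"].sum()),
            n_correct=int(grp["n_correct"].sum()),
            m_correct=int(grp["m_correct"].sum()),
            aggregate_correct=int(grp["aggregate_correct"].sum()),
            upstaged=int(dirs.get("upstaged", 0)),
            downstaged=int(dirs.get("downstaged", 0)),
            lateral=int(dirs.get("lateral", 0)),
            concordant=int(dirs.get("concordant", 0)),
            undefined_direction=int(dirs.get("undefined", 0)),
            documentation_errors=int(grp["documentation_error"].sum()),
        )
    n = len(scored)
    category_errors = {
        "T": int((~scored["t_correct"]).sum()),
        "N": int((~scored["n_correct"]).sum()),
        "M": int((~scored["m_correct"]).sum()),
    }
    return EvaluationSummary(
        per_method=per_method,
        n_records=n,
        category_errors=category_errors,
        documentation_errors=int(scored["documentation_error"].sum()),
    )


# ---------------------------------------------------------------------------
# Error-source attribution


def attribute_t_error(reader_report: StructuredReport, reference_report: StructuredReport) -> set[str]:
    """Attribute discrepancies between two structured reports to error sources.

    Tags are non-exclusive: ``size_measurement`` when the size-based T
    bins of the recorded diameters differ, ``local_infiltration`` when
    the invasion-descriptor sets differ, and ``anatomic_location`` when
    any node, separate nodule, or metastasis location differs.
    """
    tags: set[str] = set()
    a, b = reader_report.primary, reference_report.primary
    if a.measurable and b.measurable:
        if t_from_size(a.diameter_cm) is not t_from_size(b.diameter_cm):
            tags.add("size_measurement")
    elif a.measurable != b.measurable:
        tags.add("size_measurement")
    if a.descriptors != b.descriptors:
        tags.add("local_infiltration")
    nodes_a = sorted((nf.station, nf.side.value, nf.judged_malignant) for nf in reader_report.nodes)
    nodes_b = sorted((nf.station, nf.side.value, nf.judged_malignant) for nf in reference_report.nodes)
    nodules_a = sorted(n.lobe.value for n in reader_report.separate_nodules)
    nodules_b = sorted(n.lobe.value for n in reference_report.separate_nodules)
    mets_a = sorted((m.site.value, m.side.value if m.side else "", m.lesion_count) for m in reader_report.metastases)
    mets_b = sorted((m.site.value, m.side.value if m.side else "", m.lesion_count) for m in reference_report.metastases)
    if nodes_a != nodes_b or nodules_a != nodules_b or mets_a != mets_b or a.lobe is not b.lobe:
        tags.add("anatomic_location")
    return tags


# ---------------------------------------------------------------------------
# Agreement and multiplicity


@dataclass(frozen=True)
class AgreementResult:
    """Fleiss-kappa agreement over items x raters categorical ratings."""

    kappa: float
    n_items: int
    n_raters: int
    n_categories: int
    degenerate: bool = False


def fleiss_kappa(ratings: Sequence[Sequence[object]]) -> AgreementResult:
    """Fleiss kappa for >=2 raters assigning categorical labels.

    ``ratings`` is items x raters (each cell a category label).  With a
    single category used everywhere chance agreement is 1 and the usual
    formula is 0/0; perfect agreement is returned with
    ``degenerate=True``.
    """
    arr = np.asarray(ratings, dtype=object)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("ratings must be an items x raters matrix with >=2 of each")
    n_items, n_raters = arr.shape
    cats = sorted({str(x) for x in arr.ravel()})
    if len(cats) == 1:
        return AgreementResult(kappa=1.0, n_items=n_items, n_raters=n_raters, n_categories=1, degenerate=True)
    table, _ = inter_rater.aggregate_raters(np.vectorize(cats.index)(arr.astype(str)))
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))
    return AgreementResult(kappa=kappa, n_items=n_items, n_raters=n_raters, n_categories=len(cats))


def sidak_adjust(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Sidak multiplicity adjustment: ``1 - (1 - p)^m``, clipped to [0, 1].

    ``m`` defaults to the number of p-values supplied.
    """
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    out = []
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {p!r}")
        out.append(min(1.0, max(0.0, 1.0 - (1.0 - p) ** m)))
    return out


_LOGISTIC_RESIDUAL_VARIANCE = math.pi**2 / 3.0


def latent_icc(variance_components: Mapping[str, float]) -> dict[str, float]:
    """Latent-scale intraclass correlations for a logistic mixed model.

    For each grouping g, ``ICC_g = var_g / (sum(var) + pi^2/3)`` — the
    standard latent-variable convention in which the logistic residual
    contributes pi^2/3 to the total variance.
    """
    for k, v in variance_components.items():
        if v < 0:
            raise ValueError(f"variance component {k!r} is negative: {v}")
    total = sum(variance_components.values()) + _LOGISTIC_RESIDUAL_VARIANCE
    return {k: v / total for k, v in variance_components.items()}
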