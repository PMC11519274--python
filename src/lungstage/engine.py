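"""Deterministic TNM (8th edition) rule engine for NSCLC.

This module is the heart of the package: it turns an itemized
:class:`~lungstage.findings.StructuredReport` into a clinical TNM
triplet and a UICC stage group, parses and validates free-text TNM code
strings, and compares a reading against a reference in terms of
up-/down-staging.

The T rule is a max rule over contributing floors: the size-based bin
of the maximum multiplanar diameter, the floors attached to asserted
invasion descriptors, T3 for a separate nodule in the primary's lobe,
and T4 for a nodule in a different ipsilateral lobe.  Contralateral
nodules leave T entirely and are routed to M1a.  The N rule is a max
over the IASLC regionality classes of malignant nodes; nodes outside
the map leave N and are routed to M.  The M rule splits intrathoracic
spread (M1a) from single (M1b) versus multiple (M1c) extrathoracic
lesions.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .findings import (
    Laterality,
    MCategory,
    MetastasisFinding,
    NCategory,
    NodalFinding,
    PrimaryTumorFinding,
    SeparateTumorNodule,
    StructuredReport,
    TCategory,
    TFloor,
    TNMClassification,
    UICCStage,
    descriptor_floor,
)
from .nodal_map import RegionClass, resolve_station

__all__ = [
    "t_from_size",
    "classify_t",
    "classify_n",
    "classify_m",
    "classify_report",
    "uicc_stage",
    "parse_tnm_code",
    "format_tnm",
    "compare_staging",
    "StagingComparison",
    "StagingDirection",
    "TnmValidity",
    "TnmIssue",
    "IssueKind",
]

ENGINE_VERSION = "tnm8-1.0"

# size bins: (upper bound inclusive, category)
_SIZE_BINS: list[tuple[float, TCategory]] = [
    (1.0, TCategory.T1a),
    (2.0, TCategory.T1b),
    (3.0, TCategory.T1c),
    (4.0, TCategory.T2a),
    (5.0, TCategory.T2b),
    (7.0, TCategory.T3),
]


def t_from_size(diameter_cm: float) -> TCategory:
    """Size-based T category from the maximum multiplanar diameter (cm).

    Bins are left-open/right-closed (``<=`` at each upper bound):
    <=1 T1a, (1,2] T1b, (2,3] T1c, (3,4] T2a, (4,5] T2b, (5,7] T3, >7 T4.
    """
    if not diameter_cm > 0:
        raise ValueError(f"tumor diameter must be positive, got {diameter_cm!r}")
    for upper, cat in _SIZE_BINS:
        if diameter_cm <= upper:
            return cat
    return TCategory.T4


def classify_t(
    primary: PrimaryTumorFinding,
    separate_nodules: Sequence[SeparateTumorNodule] = (),
) -> TCategory:
    """T category: max rule over size, descriptor floors, and nodules.

    A non-measurable primary yields TX.  ``at_least_T2`` descriptor
    floors resolve to T2a when the size-based category is below T2a;
    size alone decides T2a versus T2b.
    """
    if not primary.measurable:
        return TCategory.TX
    t = t_from_size(primary.diameter_cm)
    floors: list[TCategory] = []
    for d in primary.descriptors:
        f = descriptor_floor(d)
        if f is TFloor.AT_LEAST_T2:
            floors.append(TCategory.T2a)
        elif f is TFloor.T3:
            floors.append(TCategory.T3)
        else:
            floors.append(TCategory.T4)
    primary_side = primary.lobe.side
    for nod in separate_nodules:
        if nod.lobe.side is not primary_side:
            continue  # contralateral nodules are M1a, not T
        floors.append(TCategory.T3 if nod.lobe is primary.lobe else TCategory.T4)
    for f in floors:
        if f.rank > t.rank:
            t = f
    return t


def classify_n(nodes: Sequence[NodalFinding], primary_side: Laterality) -> NCategory:
    """N category: max IASLC regionality over malignant nodal findings.

    Extrathoracic nodes are ignored here (they are M events); no
    malignant regional node means N0.
    """
    best = 0
    for nf in nodes:
        if not nf.judged_malignant:
            continue
        rc = resolve_station(nf.station, nf.side, primary_side)
        if rc is RegionClass.EXTRATHORACIC:
            continue
        best = max(best, rc.n_rank)
    return {0: NCategory.N0, 1: NCategory.N1, 2: NCategory.N2, 3: NCategory.N3}[best]


def classify_m(
    metastases: Sequence[MetastasisFinding],
    nodes: Sequence[NodalFinding] = (),
    separate_nodules: Sequence[SeparateTumorNodule] = (),
    primary_side: Laterality | None = None,
) -> MCategory:
    """M category from metastatic findings, extrathoracic nodes, and
    contralateral separate nodules.

    M1c: more than one extrathoracic lesion in total (any organ mix);
    M1b: exactly one extrathoracic lesion; M1a: any intrathoracic
    distant event (contralateral-lobe nodule, pleural/pericardial
    dissemination); else M0.
    """
    m1a = False
    extrathoracic_lesions = 0
    for mf in metastases:
        if mf.site.intrathoracic:
            m1a = True
        else:
            extrathoracic_lesions += mf.lesion_count
    if primary_side is not None:
        for nf in nodes:
            if not nf.judged_malignant:
                continue
            if resolve_station(nf.station, nf.side, primary_side) is RegionClass.EXTRATHORACIC:
                extrathoracic_lesions += 1
        for nod in separate_nodules:
            if nod.lobe.side is not primary_side:
                m1a = True
    if extrathoracic_lesions > 1:
        return MCategory.M1c
    if extrathoracic_lesions == 1:
        return MCategory.M1b
    if m1a:
        return MCategory.M1a
    return MCategory.M0


def classify_report(report: StructuredReport) -> TNMClassification:
    """Classify a full structured report into a TNM triplet.

    Pure and deterministic; shared routing sends extrathoracic nodes
    from N to M and contralateral nodules from T to M.
    """
    primary_side = report.primary.lobe.side
    errors: list[str] = []
    t = n = m = None
    try:
        t = classify_t(report.primary, report.separate_nodules)
    except ValueError as e:
        errors.append(f"T: {e}")
    try:
        n = classify_n(report.nodes, primary_side)
    except ValueError as e:
        errors.append(f"N: {e}")
    try:
        m = classify_m(report.metastases, report.nodes, report.separate_nodules, primary_side)
    except ValueError as e:
        errors.append(f"M: {e}")
    if errors:
        raise ValueError(f"report {report.case_id!r} could not be classified: " + "; ".join(errors))
    return TNMClassification(t=t, n=n, m=m)


# ---------------------------------------------------------------------------
# UICC stage grouping

_STAGE_M0: dict[tuple[TCategory, NCategory], UICCStage] = {}


def _fill_stage_table() -> None:
    t_sub = [TCategory.T1a, TCategory.T1b, TCategory.T1c, TCategory.T2a, TCategory.T2b]
    n0 = {
        TCategory.T1a: UICCStage.IA1,
        TCategory.T1b: UICCStage.IA2,
        TCategory.T1c: UICCStage.IA3,
        TCategory.T2a: UICCStage.IB,
        TCategory.T2b: UICCStage.IIA,
        TCategory.T3: UICCStage.IIB,
        TCategory.T4: UICCStage.IIIA,
    }
    for t, s in n0.items():
        _STAGE_M0[(t, NCategory.N0)] = s
    for t in t_sub:
        _STAGE_M0[(t, NCategory.N1)] = UICCStage.IIB
        _STAGE_M0[(t, NCategory.N2)] = UICCStage.IIIA
        _STAGE_M0[(t, NCategory.N3)] = UICCStage.IIIB
    for t in (TCategory.T3, TCategory.T4):
        _STAGE_M0[(t, NCategory.N1)] = UICCStage.IIIA
        _STAGE_M0[(t, NCategory.N2)] = UICCStage.IIIB
        _STAGE_M0[(t, NCategory.N3)] = UICCStage.IIIC


_fill_stage_table()


def uicc_stage(c: TNMClassification) -> UICCStage:
    """UICC (8th edition) stage group for a TNM triplet.

    M1c is IVB and M1a/M1b IVA regardless of T and N.  TX N0 M0 is the
    occult-carcinoma group; NX, or TX with nodal disease, cannot be
    grouped and returns ``UNDEFINED``.
    """
    if c.n is NCategory.NX:
        return UICCStage.UNDEFINED
    if c.m is MCategory.M1c:
        return UICCStage.IVB
    if c.m in (MCategory.M1a, MCategory.M1b):
        return UICCStage.IVA
    # M0 from here
    if c.t is TCategory.TX:
        return UICCStage.OCCULT if c.n is NCategory.N0 else UICCStage.UNDEFINED
    if c.t is TCategory.T0:
        return UICCStage.UNDEFINED
    if c.t is TCategory.Tis:
        return UICCStage.STAGE_0 if c.n is NCategory.N0 else UICCStage.UNDEFINED
    if c.t is TCategory.T1mi:
        return UICCStage.IA1 if c.n is NCategory.N0 else UICCStage.UNDEFINED
    return _STAGE_M0[(c.t, c.n)]


# ---------------------------------------------------------------------------
# TNM code parsing / formatting


class IssueKind(str, enum.Enum):
    MISSING_SUBCATEGORY = "missing_subcategory"
    NONEXISTENT_CODE = "nonexistent_code"
    UNPARSEABLE = "unparseable"


@dataclass(frozen=True)
class TnmIssue:
    category: str  # "T" | "N" | "M"
    kind: IssueKind
    token: Optional[str] = None


@dataclass(frozen=True)
class TnmValidity:
    """Validity verdict for a documented TNM code; issues are data, not errors."""

    issues: tuple[TnmIssue, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.issues


_T_VALID = {c.value[1:].lower(): c for c in TCategory}
_N_VALID = {c.value[1:].lower(): c for c in NCategory}
_M_VALID = {c.value[1:].lower(): c for c in MCategory}
# bare main categories that exist but require a subcategory in 8th-edition NSCLC use
_T_INCOMPLETE = {"1", "2"}
_M_INCOMPLETE = {"1"}

# subtoken stops at the next category letter so "T2bN1M0" splits cleanly,
# with explicit carve-outs for the m in "T1mi" and the s in "Tis"
_TOKEN_RE = re.compile(r"([tnm])\s*(1mi|is|(?:(?![tnm])[a-z0-9])*)", re.IGNORECASE)


def parse_tnm_code(text: str) -> tuple[Optional[TNMClassification], TnmValidity]:
    """Tolerantly parse a documented TNM code string.

    Case-insensitive; separators (spaces, commas, slashes, hyphens) are
    optional.  Returns the classification when the code is fully valid,
    else ``None`` together with the issue list.  Never raises on
    content: an invalid code is data.
    """
    issues: list[TnmIssue] = []
    found: dict[str, object] = {}
    cleaned = re.sub(r"[,/;|-]+", " ", str(text))
    tokens: list[tuple[str, str]] = []
    last_end = -1
    for m in _TOKEN_RE.finditer(cleaned):
        # a category letter must start a word or directly follow the
        # previous category token ("T2bN1M0"); an embedded letter as in
        # "recommended" is not a code
        at_boundary = m.start() == 0 or not cleaned[m.start() - 1].isalnum()
        if at_boundary or m.start() == last_end:
            tokens.append((m.group(1), m.group(2)))
            last_end = m.end()
    for letter, sub in tokens:
        cat = letter.upper()
        if cat in found:
            continue  # first occurrence wins
        sub = sub.lower()
        table = {"T": _T_VALID, "N": _N_VALID, "M": _M_VALID}[cat]
        incomplete = {"T": _T_INCOMPLETE, "N": set(), "M": _M_INCOMPLETE}[cat]
        if sub in table:
            found[cat] = table[sub]
        elif sub in incomplete:
            found[cat] = None
            issues.append(TnmIssue(cat, IssueKind.MISSING_SUBCATEGORY, f"{cat}{sub}"))
        elif sub == "":
            issues.append(TnmIssue(cat, IssueKind.UNPARSEABLE, cat))
            found[cat] = None
        else:
            found[cat] = None
            issues.append(TnmIssue(cat, IssueKind.NONEXISTENT_CODE, f"{cat}{sub}"))
    for cat in ("T", "N", "M"):
        if cat not in found:
            issues.append(TnmIssue(cat, IssueKind.UNPARSEABLE, None))
    validity = TnmValidity(tuple(issues))
    if validity.valid:
        return (
            TNMClassification(t=found["T"], n=found["N"], m=found["M"]),
            validity,
        )
    return None, validity


def format_tnm(c: TNMClassification) -> str:
    """Canonical ``"T? N? M?"`` rendering; round-trips through the parser."""
    return str(c)


# ---------------------------------------------------------------------------
# Staging-direction comparison


class StagingDirection(str, enum.Enum):
    CONCORDANT = "concordant"
    UPSTAGED = "upstaged"
    DOWNSTAGED = "downstaged"
    LATERAL = "lateral"


@dataclass(frozen=True)
class StagingComparison:
    """Reader-vs-reference verdict: per-category matches and stage direction.

    ``lateral`` marks readings whose stage-group ordinal equals the
    reference while the TNM tuple differs — an error without prognostic
    direction.
    """

    direction: StagingDirection
    t_match: bool
    n_match: bool
    m_match: bool

    @property
    def concordant(self) -> bool:
        return self.direction is StagingDirection.CONCORDANT


def compare_staging(reader: TNMClassification, reference: TNMClassification) -> StagingComparison:
    """Compare a reading against the reference on UICC stage ordinals.

    Raises ``ValueError`` when either side has an undefined stage group
    (direction is meaningless without a rank).
    """
    s_reader = uicc_stage(reader)
    s_ref = uicc_stage(reference)
    if s_reader is UICCStage.UNDEFINED or s_ref is UICCStage.UNDEFINED:
        raise ValueError("staging direction requires both stages to be defined")
    t_match = reader.t is reference.t
    n_match = reader.n is reference.n
    m_match = reader.m is reference.m
    if t_match and n_match and m_match:
        direction = StagingDirection.CONCORDANT
    elif s_reader.ordinal > s_ref.ordinal:
        direction = StagingDirection.UPSTAGED
    elif s_reader.ordinal < s_ref.ordinal:
        direction = StagingDirection.DOWNSTAGED
    else:
        direction = StagingDirection.LATERAL
    return StagingComparison(direction=direction, t_match=t_match, n_match=n_match, m_match=m_match)
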