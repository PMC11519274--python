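"""Typed domain model for structured NSCLC staging reports.

The types here mirror the items a thoracic radiologist records in a
structured report (SR) at staging: the primary tumor with its maximum
multiplanar diameter and local-invasion descriptors, separate tumor
nodules, lymph-node findings addressed by IASLC station, and distant
metastatic findings by site.  Everything downstream — the rule engine,
the reader-study evaluation, the simulator — consumes these types.

All models are immutable and validate on construction; a report that
constructs successfully is structurally fit for classification.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_serializer, field_validator, model_validator

__all__ = [
    "Laterality",
    "Side",
    "LungLobe",
    "InvasionDescriptor",
    "TFloor",
    "descriptor_floor",
    "lobe_side",
    "PrimaryTumorFinding",
    "SeparateTumorNodule",
    "NodalFinding",
    "MetastasisFinding",
    "MetastasisSite",
    "StructuredReport",
    "TCategory",
    "NCategory",
    "MCategory",
    "TNMClassification",
    "UICCStage",
]


class Laterality(str, enum.Enum):
    """Side of the thorax; a primary tumor is never midline."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def mirrored(self) -> "Laterality":
        return Laterality.RIGHT if self is Laterality.LEFT else Laterality.LEFT


class Side(str, enum.Enum):
    """Recorded side of a nodal finding; midline exists for station 7."""

    LEFT = "left"
    RIGHT = "right"
    MIDLINE = "midline"

    @property
    def mirrored(self) -> "Side":
        if self is Side.MIDLINE:
            return self
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class LungLobe(str, enum.Enum):
    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    LUL = "LUL"
    LLL = "LLL"

    @property
    def side(self) -> Laterality:
        return Laterality.RIGHT if self.value.startswith("R") else Laterality.LEFT


def lobe_side(lobe: LungLobe) -> Laterality:
    """Laterality of a lobe (R** -> right, L** -> left)."""
    return LungLobe(lobe).side


class TFloor(enum.Enum):
    """Minimum T category forced by an invasion descriptor.

    ``AT_LEAST_T2`` resolves to T2a when size alone stays below T2a;
    size governs T2a vs T2b.  T3/T4 floors are absolute.
    """

    AT_LEAST_T2 = "at_least_T2"
    T3 = "T3"
    T4 = "T4"


class InvasionDescriptor(str, enum.Enum):
    """Local-invasion descriptors a reporter can assert for the primary.

    Pleural *contact* is deliberately absent: invasion of the visceral
    pleura is a human judgment the reporter must assert explicitly; the
    engine never infers it from contact.
    """

    # at least T2
    VISCERAL_PLEURA_INVASION = "visceral_pleura_invasion"
    MAIN_BRONCHUS_INVOLVEMENT = "main_bronchus_involvement"
    ATELECTASIS_OR_OBSTRUCTIVE_PNEUMONITIS = "atelectasis_or_obstructive_pneumonitis"
    # T3
    CHEST_WALL = "chest_wall"
    PARIETAL_PLEURA = "parietal_pleura"
    PHRENIC_NERVE = "phrenic_nerve"
    PARIETAL_PERICARDIUM = "parietal_pericardium"
    # T4
    DIAPHRAGM = "diaphragm"
    MEDIASTINUM = "mediastinum"
    HEART = "heart"
    GREAT_VESSELS = "great_vessels"
    TRACHEA = "trachea"
    CARINA = "carina"
    RECURRENT_LARYNGEAL_NERVE = "recurrent_laryngeal_nerve"
    ESOPHAGUS = "esophagus"
    VERTEBRAL_BODY = "vertebral_body"


_DESCRIPTOR_FLOOR: dict[InvasionDescriptor, TFloor] = {
    InvasionDescriptor.VISCERAL_PLEURA_INVASION: TFloor.AT_LEAST_T2,
    InvasionDescriptor.MAIN_BRONCHUS_INVOLVEMENT: TFloor.AT_LEAST_T2,
    InvasionDescriptor.ATELECTASIS_OR_OBSTRUCTIVE_PNEUMONITIS: TFloor.AT_LEAST_T2,
    InvasionDescriptor.CHEST_WALL: TFloor.T3,
    InvasionDescriptor.PARIETAL_PLEURA: TFloor.T3,
    InvasionDescriptor.PHRENIC_NERVE: TFloor.T3,
    InvasionDescriptor.PARIETAL_PERICARDIUM: TFloor.T3,
    InvasionDescriptor.DIAPHRAGM: TFloor.T4,
    InvasionDescriptor.MEDIASTINUM: TFloor.T4,
    InvasionDescriptor.HEART: TFloor.T4,
    InvasionDescriptor.GREAT_VESSELS: TFloor.T4,
    InvasionDescriptor.TRACHEA: TFloor.T4,
    InvasionDescriptor.CARINA: TFloor.T4,
    InvasionDescriptor.RECURRENT_LARYNGEAL_NERVE: TFloor.T4,
    InvasionDescriptor.ESOPHAGUS: TFloor.T4,
    InvasionDescriptor.VERTEBRAL_BODY: TFloor.T4,
}


def descriptor_floor(descriptor: InvasionDescriptor | str) -> TFloor:
    """Return the T floor attached to an invasion descriptor.

    Raises ``ValueError`` naming the offending token for anything
    outside the closed descriptor set.
    """
    try:
        d = InvasionDescriptor(descriptor)
    except ValueError:
        raise ValueError(f"unknown invasion descriptor: {descriptor!r}") from None
    return _DESCRIPTOR_FLOOR[d]


class MetastasisSite(str, enum.Enum):
    """Distant-disease sites; the first three are intrathoracic (M1a)."""

    PLEURAL_NODULE = "pleural_nodule"
    MALIGNANT_PLEURAL_EFFUSION = "malignant_pleural_effusion"
    MALIGNANT_PERICARDIAL_EFFUSION = "malignant_pericardial_effusion"
    ADRENAL = "adrenal"
    BONE = "bone"
    BRAIN = "brain"
    LIVER = "liver"
    EXTRATHORACIC_NODE = "extrathoracic_node"
    SKIN = "skin"
    OTHER_EXTRATHORACIC = "other_extrathoracic"

    @property
    def intrathoracic(self) -> bool:
        return self in _INTRATHORACIC_SITES


_INTRATHORACIC_SITES = frozenset(
    {
        MetastasisSite.PLEURAL_NODULE,
        MetastasisSite.MALIGNANT_PLEURAL_EFFUSION,
        MetastasisSite.MALIGNANT_PERICARDIAL_EFFUSION,
    }
)


class _Frozen(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True, use_enum_values=False)


class PrimaryTumorFinding(_Frozen):
    """The primary tumor: lobe, maximum multiplanar diameter, descriptors.

    The diameter is the maximum over all reconstruction planes in cm,
    not the axial diameter alone.  ``measurable=False`` (e.g., the tumor
    cannot be delineated) yields TX downstream.
    """

    lobe: LungLobe
    diameter_cm: Optional[float] = None
    descriptors: frozenset[InvasionDescriptor] = frozenset()
    measurable: bool = True

    @model_validator(mode="after")
    def _check_diameter(self) -> "PrimaryTumorFinding":
        if self.measurable:
            if self.diameter_cm is None or self.diameter_cm <= 0:
                raise ValueError("a measurable primary requires diameter_cm > 0")
        return self

    @field_serializer("descriptors")
    def _ser_descriptors(self, v: frozenset[InvasionDescriptor]):
        return sorted(d.value for d in v)

    @field_serializer("diameter_cm")
    def _ser_diameter(self, v: Optional[float]):
        # cm with one-decimal precision, the template's reporting granularity
        return None if v is None else round(v, 1)


class SeparateTumorNodule(_Frozen):
    """A separate tumor nodule; only its lobe matters for staging."""

    lobe: LungLobe


# Non-IASLC nodal tokens a reporter may record; they route to M, not N.
EXTRATHORACIC_NODE_TOKENS = frozenset(
    {"axillary", "abdominal", "inguinal", "internal_mammary", "diaphragmatic", "retroperitoneal", "cervical"}
)

_IASLC_STATIONS = frozenset(str(i) for i in range(1, 15))


class NodalFinding(_Frozen):
    """A lymph-node finding by IASLC station (``"1"``–``"14"``) or an
    extrathoracic token such as ``axillary``.

    Station 7 (subcarinal) is midline by definition; stations 5 and 6
    are left-sided structures.  Only ``judged_malignant`` findings
    contribute to N/M.
    """

    station: str
    side: Side
    judged_malignant: bool = True

    @field_validator("station")
    @classmethod
    def _known_station(cls, v: str) -> str:
        token = v.strip()
        if token not in _IASLC_STATIONS and token not in EXTRATHORACIC_NODE_TOKENS:
            raise ValueError(f"unknown nodal station token: {v!r}")
        return token

    @model_validator(mode="after")
    def _side_consistency(self) -> "NodalFinding":
        if self.station == "7" and self.side is not Side.MIDLINE:
            raise ValueError("station 7 (subcarinal) must be recorded midline")
        if self.station in {"5", "6"} and self.side is not Side.LEFT:
            raise ValueError(f"station {self.station} is a left-sided structure")
        if self.station != "7" and self.side is Side.MIDLINE:
            raise ValueError(f"station {self.station!r} must be recorded left or right, not midline")
        return self


class MetastasisFinding(_Frozen):
    """Distant disease at one site; ``lesion_count`` counts discrete lesions."""

    site: MetastasisSite
    side: Optional[Laterality] = None
    lesion_count: int = Field(default=1, ge=1)


class StructuredReport(_Frozen):
    """One case's itemized structured-report findings."""

    case_id: str = Field(min_length=1)
    primary: PrimaryTumorFinding
    separate_nodules: tuple[SeparateTumorNodule, ...] = ()
    nodes: tuple[NodalFinding, ...] = ()
    metastases: tuple[MetastasisFinding, ...] = ()


# ---------------------------------------------------------------------------
# TNM categories and UICC stage groups


class TCategory(str, enum.Enum):
    TX = "TX"
    T0 = "T0"
    Tis = "Tis"
    T1mi = "T1mi"
    T1a = "T1a"
    T1b = "T1b"
    T1c = "T1c"
    T2a = "T2a"
    T2b = "T2b"
    T3 = "T3"
    T4 = "T4"

    @property
    def rank(self) -> int:
        return _T_ORDER.index(self)


_T_ORDER = [
    TCategory.TX,
    TCategory.T0,
    TCategory.Tis,
    TCategory.T1mi,
    TCategory.T1a,
    TCategory.T1b,
    TCategory.T1c,
    TCategory.T2a,
    TCategory.T2b,
    TCategory.T3,
    TCategory.T4,
]


class NCategory(str, enum.Enum):
    NX = "NX"
    N0 = "N0"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"

    @property
    def rank(self) -> int:
        return [NCategory.NX, NCategory.N0, NCategory.N1, NCategory.N2, NCategory.N3].index(self)


class MCategory(str, enum.Enum):
    M0 = "M0"
    M1a = "M1a"
    M1b = "M1b"
    M1c = "M1c"

    @property
    def rank(self) -> int:
        return [MCategory.M0, MCategory.M1a, MCategory.M1b, MCategory.M1c].index(self)


class TNMClassification(_Frozen):
    """A complete clinical TNM triplet; no category may be blank."""

    t: TCategory
    n: NCategory
    m: MCategory

    def __str__(self) -> str:
        return f"{self.t.value} {self.n.value} {self.m.value}"


class UICCStage(str, enum.Enum):
    """UICC stage groups in prognostic order; ``UNDEFINED`` has no rank."""

    OCCULT = "occult"
    STAGE_0 = "0"
    IA1 = "IA1"
    IA2 = "IA2"
    IA3 = "IA3"
    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"
    IIIA = "IIIA"
    IIIB = "IIIB"
    IIIC = "IIIC"
    IVA = "IVA"
    IVB = "IVB"
    UNDEFINED = "undefined"

    @property
    def ordinal(self) -> int:
        """Strict rank in prognostic order; raises on ``UNDEFINED``."""
        if self is UICCStage.UNDEFINED:
            raise ValueError("undefined stage has no ordinal rank")
        return _STAGE_ORDER.index(self)

    @property
    def group(self) -> str:
        """Coarse roman group I/II/III/IV (occult and 0 map to I)."""
        if self is UICCStage.UNDEFINED:
            raise ValueError("undefined stage has no group")
        v = self.value
        for g in ("IV", "III", "II", "I"):
            if v.startswith(g):
                return g
        return "I"  # occult, 0


_STAGE_ORDER = [
    UICCStage.OCCULT,
    UICCStage.STAGE_0,
    UICCStage.IA1,
    UICCStage.IA2,
    UICCStage.IA3,
    UICCStage.IB,
    UICCStage.IIA,
    UICCStage.IIB,
    UICCStage.IIIA,
    UICCStage.IIIB,
    UICCStage.IIIC,
    UICCStage.IVA,
    UICCStage.IVB,
]
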