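"""Synthetic staging cohorts and imperfect-reader simulation.

No clinical images or readings ship with this package, so end-to-end
behaviour is exercised on a stated synthetic world: a 20-case cohort
with the validation mix of UICC groups (4 stage I, 3 stage II, 6 stage
III, 7 stage IV), read by nine readers under both reporting methods.

Ground truth is sampled at the TNM-tuple level first and findings are
constructed second, so every case classifies back to its label by
construction — the central round-trip invariant.  Reader imperfection
is generated in two layers:

* a logistic correctness model with fixed effects for method and TNM
  category and Gaussian random intercepts for case and reader decides
  *whether* a category is read correctly;
* configured error channels decide *how* an incorrect category
  manifests — size mismeasurement or infiltration-descriptor error for
  T, anatomic mislocalization for N and M.  A channel whose rate is
  zero cannot realize an error, so disabling all channels yields
  perfect readings and disabling a channel isolates the categories it
  feeds.

Structured-report (SR) readings are derived by perturbing the findings
and running the rule engine, so annotation errors propagate to TNM via
the rules; free-text (FTR) readings take a direct code path that can
additionally be corrupted at documentation time (e.g. ``T2`` without
its subcategory), mirroring that documentation errors occur only in
free text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import classify_report, format_tnm, uicc_stage
from .evaluation import ReaderRecord
from .findings import (
    InvasionDescriptor,
    Laterality,
    LungLobe,
    MCategory,
    MetastasisFinding,
    MetastasisSite,
    NCategory,
    NodalFinding,
    PrimaryTumorFinding,
    SeparateTumorNodule,
    Side,
    StructuredReport,
    TCategory,
    TFloor,
    TNMClassification,
    UICCStage,
    descriptor_floor,
)

__all__ = [
    "SimulationConfig",
    "LabeledCase",
    "generate_case",
    "generate_cohort",
    "simulate_reader",
    "simulate_reader_study",
]

# T categories the generator emits (Tis/T1mi are representable in the
# type system but absent from a staging cohort like the validation set)
_GEN_T = (
    TCategory.T1a,
    TCategory.T1b,
    TCategory.T1c,
    TCategory.T2a,
    TCategory.T2b,
    TCategory.T3,
    TCategory.T4,
)
_GEN_N = (NCategory.N0, NCategory.N1, NCategory.N2, NCategory.N3)
_GEN_M = (MCategory.M0, MCategory.M1a, MCategory.M1b, MCategory.M1c)

_T_BIN: dict[TCategory, tuple[float, float]] = {
    TCategory.T1a: (0.4, 1.0),
    TCategory.T1b: (1.0, 2.0),
    TCategory.T1c: (2.0, 3.0),
    TCategory.T2a: (3.0, 4.0),
    TCategory.T2b: (4.0, 5.0),
    TCategory.T3: (5.0, 7.0),
    TCategory.T4: (7.0, 10.0),
}

_FLOOR_DESCRIPTORS = {
    TFloor.AT_LEAST_T2: [d for d in InvasionDescriptor if descriptor_floor(d) is TFloor.AT_LEAST_T2],
    TFloor.T3: [d for d in InvasionDescriptor if descriptor_floor(d) is TFloor.T3],
    TFloor.T4: [d for d in InvasionDescriptor if descriptor_floor(d) is TFloor.T4],
}

_EXTRATHORACIC_SITES = [s for s in MetastasisSite if not s.intrathoracic]
_INTRATHORACIC_SITES = [s for s in MetastasisSite if s.intrathoracic]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for synthetic cohorts and reader error.

    Defaults state the study world: 20 cases split 4/3/6/7 over UICC
    groups I-IV, nine readers, a true SR-vs-FTR odds ratio of 1.707,
    category effects and random-intercept SDs at the fitted values of
    the correctness model (case 1.128, reader 0.153), and observed
    error-channel proportions (size 12.0%, infiltration 17.6%,
    anatomic mislocalization 48/358, documentation 8/180).
    """

    n_cases: int = 20
    stage_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"I": 4, "II": 3, "III": 6, "IV": 7}
    )
    n_readers: int = 9
    method_or: float = 1.707
    intercept_or: float = 56.926
    category_effects: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.0, "N": math.log(0.203), "T": math.log(0.051)}
    )
    sd_image: float = 1.128
    sd_reader: float = 0.153
    error_channel_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "size_measurement": 0.120,
            "local_infiltration": 0.176,
            "anatomic_location": 0.134,
            "documentation": 0.044,
        }
    )
    n_missing_sr: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_readers < 1:
            raise ValueError("n_cases and n_readers must be positive")
        if self.method_or <= 0 or self.intercept_or <= 0:
            raise ValueError("odds ratios must be positive")
        if self.sd_image < 0 or self.sd_reader < 0:
            raise ValueError("random-effect SDs must be non-negative")
        for k, v in self.error_channel_rates.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"channel rate {k!r} out of [0, 1]: {v}")
        unknown = set(self.stage_distribution) - {"I", "II", "III", "IV"}
        if unknown:
            raise ValueError(f"unknown stage groups in distribution: {sorted(unknown)}")
        vals = list(self.stage_distribution.values())
        if any(v < 0 for v in vals):
            raise ValueError("stage distribution entries must be non-negative")
        if all(float(v).is_integer() for v in vals) and sum(vals) > 0:
            if int(sum(vals)) != self.n_cases and not math.isclose(sum(vals), 1.0):
                raise ValueError(
                    f"stage counts {vals} do not sum to n_cases={self.n_cases}"
                )

    @property
    def stage_counts(self) -> dict[str, int]:
        """Exact per-group case counts (integer counts required)."""
        vals = self.stage_distribution
        if all(float(v).is_integer() for v in vals.values()) and int(sum(vals.values())) == self.n_cases:
            return {k: int(v) for k, v in vals.items()}
        raise ValueError("stage_distribution does not specify exact counts")


@dataclass(frozen=True)
class LabeledCase:
    """A generated case: the report plus its ground-truth classification."""

    report: StructuredReport
    truth: TNMClassification

    @property
    def case_id(self) -> str:
        return self.report.case_id

    @property
    def stage(self) -> UICCStage:
        return uicc_stage(self.truth)


def _tuples_for_group(group: str) -> list[TNMClassification]:
    out = []
    for t in _GEN_T:
        for n in _GEN_N:
            for m in _GEN_M:
                c = TNMClassification(t=t, n=n, m=m)
                if uicc_stage(c).group == group:
                    out.append(c)
    return out


_GROUP_TUPLES = {g: _tuples_for_group(g) for g in ("I", "II", "III", "IV")}


def _draw_diameter(t: TCategory, rng: np.random.Generator) -> float:
    lo, hi = _T_BIN[t]
    # keep one-decimal rounding inside the open-left/closed-right bin
    d = round(float(rng.uniform(lo + 0.06, hi)), 1)
    return min(max(d, round(lo + 0.1, 1)), hi)


def _realize_t(
    t: TCategory,
    lobe: LungLobe,
    rng: np.random.Generator,
    allow_descriptor_route: bool = True,
) -> tuple[float, frozenset[InvasionDescriptor], tuple[SeparateTumorNodule, ...]]:
    """Findings whose max-rule T equals ``t`` exactly.

    T2a/T3/T4 can be realized either purely by size or by a
    descriptor/nodule floor over a smaller tumor (as in real cohorts,
    where e.g. visceral pleural invasion upgrades a small tumor).
    """
    descriptors: frozenset[InvasionDescriptor] = frozenset()
    nodules: tuple[SeparateTumorNodule, ...] = ()
    use_floor = allow_descriptor_route and t in (TCategory.T2a, TCategory.T3, TCategory.T4) and rng.random() < 0.5
    if not use_floor:
        return _draw_diameter(t, rng), descriptors, nodules
    # a diameter strictly below the floored category
    lower_bins = [c for c in _GEN_T if c.rank < t.rank]
    d = _draw_diameter(lower_bins[int(rng.integers(len(lower_bins)))], rng)
    if t is TCategory.T2a:
        descriptors = frozenset({_FLOOR_DESCRIPTORS[TFloor.AT_LEAST_T2][int(rng.integers(3))]})
    elif t is TCategory.T3:
        if rng.random() < 0.5:
            descriptors = frozenset({_FLOOR_DESCRIPTORS[TFloor.T3][int(rng.integers(len(_FLOOR_DESCRIPTORS[TFloor.T3])))]})
        else:
            nodules = (SeparateTumorNodule(lobe=lobe),)  # same lobe -> T3
    else:  # T4
        if rng.random() < 0.5:
            descriptors = frozenset({_FLOOR_DESCRIPTORS[TFloor.T4][int(rng.integers(len(_FLOOR_DESCRIPTORS[TFloor.T4])))]})
        else:
            other = [lb for lb in LungLobe if lb.side is lobe.side and lb is not lobe]
            nodules = (SeparateTumorNodule(lobe=other[int(rng.integers(len(other)))]),)
    return d, descriptors, nodules


_N1_STATIONS = [str(s) for s in range(10, 15)]
_N2_LATERAL_STATIONS = ["2", "3", "4", "8", "9"]


def _realize_n(
    n: NCategory, primary_side: Laterality, rng: np.random.Generator
) -> tuple[NodalFinding, ...]:
    """Nodal findings (in-map stations only) whose max regionality is ``n``."""
    ipsi = Side(primary_side.value)
    contra = ipsi.mirrored
    nodes: list[NodalFinding] = []
    if n is NCategory.N0:
        if rng.random() < 0.3:  # an incidental benign node
            nodes.append(NodalFinding(station="7", side=Side.MIDLINE, judged_malignant=False))
        return tuple(nodes)
    if n is NCategory.N1:
        st = _N1_STATIONS[int(rng.integers(len(_N1_STATIONS)))]
        nodes.append(NodalFinding(station=st, side=ipsi, judged_malignant=True))
    elif n is NCategory.N2:
        choices = ["7"] + _N2_LATERAL_STATIONS + (["5", "6"] if primary_side is Laterality.LEFT else [])
        st = choices[int(rng.integers(len(choices)))]
        side = Side.MIDLINE if st == "7" else (Side.LEFT if st in ("5", "6") else ipsi)
        nodes.append(NodalFinding(station=st, side=side, judged_malignant=True))
        if rng.random() < 0.5:  # concurrent hilar disease
            nodes.append(NodalFinding(station="10", side=ipsi, judged_malignant=True))
    else:  # N3
        if rng.random() < 0.4:
            side = ipsi if rng.random() < 0.5 else contra
            nodes.append(NodalFinding(station="1", side=side, judged_malignant=True))
        else:
            st = (_N2_LATERAL_STATIONS + _N1_STATIONS)[int(rng.integers(10))]
            nodes.append(NodalFinding(station=st, side=contra, judged_malignant=True))
        if rng.random() < 0.5:
            nodes.append(NodalFinding(station="7", side=Side.MIDLINE, judged_malignant=True))
    return tuple(nodes)


def _realize_m(m: MCategory, rng: np.random.Generator) -> tuple[MetastasisFinding, ...]:
    """Metastatic findings classifying exactly to ``m``."""
    if m is MCategory.M0:
        return ()
    if m is MCategory.M1a:
        site = _INTRATHORACIC_SITES[int(rng.integers(len(_INTRATHORACIC_SITES)))]
        return (MetastasisFinding(site=site, lesion_count=1),)
    if m is MCategory.M1b:
        site = _EXTRATHORACIC_SITES[int(rng.integers(len(_EXTRATHORACIC_SITES)))]
        return (MetastasisFinding(site=site, lesion_count=1),)
    # M1c: multiple extrathoracic lesions (one organ with >=2, or two organs)
    if rng.random() < 0.5:
        site = _EXTRATHORACIC_SITES[int(rng.integers(len(_EXTRATHORACIC_SITES)))]
        return (MetastasisFinding(site=site, lesion_count=int(rng.integers(2, 5))),)
    i, j = rng.choice(len(_EXTRATHORACIC_SITES), size=2, replace=False)
    return (
        MetastasisFinding(site=_EXTRATHORACIC_SITES[int(i)], lesion_count=1),
        MetastasisFinding(site=_EXTRATHORACIC_SITES[int(j)], lesion_count=1),
    )


def generate_case(
    target_stage: str,
    rng: np.random.Generator,
    case_id: str = "case",
) -> LabeledCase:
    """Generate one case whose classification lands in ``target_stage``.

    The (T, N, M) tuple is drawn uniformly from all tuples whose UICC
    group matches the target, then findings realizing exactly that
    tuple are constructed; ``classify_report`` reproduces the label by
    construction.
    """
    if target_stage not in _GROUP_TUPLES:
        raise ValueError(f"target stage group must be I/II/III/IV, got {target_stage!r}")
    tuples = _GROUP_TUPLES[target_stage]
    truth = tuples[int(rng.integers(len(tuples)))]
    lobe = list(LungLobe)[int(rng.integers(5))]
    diameter, descriptors, nodules = _realize_t(truth.t, lobe, rng)
    nodes = _realize_n(truth.n, lobe.side, rng)
    mets = _realize_m(truth.m, rng)
    report = StructuredReport(
        case_id=case_id,
        primary=PrimaryTumorFinding(lobe=lobe, diameter_cm=diameter, descriptors=descriptors),
        separate_nodules=nodules,
        nodes=nodes,
        metastases=mets,
    )
    got = classify_report(report)
    if got != truth:  # internal consistency guard; should be unreachable
        raise RuntimeError(f"generator produced {got}, wanted {truth}")
    return LabeledCase(report=report, truth=truth)


def generate_cohort(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> list[LabeledCase]:
    """Generate the full cohort with exact per-group stage counts."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = config.stage_counts
    cases: list[LabeledCase] = []
    idx = 1
    for group in ("I", "II", "III", "IV"):
        for _ in range(counts.get(group, 0)):
            cases.append(generate_case(group, rng, case_id=f"case{idx:02d}"))
            idx += 1
    return cases


# ---------------------------------------------------------------------------
# Reader simulation

_CHANNELS_BY_CATEGORY = {
    "T": ("size_measurement", "local_infiltration"),
    "N": ("anatomic_location",),
    "M": ("anatomic_location",),
}


def _neighbor(seq: Sequence, value, rng: np.random.Generator):
    """A category adjacent to ``value`` on its ladder (mismeasurements
    and mislocalizations typically shift one level)."""
    i = seq.index(value)
    if i == 0:
        return seq[1]
    if i == len(seq) - 1:
        return seq[-2]
    return seq[i + 1] if rng.random() < 0.5 else seq[i - 1]


def _perturbed_report(
    case: LabeledCase,
    erroneous: TNMClassification,
    channels: Mapping[str, Optional[str]],
    rng: np.random.Generator,
) -> StructuredReport:
    """Rebuild the report so it classifies exactly to ``erroneous``.

    Only the findings feeding a miscategorized channel are re-realized;
    correct categories keep the reference findings, so enabling a single
    channel never disturbs the other categories.
    """
    report = case.report
    primary = report.primary
    nodules = report.separate_nodules
    nodes = report.nodes
    mets = report.metastases
    if channels.get("T"):
        via_size = channels["T"] == "size_measurement"
        diameter, descriptors, new_nodules = _realize_t(
            erroneous.t, primary.lobe, rng, allow_descriptor_route=not via_size
        )
        if via_size:
            # pure mismeasurement: keep the descriptor set if it does not
            # floor above the erroneous category, else drop it
            floors_ok = all(
                (descriptor_floor(d) is TFloor.AT_LEAST_T2 and erroneous.t.rank >= TCategory.T2a.rank)
                or (descriptor_floor(d) is TFloor.T3 and erroneous.t.rank >= TCategory.T3.rank)
                or (descriptor_floor(d) is TFloor.T4 and erroneous.t.rank >= TCategory.T4.rank)
                for d in primary.descriptors
            )
            descriptors = primary.descriptors if floors_ok else frozenset()
            # nodule floors must also not exceed the erroneous T
            keep = []
            for nd in report.separate_nodules:
                if nd.lobe.side is not primary.lobe.side:
                    keep.append(nd)  # contralateral: M territory, keep
                elif nd.lobe is primary.lobe and erroneous.t.rank >= TCategory.T3.rank:
                    keep.append(nd)
                elif nd.lobe is not primary.lobe and erroneous.t.rank >= TCategory.T4.rank:
                    keep.append(nd)
            new_nodules = tuple(keep)
        else:
            new_nodules = new_nodules + tuple(
                nd for nd in report.separate_nodules if nd.lobe.side is not primary.lobe.side
            )
        primary = PrimaryTumorFinding(
            lobe=primary.lobe, diameter_cm=diameter, descriptors=descriptors, measurable=True
        )
        nodules = new_nodules
    if channels.get("N"):
        nodes = _realize_n(erroneous.n, primary.lobe.side, rng)
    if channels.get("M"):
        mets = _realize_m(erroneous.m, rng)
        # drop contralateral nodules / extrathoracic nodes only if they
        # were the M driver being re-realized
        nodules = tuple(nd for nd in nodules if nd.lobe.side is primary.lobe.side)
    return StructuredReport(
        case_id=report.case_id,
        primary=primary,
        separate_nodules=nodules,
        nodes=nodes,
        metastases=mets,
    )


def _corrupt_documentation(code: str, rng: np.random.Generator) -> str:
    """Produce an incomplete or nonexistent documented code (FTR only)."""
    parts = code.split()
    styles = []
    if parts[0] in ("T1a", "T1b", "T1c", "T2a", "T2b"):
        styles.append("t_sub")
    if parts[2].startswith("M1"):
        styles.append("m_sub")
    styles.append("m2")
    pick = styles[int(rng.integers(len(styles)))]
    if pick == "t_sub":
        parts[0] = parts[0][:2]  # "T2a" -> "T2": missing subcategory
    elif pick == "m_sub":
        parts[2] = "M1"  # missing subcategory
    else:
        parts[2] = "M2"  # nonexistent code
    return " ".join(parts)


def simulate_reader(
    case: LabeledCase,
    method: str,
    reader_effect: float,
    case_effect: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    reader_id: str = "reader",
) -> ReaderRecord:
    """Simulate one reading of ``case`` under ``method`` ("SR"/"FTR").

    Per category, the logistic correctness model decides whether an
    error is intended; an intended error is realized only through an
    enabled channel.  SR readings derive their code from the rule
    engine applied to the perturbed report; FTR readings write the code
    directly and may additionally suffer documentation corruption.
    """
    if method not in ("SR", "FTR"):
        raise ValueError(f"method must be SR or FTR, got {method!r}")
    rates = config.error_channel_rates
    truth = case.truth
    realized = {"T": truth.t, "N": truth.n, "M": truth.m}
    ladders = {"T": list(_GEN_T), "N": list(_GEN_N), "M": list(_GEN_M)}
    channels: dict[str, Optional[str]] = {"T": None, "N": None, "M": None}
    base = math.log(config.intercept_or) + (math.log(config.method_or) if method == "SR" else 0.0)
    for cat in ("T", "N", "M"):
        eta = base + config.category_effects.get(cat, 0.0) + case_effect + reader_effect
        p_correct = 1.0 / (1.0 + math.exp(-eta))
        if rng.random() < p_correct:
            continue
        weights = np.array([rates.get(ch, 0.0) for ch in _CHANNELS_BY_CATEGORY[cat]])
        if weights.sum() <= 0:
            continue  # no enabled channel can realize the error
        ch = _CHANNELS_BY_CATEGORY[cat][int(rng.choice(len(weights), p=weights / weights.sum()))]
        ladder = ladders[cat]
        current = realized[cat]
        if current not in ladder:  # e.g. a truth outside the generator set
            continue
        realized[cat] = _neighbor(ladder, current, rng)
        channels[cat] = ch
    erroneous = TNMClassification(t=realized["T"], n=realized["N"], m=realized["M"])
    if method == "SR":
        if any(channels.values()):
            perturbed = _perturbed_report(case, erroneous, channels, rng)
            reported = format_tnm(classify_report(perturbed))
        else:
            reported = format_tnm(classify_report(case.report))
    else:
        reported = format_tnm(erroneous)
        if rng.random() < rates.get("documentation", 0.0):
            reported = _corrupt_documentation(reported, rng)
    return ReaderRecord(
        reader_id=reader_id,
        case_id=case.case_id,
        method=method,
        reported_code=reported,
        reference_code=format_tnm(truth),
    )


def simulate_reader_study(
    config: SimulationConfig,
    cohort: Optional[list[LabeledCase]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the full factorial readers x cases x methods study.

    Returns the reader-study table (columns ``reader_id``, ``case_id``,
    ``method``, ``reported_code``, ``reference_code``) and the
    generative truth (parameters, per-case labels, sampled random
    effects) for parameter-recovery testing.  With ``n_missing_sr`` > 0
    that many SR readings of the first reader are dropped, mirroring
    undocumented readings.
    """
    rng = np.random.default_rng(config.seed)
    if cohort is None:
        cohort = generate_cohort(config, rng)
    reader_ids = [f"reader{i+1}" for i in range(config.n_readers)]
    reader_effects = {r: float(e) for r, e in zip(reader_ids, rng.normal(0.0, config.sd_reader, config.n_readers))}
    case_effects = {c.case_id: float(e) for c, e in zip(cohort, rng.normal(0.0, config.sd_image, len(cohort)))}
    records: list[ReaderRecord] = []
    for rid in reader_ids:
        for case in cohort:
            for method in ("SR", "FTR"):
                records.append(
                    simulate_reader(
                        case,
                        method,
                        reader_effects[rid],
                        case_effects[case.case_id],
                        config,
                        rng,
                        reader_id=rid,
                    )
                )
    df = pd.DataFrame([r.__dict__ for r in records])
    if config.n_missing_sr:
        drop_cases = [c.case_id for c in cohort[: config.n_missing_sr]]
        mask = (df["reader_id"] == reader_ids[0]) & (df["method"] == "SR") & (df["case_id"].isin(drop_cases))
        df = df[~mask].reset_index(drop=True)
    truth = {
        "config": config,
        "cases": {c.case_id: {"tnm": format_tnm(c.truth), "stage": c.stage.value} for c in cohort},
        "reader_effects": reader_effects,
        "case_effects": case_effects,
        "log_method_or": math.log(config.method_or),
    }
    return df, truth
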