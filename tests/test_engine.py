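"""Rule-engine tests: size bins, max-rule T, N/M routing, stage table,
code parsing, and staging-direction comparison — each against an
independent oracle where the rule admits one."""

import itertools

import pytest
from hypothesis import given, strategies as st

from lungstage.engine import (
    IssueKind,
    StagingDirection,
    classify_m,
    classify_n,
    classify_report,
    classify_t,
    compare_staging,
    format_tnm,
    parse_tnm_code,
    t_from_size,
    uicc_stage,
)
from lungstage.findings import (
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
    StructuredReport,
    TCategory,
    TNMClassification,
    UICCStage,
)
from lungstage.simulate import generate_case


# ---------------------------------------------------------------------------
# size bins


@pytest.mark.parametrize(
    "diameter,expected",
    [
        (4.9, TCategory.T2b),  # multiplanar measurement upgrades the axial call
        (3.9, TCategory.T2a),
        (0.8, TCategory.T1a),
        (1.0, TCategory.T1a),
        (1.1, TCategory.T1b),
        (2.0, TCategory.T1b),
        (3.0, TCategory.T1c),
        (4.0, TCategory.T2a),
        (5.0, TCategory.T2b),
        (7.0, TCategory.T3),
        (7.1, TCategory.T4),
    ],
)
def test_t_from_size_bins(diameter, expected):
    assert t_from_size(diameter) is expected


@pytest.mark.parametrize("bad", [0.0, -1.0])
def test_t_from_size_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        t_from_size(bad)


# ---------------------------------------------------------------------------
# T classification: max rule vs brute-force oracle


def oracle_t(diameter, descriptors, nodule_lobes, primary_lobe):
    """Independent max-rule enumeration of all contributing floors."""
    order = ["T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4"]
    for upper, cat in [(1, "T1a"), (2, "T1b"), (3, "T1c"), (4, "T2a"), (5, "T2b"), (7, "T3")]:
        if diameter <= upper:
            size_t = cat
            break
    else:
        size_t = "T4"
    floors = [size_t]
    floor_of = {
        "visceral_pleura_invasion": "T2a", "main_bronchus_involvement": "T2a",
        "atelectasis_or_obstructive_pneumonitis": "T2a",
        "chest_wall": "T3", "parietal_pleura": "T3", "phrenic_nerve": "T3",
        "parietal_pericardium": "T3",
        "diaphragm": "T4", "mediastinum": "T4", "heart": "T4", "great_vessels": "T4",
        "trachea": "T4", "carina": "T4", "recurrent_laryngeal_nerve": "T4",
        "esophagus": "T4", "vertebral_body": "T4",
    }
    floors += [floor_of[d] for d in descriptors]
    for lobe in nodule_lobes:
        if lobe[0] != primary_lobe[0]:  # first letter encodes the side
            continue
        floors.append("T3" if lobe == primary_lobe else "T4")
    return max(floors, key=order.index)


_DESC_SUBSETS = [
    frozenset(),
    frozenset({InvasionDescriptor.VISCERAL_PLEURA_INVASION}),
    frozenset({InvasionDescriptor.CHEST_WALL}),
    frozenset({InvasionDescriptor.MEDIASTINUM}),
    frozenset({InvasionDescriptor.VISCERAL_PLEURA_INVASION, InvasionDescriptor.CHEST_WALL}),
    frozenset({InvasionDescriptor.MAIN_BRONCHUS_INVOLVEMENT, InvasionDescriptor.ESOPHAGUS}),
]
_NODULE_PLACEMENTS = [(), (LungLobe.RUL,), (LungLobe.RLL,), (LungLobe.LUL,), (LungLobe.RUL, LungLobe.LLL)]


def test_classify_t_matches_bruteforce_oracle():
    diameters = [0.8, 1.5, 2.9, 3.5, 4.9, 6.0, 8.0]
    primary_lobe = LungLobe.RUL  # right-sided primary
    for d, descs, nodules in itertools.product(diameters, _DESC_SUBSETS, _NODULE_PLACEMENTS):
        primary = PrimaryTumorFinding(lobe=primary_lobe, diameter_cm=d, descriptors=descs)
        got = classify_t(primary, tuple(SeparateTumorNodule(lobe=lb) for lb in nodules))
        want = oracle_t(d, {x.value for x in descs}, [lb.value for lb in nodules], primary_lobe.value)
        assert got.value == want, (d, descs, nodules)


def test_classify_t_pleural_invasion_upgrades_small_tumor():
    primary = PrimaryTumorFinding(
        lobe=LungLobe.RUL, diameter_cm=2.9,
        descriptors=frozenset({InvasionDescriptor.VISCERAL_PLEURA_INVASION}),
    )
    assert classify_t(primary) is TCategory.T2a  # size alone would be T1c


def test_classify_t_at_least_t2_floor_never_gives_t2b():
    # the floor resolves to T2a; only size reaches T2b
    primary = PrimaryTumorFinding(
        lobe=LungLobe.RUL, diameter_cm=0.9,
        descriptors=frozenset({InvasionDescriptor.MAIN_BRONCHUS_INVOLVEMENT}),
    )
    assert classify_t(primary) is TCategory.T2a


def test_classify_t_unmeasurable_is_tx():
    primary = PrimaryTumorFinding(lobe=LungLobe.RUL, measurable=False)
    assert classify_t(primary) is TCategory.TX


# ---------------------------------------------------------------------------
# N and M


def test_classify_n_axillary_node_is_not_regional(axillary_node_report):
    assert classify_n(axillary_node_report.nodes, Laterality.RIGHT) is NCategory.N0


def test_classify_n_max_over_resolved_classes():
    nodes = (
        NodalFinding(station="10", side="right", judged_malignant=True),   # ipsi N1
        NodalFinding(station="4", side="left", judged_malignant=True),     # contra N3
    )
    assert classify_n(nodes, Laterality.RIGHT) is NCategory.N3
    assert classify_n(nodes[:1], Laterality.RIGHT) is NCategory.N1


def test_classify_n_benign_nodes_do_not_count():
    nodes = (NodalFinding(station="7", side="midline", judged_malignant=False),)
    assert classify_n(nodes, Laterality.LEFT) is NCategory.N0


@pytest.mark.parametrize(
    "mets,nodes,nodules,expected",
    [
        ((), (), (), MCategory.M0),
        ((MetastasisFinding(site=MetastasisSite.PLEURAL_NODULE),), (), (), MCategory.M1a),
        ((), (), (SeparateTumorNodule(lobe=LungLobe.LUL),), MCategory.M1a),  # contralateral
        ((MetastasisFinding(site=MetastasisSite.ADRENAL),), (), (), MCategory.M1b),
        ((MetastasisFinding(site=MetastasisSite.ADRENAL),
          MetastasisFinding(site=MetastasisSite.BONE)), (), (), MCategory.M1c),
        ((MetastasisFinding(site=MetastasisSite.BRAIN, lesion_count=3),), (), (), MCategory.M1c),
        # single extrathoracic node: distant disease, one lesion -> M1b
        ((), (NodalFinding(station="axillary", side="right"),), (), MCategory.M1b),
    ],
)
def test_classify_m(mets, nodes, nodules, expected):
    assert classify_m(mets, nodes, nodules, Laterality.RIGHT) is expected


def test_classify_report_axillary_node_composition(axillary_node_report):
    c = classify_report(axillary_node_report)
    assert format_tnm(c) == "T1c N0 M1b"
    assert uicc_stage(c) is UICCStage.IVA


def test_classify_report_minimal():
    r = StructuredReport(
        case_id="tiny", primary=PrimaryTumorFinding(lobe=LungLobe.LLL, diameter_cm=0.9)
    )
    assert format_tnm(classify_report(r)) == "T1a N0 M0"


# ---------------------------------------------------------------------------
# UICC stage table

_FULL_T = [TCategory.T1a, TCategory.T1b, TCategory.T1c, TCategory.T2a, TCategory.T2b,
           TCategory.T3, TCategory.T4]
_FULL_N = [NCategory.N0, NCategory.N1, NCategory.N2, NCategory.N3]
_FULL_M = list(MCategory)


def test_stage_table_total_on_fully_specified_tuples():
    for t, n, m in itertools.product(_FULL_T, _FULL_N, _FULL_M):
        s = uicc_stage(TNMClassification(t=t, n=n, m=m))
        assert s is not UICCStage.UNDEFINED


@pytest.mark.parametrize(
    "code,stage",
    [
        ("T1c N0 M0", UICCStage.IA3),
        ("T2b N1 M0", UICCStage.IIB),
        ("T1a N0 M0", UICCStage.IA1),
        ("T2a N0 M0", UICCStage.IB),
        ("T3 N0 M0", UICCStage.IIB),
        ("T4 N0 M0", UICCStage.IIIA),
        ("T1b N2 M0", UICCStage.IIIA),
        ("T3 N2 M0", UICCStage.IIIB),
        ("T2a N3 M0", UICCStage.IIIB),
        ("T4 N3 M0", UICCStage.IIIC),
        ("T1a N0 M1a", UICCStage.IVA),
        ("TX N0 M0", UICCStage.OCCULT),
        ("Tis N0 M0", UICCStage.STAGE_0),
        ("T1mi N0 M0", UICCStage.IA1),
        ("TX N1 M0", UICCStage.UNDEFINED),
        ("T1a NX M0", UICCStage.UNDEFINED),
    ],
)
def test_stage_lookup(code, stage):
    c, validity = parse_tnm_code(code)
    assert validity.valid
    assert uicc_stage(c) is stage


def test_m1c_overrides_everything():
    for t, n in itertools.product(_FULL_T, _FULL_N):
        assert uicc_stage(TNMClassification(t=t, n=n, m=MCategory.M1c)) is UICCStage.IVB


# ---------------------------------------------------------------------------
# parsing / formatting


@pytest.mark.parametrize(
    "text,category,kind",
    [
        ("T2 N0 M0", "T", IssueKind.MISSING_SUBCATEGORY),
        ("T1a N0 M2", "M", IssueKind.NONEXISTENT_CODE),
        ("T1a N0 M1", "M", IssueKind.MISSING_SUBCATEGORY),
        ("T1 N0 M0", "T", IssueKind.MISSING_SUBCATEGORY),
        ("T5 N0 M0", "T", IssueKind.NONEXISTENT_CODE),
        ("T1a N7 M0", "N", IssueKind.NONEXISTENT_CODE),
    ],
)
def test_parse_flags_invalid_codes(text, category, kind):
    parsed, validity = parse_tnm_code(text)
    assert parsed is None and not validity.valid
    assert any(i.category == category and i.kind is kind for i in validity.issues)


def test_parse_garbage_is_unparseable_not_an_exception():
    parsed, validity = parse_tnm_code("follow-up recommended")
    assert parsed is None
    assert {i.kind for i in validity.issues} == {IssueKind.UNPARSEABLE}


@pytest.mark.parametrize("text", ["t2b n1 m0", "T2b/N1/M0", "T2b, N1, M0", "T2bN1M0"])
def test_parse_is_tolerant_to_case_and_separators(text):
    parsed, validity = parse_tnm_code(text)
    assert validity.valid
    assert format_tnm(parsed) == "T2b N1 M0"


@given(
    t=st.sampled_from(list(TCategory)),
    n=st.sampled_from(list(NCategory)),
    m=st.sampled_from(list(MCategory)),
)
def test_format_parse_round_trip(t, n, m):
    c = TNMClassification(t=t, n=n, m=m)
    parsed, validity = parse_tnm_code(format_tnm(c))
    assert validity.valid and parsed == c


# ---------------------------------------------------------------------------
# staging comparison


def test_compare_missed_invasion_is_downstaged():
    reader, _ = parse_tnm_code("T1c N0 M0")
    reference, _ = parse_tnm_code("T2a N0 M0")
    cmp = compare_staging(reader, reference)
    assert cmp.direction is StagingDirection.DOWNSTAGED
    assert not cmp.t_match and cmp.n_match and cmp.m_match


def test_compare_equal_ordinal_different_tuple_is_lateral():
    reader, _ = parse_tnm_code("T2a N1 M0")   # IIB
    reference, _ = parse_tnm_code("T2b N1 M0")  # IIB
    assert compare_staging(reader, reference).direction is StagingDirection.LATERAL


def test_compare_matches_ordinal_oracle_on_full_table():
    tuples = [TNMClassification(t=t, n=n, m=m)
              for t, n, m in itertools.product(_FULL_T, _FULL_N, _FULL_M)]
    stages = {format_tnm(c): uicc_stage(c).ordinal for c in tuples}
    for a in tuples[::7]:
        for b in tuples[::5]:
            cmp = compare_staging(a, b)
            sa, sb = stages[format_tnm(a)], stages[format_tnm(b)]
            if a == b:
                assert cmp.direction is StagingDirection.CONCORDANT
            elif sa > sb:
                assert cmp.direction is StagingDirection.UPSTAGED
            elif sa < sb:
                assert cmp.direction is StagingDirection.DOWNSTAGED
            else:
                assert cmp.direction in (StagingDirection.LATERAL, StagingDirection.CONCORDANT)


def test_compare_rejects_undefined_stage():
    nx, _ = parse_tnm_code("T1a NX M0")
    ok, _ = parse_tnm_code("T1a N0 M0")
    with pytest.raises(ValueError):
        compare_staging(nx, ok)


# ---------------------------------------------------------------------------
# monotonicity: adding a finding never lowers T, N, M, or the stage ordinal


def _augmented(report, rng):
    kind = rng.integers(4)
    if kind == 0:
        d = list(InvasionDescriptor)[int(rng.integers(len(InvasionDescriptor)))]
        primary = report.primary.model_copy(update={"descriptors": report.primary.descriptors | {d}})
        return report.model_copy(update={"primary": primary})
    if kind == 1:
        lobe = list(LungLobe)[int(rng.integers(5))]
        return report.model_copy(update={"separate_nodules": report.separate_nodules + (SeparateTumorNodule(lobe=lobe),)})
    if kind == 2:
        stations = [("7", "midline"), ("4", "left"), ("10", "right"), ("1", "left"), ("axillary", "right")]
        stn, side = stations[int(rng.integers(len(stations)))]
        nf = NodalFinding(station=stn, side=side, judged_malignant=True)
        return report.model_copy(update={"nodes": report.nodes + (nf,)})
    site = list(MetastasisSite)[int(rng.integers(len(MetastasisSite)))]
    return report.model_copy(update={"metastases": report.metastases + (MetastasisFinding(site=site),)})


def test_monotonicity_under_finding_addition(rng):
    for _ in range(300):
        group = ("I", "II", "III", "IV")[int(rng.integers(4))]
        base = generate_case(group, rng, case_id="mono").report
        before = classify_report(base)
        after = classify_report(_augmented(base, rng))
        assert after.t.rank >= before.t.rank
        assert after.n.rank >= before.n.rank
        assert after.m.rank >= before.m.rank
        assert uicc_stage(after).ordinal >= uicc_stage(before).ordinal
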