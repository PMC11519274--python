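"""Evaluation-layer tests: scoring, summaries, error attribution,
Fleiss kappa (hand-worked oracle), Sidak, latent-scale ICC."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lungstage.evaluation import (
    ReaderRecord,
    attribute_t_error,
    fleiss_kappa,
    latent_icc,
    round_pct,
    score_records,
    sidak_adjust,
    summarize,
)


def _rec(reported, reference, method="SR", reader="r1", case="c1"):
    return ReaderRecord(reader_id=reader, case_id=case, method=method,
                        reported_code=reported, reference_code=reference)


HAND_SCORED = [
    # reported, reference, t_ok, n_ok, m_ok, doc_err, direction
    ("T2a N0 M0", "T2a N0 M0", True, True, True, False, "concordant"),
    ("T1c N0 M0", "T2a N0 M0", False, True, True, False, "downstaged"),
    ("T2 N0 M0", "T2a N0 M0", False, True, True, True, "undefined"),
    ("T1a N0 M2", "T1a N0 M0", True, True, False, True, "undefined"),
    ("T2a N1 M0", "T2b N1 M0", False, True, True, False, "lateral"),
    ("T1a N3 M0", "T1a N0 M0", True, False, True, False, "upstaged"),
]


def test_score_records_hand_scored_fixture():
    records = [_rec(rep, ref, case=f"c{i}") for i, (rep, ref, *_rest) in enumerate(HAND_SCORED)]
    scored = score_records(records)
    for i, (_rep, _ref, t_ok, n_ok, m_ok, doc, direction) in enumerate(HAND_SCORED):
        row = scored.iloc[i]
        assert row.t_correct == t_ok and row.n_correct == n_ok and row.m_correct == m_ok
        assert row.documentation_error == doc
        assert row.direction == direction
        assert row.aggregate_correct == (t_ok and n_ok and m_ok)


def test_score_records_rejects_dirty_reference():
    with pytest.raises(ValueError, match="reference"):
        score_records([_rec("T1a N0 M0", "T2 N0 M0")])


def test_summarize_conserves_counts():
    records = [_rec(rep, ref, method=("SR" if i % 2 else "FTR"), case=f"c{i}")
               for i, (rep, ref, *_r) in enumerate(HAND_SCORED * 3)]
    scored = score_records(records)
    summary = summarize(scored)
    assert summary.n_records == len(records)
    for method, ms in summary.per_method.items():
        assert ms.n_records == (scored.method == method).sum()
        assert ms.concordant + ms.upstaged + ms.downstaged + ms.lateral + ms.undefined_direction == ms.n_records
        assert ms.aggregate_correct <= ms.n_records


def test_summarize_all_correct_table():
    records = [_rec("T1a N0 M0", "T1a N0 M0", method=m, case=f"c{i}")
               for i in range(5) for m in ("SR", "FTR")]
    summary = summarize(score_records(records))
    for ms in summary.per_method.values():
        assert ms.aggregate_pct == 100.0
        assert ms.upstaged == ms.downstaged == 0
        assert ms.concordant == ms.n_records


def test_summarize_rejects_empty():
    with pytest.raises(ValueError):
        summarize(pd.DataFrame())


def test_round_pct_half_up_matches_printed_convention():
    assert round_pct(128, 178) == 71.9
    assert round_pct(1, 8) == 12.5
    assert round_pct(1, 3) == 33.3


# ---------------------------------------------------------------------------
# error attribution


def test_attribute_size_measurement(size_mismeasure_reports):
    reader, reference = size_mismeasure_reports
    assert attribute_t_error(reader, reference) == {"size_measurement"}


def test_attribute_local_infiltration(pleural_invasion_reports):
    reader, reference = pleural_invasion_reports
    assert attribute_t_error(reader, reference) == {"local_infiltration"}


def test_attribute_identical_reports_is_empty(axillary_node_report):
    assert attribute_t_error(axillary_node_report, axillary_node_report) == set()


def test_attribute_anatomic_location(axillary_node_report):
    moved = axillary_node_report.model_copy(update={"nodes": ()})
    assert attribute_t_error(moved, axillary_node_report) == {"anatomic_location"}


# ---------------------------------------------------------------------------
# Fleiss kappa


def test_fleiss_kappa_hand_worked_matrix():
    # items x raters: per-item category counts give P_1=1, P_2=1, P_3=1/3
    # -> Pbar=7/9; marginals p_A=5/9, p_B=4/9 -> Pe=41/81;
    # kappa = (7/9 - 41/81)/(1 - 41/81) = 22/40 = 0.55
    ratings = [["A", "A", "A"], ["B", "B", "B"], ["A", "A", "B"]]
    res = fleiss_kappa(ratings)
    assert res.kappa == pytest.approx(0.55, abs=1e-12)
    assert (res.n_items, res.n_raters, res.n_categories) == (3, 3, 2)


def test_fleiss_kappa_perfect_agreement_multiple_categories():
    ratings = [["A", "A"], ["B", "B"], ["C", "C"]]
    assert fleiss_kappa(ratings).kappa == pytest.approx(1.0)


def test_fleiss_kappa_degenerate_single_category():
    res = fleiss_kappa([["A", "A"], ["A", "A"]])
    assert res.kappa == 1.0 and res.degenerate


def test_fleiss_kappa_invariances():
    rng = np.random.default_rng(7)
    ratings = rng.choice(["X", "Y", "Z"], size=(8, 4))
    base = fleiss_kappa(ratings).kappa
    # rater exchangeability
    assert fleiss_kappa(ratings[:, ::-1]).kappa == pytest.approx(base)
    # category relabeling
    relabeled = np.vectorize({"X": "c1", "Y": "c2", "Z": "c3"}.get)(ratings)
    assert fleiss_kappa(relabeled).kappa == pytest.approx(base)


def test_fleiss_kappa_rejects_tiny_input():
    with pytest.raises(ValueError):
        fleiss_kappa([["A", "B"]])


# ---------------------------------------------------------------------------
# Sidak and latent ICC


@pytest.mark.parametrize(
    "p,m,expected",
    [(0.03, 1, 0.03), (0.0, 3, 0.0), (0.02, 3, 1 - 0.98**3), (1.0, 5, 1.0)],
)
def test_sidak_values(p, m, expected):
    assert sidak_adjust([p], m=m)[0] == pytest.approx(expected, abs=1e-12)


def test_sidak_monotone_in_p_and_m():
    ps = [0.0, 0.01, 0.05, 0.2, 0.9]
    for m in (1, 2, 5):
        adj = sidak_adjust(ps, m=m)
        assert adj == sorted(adj)
    for p in ps:
        vals = [sidak_adjust([p], m=m)[0] for m in range(1, 6)]
        assert vals == sorted(vals)


def test_sidak_rejects_out_of_range():
    with pytest.raises(ValueError):
        sidak_adjust([1.2])


def test_latent_icc_printed_variance_components():
    icc = latent_icc({"image": 1.273, "reader": 0.023})
    assert round(icc["image"], 3) == 0.278
    assert round(100 * icc["reader"], 1) == 0.5


def test_latent_icc_zero_and_negative():
    assert latent_icc({"a": 0.0, "b": 0.0}) == {"a": 0.0, "b": 0.0}
    with pytest.raises(ValueError):
        latent_icc({"a": -0.1})


def test_latent_icc_sums_strictly_below_one():
    rng = np.random.default_rng(3)
    for _ in range(50):
        comps = {f"g{i}": float(v) for i, v in enumerate(rng.gamma(1.0, 2.0, size=3))}
        total = sum(latent_icc(comps).values())
        assert 0.0 <= total < 1.0
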