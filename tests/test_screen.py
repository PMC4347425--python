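"""Plate-screen quantification: response formula, hits, potency, QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orscout.screen import (
    aggregate_replicates,
    call_hit,
    compute_response,
    hit_calls,
    lowest_effective_concentration,
    normalize_profile,
    potency_matrix,
    qc_plate,
    response_table,
    summarize_screen,
)
from orscout.synthetic import (
    demo_agonist_truth,
    expected_potency_class,
    simulate_plate_dataset,
)


@pytest.mark.parametrize(
    "terms,expected",
    [
        ((8e5, 1e5, 2e5, 1e5), 6e5),
        ((5e5, 5e5, 5e5, 5e5), 0.0),
        ((1e5, 2e5, 3e5, 1e5), -3e5),  # negative responses preserved
    ],
)
def test_response_formula(terms, expected):
    assert compute_response(*terms) == pytest.approx(expected)


def test_response_requires_all_terms():
    with pytest.raises(ValueError):
        compute_response(1e5, float("nan"), 1e5, 1e5)


@given(
    f=st.tuples(*[st.floats(0, 1e6) for _ in range(4)]),
    offset=st.floats(-1e5, 1e6),
)
@settings(max_examples=200, derandomize=True)
def test_plate_wide_offset_cancels(f, offset):
    base = compute_response(*f)
    shifted = compute_response(*(x + offset for x in f))
    assert shifted == pytest.approx(base, abs=1e-6 * max(1.0, abs(base)))


@pytest.mark.parametrize(
    "r,hit",
    [
        (3.0e5, False),  # exactly at threshold: strict inequality
        (3.1e5, True),
        (-5e5, False),
        (3.0e5 + 1, True),
    ],
)
def test_hit_threshold_strict(r, hit):
    assert call_hit(r) is hit


def test_hit_monotone_in_or_odorant_signal():
    rng = np.random.default_rng(4)
    for _ in range(100):
        f = rng.uniform(0, 1e6, 4)
        bump = rng.uniform(0, 1e6)
        r0 = compute_response(*f)
        r1 = compute_response(f[0] + bump, f[1], f[2], f[3])
        if call_hit(r0):
            assert call_hit(r1)  # raising the OR+odorant term never unmakes a hit


def test_aggregate_replicates():
    mean, sem, n = aggregate_replicates([4.0, 6.0])
    assert (mean, sem, n) == (5.0, pytest.approx(1.0), 2)
    mean, sem, n = aggregate_replicates([5.0])
    assert (mean, sem, n) == (5.0, None, 1)


def test_aggregate_mean_converges():
    rng = np.random.default_rng(8)
    draws = rng.normal(5.0, 1.0, 10_000)
    mean, sem, n = aggregate_replicates(draws)
    assert abs(mean - 5.0) < 3.0 / np.sqrt(n)
    assert sem == pytest.approx(1.0 / np.sqrt(n), rel=0.1)


def test_normalize_profile():
    out = normalize_profile({"a": 2e5, "b": 6e5, "c": 3e5})
    assert out == pytest.approx({"a": 100 / 3, "b": 100.0, "c": 50.0})
    assert normalize_profile({"only": 4e5}) == {"only": 100.0}
    neg = normalize_profile({"a": 6e5, "b": -3e5})
    assert neg["b"] == pytest.approx(-50.0)  # negatives kept, not clipped
    with pytest.raises(ValueError):
        normalize_profile({"a": -1.0, "b": 0.0})


@pytest.mark.parametrize(
    "flags,lec,potency",
    [
        ({10.0: True, 100.0: True, 1000.0: True}, 10.0, "high"),
        ({10.0: False, 100.0: True, 1000.0: True}, 100.0, "mid"),
        ({10.0: False, 100.0: False, 1000.0: True}, 1000.0, "low"),
        ({10.0: False, 100.0: False, 1000.0: False}, None, "none"),
    ],
)
def test_lowest_effective_concentration(flags, lec, potency):
    assert lowest_effective_concentration(flags) == (lec, potency)


@pytest.mark.parametrize("frac,passed", [(0.70, True), (0.69, False), (1.0, True)])
def test_qc_boundary_inclusive(frac, passed):
    assert qc_plate("p1", frac).passed is passed


def test_qc_fraction_validated():
    with pytest.raises(ValueError):
        qc_plate("p1", 1.2)


def test_noiseless_screen_recovers_planted_effects_exactly():
    truth_map = {("OR1", "odA"): ("potent", 6e5)}
    wells, _ = simulate_plate_dataset(
        ["OR1", "OR2"], ["odA"], truth_map, noise_sd_AU=0.0, seed=0
    )
    resp, qc = response_table(wells)
    assert all(q.passed for q in qc)
    r = resp.set_index(["or_name", "concentration_uM"])["R_AU"]
    assert r[("OR1", 1000.0)] == pytest.approx(6e5)
    assert r[("OR1", 100.0)] == pytest.approx(5.4e5)
    assert r[("OR1", 10.0)] == pytest.approx(3.6e5)
    assert r[("OR2", 1000.0)] == pytest.approx(0.0)  # non-agonist: exactly zero
    calls = {(c.or_name, c.odorant): c for c in hit_calls(resp)}
    assert calls[("OR1", "odA")].potency_class == "high"
    assert calls[("OR1", "odA")].lowest_effective_concentration_uM == 10.0
    assert calls[("OR2", "odA")].potency_class == "none"


def test_missing_condition_is_not_evaluable_never_zero():
    truth_map = {("OR1", "odA"): ("potent", 6e5)}
    wells, _ = simulate_plate_dataset(["OR1"], ["odA"], truth_map, noise_sd_AU=0.0)
    wells = wells[~((wells.construct == "empty_vector") & (wells.concentration_uM == 10.0))]
    resp, _ = response_table(wells)
    row = resp[(resp.or_name == "OR1") & (resp.concentration_uM == 10.0)].iloc[0]
    assert not row.evaluable
    assert np.isnan(row.R_AU)


def test_failing_plate_excluded_from_responses():
    truth_map = {("OR1", "odA"): ("potent", 6e5)}
    wells, _ = simulate_plate_dataset(
        ["OR1"], ["odA", "odB"], truth_map, noise_sd_AU=0.0, gfp_fraction=0.95
    )
    wells.loc[
        (wells.plate_id == "plate001") & (wells.construct == "gfp_control"),
        "gfp_fraction",
    ] = 0.5
    resp, qc = response_table(wells)
    failed = {q.plate_id: q.passed for q in qc}
    assert failed["plate001"] is False and failed["plate002"] is True
    assert (resp["plate_id"] != "plate001").all()


def test_tagged_and_untagged_tracked_separately():
    truth_map = {("OR1", "odA"): ("potent", 6e5)}
    wells, _ = simulate_plate_dataset(
        ["OR1"], ["odA"], truth_map, noise_sd_AU=0.0,
        rho_tagged_states=(False, True),
    )
    resp, _ = response_table(wells)
    assert set(resp["rho_tagged"]) == {False, True}
    mat = potency_matrix(hit_calls(resp))
    assert ("OR1", False) in mat.index and ("OR1", True) in mat.index


def test_replicate_sem_reported():
    truth_map = {("OR1", "odA"): ("potent", 6e5)}
    wells, _ = simulate_plate_dataset(
        ["OR1"], ["odA"], truth_map, noise_sd_AU=2e4, n_replicates=2, seed=5
    )
    resp, _ = response_table(wells)
    ev = resp[resp.evaluable]
    assert (ev["n_replicates"] == 2).all()
    assert ev["sem_AU"].notna().all()
    assert (ev["sem_AU"] >= 0).all()


def test_potency_matrix_equals_truth_under_strong_signal():
    """Exact recovery of the planted potency matrix when effects are 3x the
    threshold and noise is a tenth of it."""
    ors = [f"OR{i}" for i in range(1, 10)]
    ods = [f"od{i:02d}" for i in range(1, 38)]
    truth_map = {
        pair: (potency, 9e5)
        for pair, (potency, _) in demo_agonist_truth(ors, ods).items()
    }
    wells, truth = simulate_plate_dataset(ors, ods, truth_map, noise_sd_AU=3e4, seed=13)
    resp, _ = response_table(wells)
    calls = {(c.or_name, c.odorant): c.potency_class for c in hit_calls(resp)}
    for a in truth.agonists:
        want = expected_potency_class(a.true_potency_class, a.effect_size_AU)
        assert calls[(a.or_name, a.odorant)] == want


def test_screen_summary_counts_match_generator_truth(demo_screen):
    wells, truth, truth_map = demo_screen
    resp, _ = response_table(wells)
    s = summarize_screen(hit_calls(resp))
    true_responding = {od for (_, od) in truth_map}
    assert s.n_odorants_responding == len(true_responding) == 14
    assert s.n_odorants_hit_at_10uM == 9
    assert s.n_ors_hit_at_10uM == 5
    assert s.n_ors_responding == 9


def test_empty_hit_table_summary():
    s = summarize_screen([])
    assert (s.n_odorants_responding, s.n_odorants_hit_at_10uM) == (0, 0)


def test_tuning_breadth_counts_odorants_hit():
    wells, truth, truth_map = (
        simulate_plate_dataset(
            ["ORb"],
            ["od1", "od2", "od3"],
            {("ORb", od): ("potent", 9e5) for od in ["od1", "od2", "od3"]},
            noise_sd_AU=0.0,
        )[0],
        None,
        None,
    )
    resp, _ = response_table(wells)
    s = summarize_screen(hit_calls(resp))
    assert s.tuning_breadth[("ORb", False)] == 3
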