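"""Reactivity propagation, enrichment, exact tests, antibody index,
subclass accounting, BCR features and privacy search."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import bcrcsf as b
from bcrcsf.clones import Clone
from bcrcsf.germline import ChainRecord, ReceptorCell, ValidationError
from bcrcsf.specificity import (
    ConflictError,
    adjusted_specificity,
    antibody_index,
    cdr3_charge,
    closest_identity,
    correlate_mutations_affinity,
    fisher_exact,
    gene_family,
    igg4_ratio,
    propagate_reactivity,
    stratify_by_clone_size,
    subclass_switch_summary,
    synthetic_cdr_reference,
)


def _clone(members, founder=None):
    return Clone("cl", sorted(members), "IGHV1-2", "IGHJ4", 12, founder=founder)


# -- reactivity propagation --------------------------------------------------


def test_propagation_fills_untested_members():
    labels, had = propagate_reactivity(
        _clone(["a", "b", "c"]), {"a": "LGI1", "b": "untested", "c": "untested"})
    assert labels == {"a": "LGI1", "b": "LGI1", "c": "LGI1"} and had


def test_propagation_leaves_untested_clone_flagged():
    labels, had = propagate_reactivity(_clone(["a", "b"]), {"a": "untested"})
    assert not had and set(labels.values()) == {"untested"}


def test_conflicting_tested_labels_raise():
    with pytest.raises(ConflictError, match="cl"):
        propagate_reactivity(_clone(["a", "b"]), {"a": "LGI1", "b": "negative"})


def test_propagation_never_changes_tested_labels():
    labels, _ = propagate_reactivity(
        _clone(["a", "b"]), {"a": "negative", "b": "untested"})
    assert labels["a"] == "negative"


# -- Fisher exact ------------------------------------------------------------


def test_fisher_small_table_full_enumeration():
    res = fisher_exact([[3, 1], [1, 9]])
    assert res.p_two_sided == pytest.approx(41 / 1001, rel=1e-12)
    assert res.odds_ratio == pytest.approx(27.0)


def test_fisher_symmetric_table_is_one():
    assert fisher_exact([[1, 1], [1, 1]]).p_two_sided == 1.0


def test_fisher_large_effect_table():
    assert fisher_exact([[114, 17], [4, 10]]).p_two_sided < 0.001


def test_fisher_rejects_zero_margin():
    with pytest.raises(ValidationError):
        fisher_exact([[0, 0], [1, 2]])


def test_fisher_infinite_odds():
    assert math.isinf(fisher_exact([[5, 0], [1, 5]]).odds_ratio)


def test_fisher_agrees_with_scipy_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, bb, c, d = rng.integers(0, 30, 4)
        if min(a + bb, c + d, a + c, bb + d) == 0:
            continue
        mine = fisher_exact([[a, bb], [c, d]]).p_two_sided
        ref = scipy.stats.fisher_exact([[a, bb], [c, d]]).pvalue
        assert mine == pytest.approx(ref, abs=1e-12)


# -- enrichment --------------------------------------------------------------


def _cells(ids, donor="donor1"):
    return [
        ReceptorCell(cell_id=i, heavy=ChainRecord(i, "IGH", "ACGT" * 20, junction=""),
                     donor=donor)
        for i in ids
    ]


def test_stratified_rates():
    ids = [f"s{i}" for i in range(10)]
    cells = _cells(ids)
    clones = [_clone([i]) for i in ids]
    labels = {i: ("LGI1" if k < 6 else "negative") for k, i in enumerate(ids)}
    summary = stratify_by_clone_size(cells, clones, labels)
    assert summary.per_category["singleton"]["rate"] == pytest.approx(0.6)
    assert summary.per_category["small"]["rate"] is None
    assert summary.per_category["large"]["rate"] is None


def test_fully_reactive_large_clones_rate_one(fitted):
    assert fitted.enrichment.per_category["large"]["rate"] == 1.0


def test_adjusted_specificity_formula():
    assert adjusted_specificity(100, 120, 40, 0.6) == pytest.approx((100 + 24) / 160)
    assert adjusted_specificity(10, 20, 0, 0.9) == pytest.approx(0.5)
    assert adjusted_specificity(10, 20, 10, 0.0) == pytest.approx(10 / 30)
    with pytest.raises(ValidationError):
        adjusted_specificity(0, 0, 0, 0.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    n_reactive=st.integers(0, 50),
    extra_tested=st.integers(0, 50),
    n_untested=st.integers(0, 100),
    r1=st.floats(0, 1),
    r2=st.floats(0, 1),
)
def test_adjusted_specificity_monotone_and_bounded(n_reactive, extra_tested,
                                                   n_untested, r1, r2):
    n_tested = n_reactive + extra_tested
    if n_tested + n_untested == 0:
        return
    lo, hi = sorted([r1, r2])
    a_lo = adjusted_specificity(n_reactive, n_tested, n_untested, lo)
    a_hi = adjusted_specificity(n_reactive, n_tested, n_untested, hi)
    assert a_lo <= a_hi + 1e-12
    if n_tested:
        unadjusted = n_reactive / n_tested
        assert min(unadjusted, lo) - 1e-12 <= a_lo <= max(unadjusted, lo) + 1e-12


def test_enrichment_recovers_simulated_gradient(library):
    cfg = b.SimConfig(seed=5, n_clones=500)
    cells, _ = b.simulate_repertoire(library, cfg)
    res = b.RepertoireAnalysis(cells, library).fit()
    pc = res.enrichment.per_category
    assert pc["large"]["rate"] == 1.0
    for cat, p in [("singleton", 0.6), ("small", 0.8)]:
        n, rate = pc[cat]["n_tested"], pc[cat]["rate"]
        half_ci = 1.96 * math.sqrt(p * (1 - p) / n)
        assert abs(rate - p) <= half_ci + 0.02


# -- antibody index and subclass ratios --------------------------------------


def test_antibody_index_arithmetic():
    res = antibody_index(10, 2, 5, 500)
    assert res.value == pytest.approx(500.0) and res.intrathecal


def test_antibody_index_equal_ratios_not_intrathecal():
    res = antibody_index(3, 3, 7, 7)
    assert res.value == pytest.approx(1.0) and not res.intrathecal


def test_antibody_index_cutoff_is_strict():
    assert not antibody_index(4, 1, 1, 1).intrathecal
    assert antibody_index(4.001, 1, 1, 1).intrathecal


def test_antibody_index_scale_invariance():
    base = antibody_index(10, 2, 5, 500).value
    scaled = antibody_index(10 * 37.5, 2 * 37.5, 5, 500).value
    assert scaled == pytest.approx(base)


def test_antibody_index_rejects_nonpositive():
    with pytest.raises(ValidationError):
        antibody_index(0, 1, 1, 1)


def test_igg4_ratio():
    assert igg4_ratio({"IGHG1": 3, "IGHG2": 0, "IGHG3": 0, "IGHG4": 97}) == pytest.approx(0.97)
    assert igg4_ratio({"IGHG4": 5}) == 1.0
    assert igg4_ratio({"IGHG1": 5}) == 0.0
    with pytest.raises(ValidationError):
        igg4_ratio({})


# -- subclass switching ------------------------------------------------------


def test_subclass_counts_and_downstream_switch():
    clones = [
        _clone(["a", "b"], founder="a"),
        _clone(["c", "d"], founder="c"),
    ]
    calls = {"a": "IGHG4", "b": "IGHG4", "c": "IGHG1", "d": "IGHG4"}
    res = subclass_switch_summary(clones, calls)
    assert res.n_one_subclass == 1 and res.n_two_subclasses == 1
    assert res.violations == []


def test_upstream_switch_is_flagged():
    clones = [_clone(["a", "b"], founder="a")]
    res = subclass_switch_summary(clones, {"a": "IGHG2", "b": "IGHG3"})
    assert res.violations == [("cl", "IGHG2", "IGHG3")]


def test_unknown_c_call_rejected():
    with pytest.raises(ValidationError):
        subclass_switch_summary([_clone(["a"])], {"a": "IGHM"})


def test_simulator_output_has_no_upstream_switches(fitted):
    assert fitted.subclass_switches.violations == []
    assert fitted.subclass_switches.n_more_than_two == 0


# -- BCR features ------------------------------------------------------------


@pytest.mark.parametrize(
    "junction_aa, charge",
    [("CARDRW", 1.0), ("CAKDEW", -1.0), ("GGGGGG", 0.0), ("HHH", 0.0)],
)
def test_cdr3_charge(junction_aa, charge):
    assert cdr3_charge(junction_aa) == charge


def test_cdr3_charge_histidine_weight():
    assert cdr3_charge("HHH", histidine_weight=0.1) == pytest.approx(0.3)


def test_cdr3_charge_invalid_characters():
    with pytest.raises(ValidationError):
        cdr3_charge("CAR1W")


def test_gene_family_extraction():
    assert gene_family("IGHV3-23*01") == "IGHV3"
    assert gene_family("IGHJ4*01") == "IGHJ4"
    assert gene_family(None) is None


def test_features_table_shape(fitted):
    f = fitted.features
    assert len(f) == len(fitted.cells)
    assert {"subclass", "cdr3_length_aa", "cdr3_charge", "light_locus",
            "vh_family", "vl_family", "total_mutations"} <= set(f.columns)
    assert f["vh_family"].str.startswith("IGHV").all()


# -- mutation/affinity correlation -------------------------------------------


def _conc_cells(pairs):
    out = []
    for i, (mut, conc) in enumerate(pairs):
        cid = f"c{i}"
        out.append(
            ReceptorCell(cell_id=cid, endpoint_conc=conc,
                         heavy=ChainRecord(cid, "IGH", "ACGT" * 20, junction="")))
    return out


def test_perfectly_monotone_decreasing_correlation():
    pairs = [(m, 100.0 / (m + 1)) for m in range(10)]
    cells = _conc_cells(pairs)
    counts = {c.cell_id: p[0] for c, p in zip(cells, pairs)}
    res = correlate_mutations_affinity(cells, counts)
    assert res.coefficient == pytest.approx(-1.0)


def test_independent_data_has_small_correlation():
    rng = np.random.default_rng(0)
    pairs = [(int(rng.integers(0, 40)), float(rng.lognormal(1, 0.5)))
             for _ in range(1000)]
    cells = _conc_cells(pairs)
    counts = {c.cell_id: p[0] for c, p in zip(cells, pairs)}
    res = correlate_mutations_affinity(cells, counts)
    assert abs(res.coefficient) < 0.2


def test_constant_vector_not_applicable():
    cells = _conc_cells([(5, 1.0), (5, 2.0), (5, 3.0)])
    res = correlate_mutations_affinity(cells, {c.cell_id: 5 for c in cells})
    assert not res.applicable


def test_simulated_affinity_correlation_is_negative(library):
    cfg = b.SimConfig(seed=13, n_clones=120)  # >= 60 tested founder mAbs
    cells, _ = b.simulate_repertoire(library, cfg)
    res = b.RepertoireAnalysis(cells, library).fit()
    assert res.mutation_affinity.coefficient < 0
    assert res.mutation_affinity.p_value < 0.05


# -- privacy search ----------------------------------------------------------


def test_query_in_reference_is_100_percent():
    res = closest_identity("CARDYW", {"CARDYW", "CARDYF"})
    assert res.max_identity_pct == 100.0 and res.private is False


def test_single_mismatch_identity():
    res = closest_identity("A" * 10, {"A" * 9 + "C"})
    assert res.max_identity_pct == pytest.approx(90.0)


def test_private_threshold_is_strict():
    # 799/1000 positions matching -> 79.9% -> private; 800 -> not private
    q = "A" * 1000
    ref_799 = "A" * 799 + "C" * 201
    ref_800 = "A" * 800 + "C" * 200
    assert closest_identity(q, {ref_799}).private is True
    assert closest_identity(q, {ref_800}).private is False


def test_no_length_compatible_reference():
    res = closest_identity("CARDYW", {"SHORT"})
    assert res.max_identity_pct is None and res.private is None


def test_synthetic_reference_generator_shape():
    ref = synthetic_cdr_reference(50, 12, seed=1)
    assert len(ref) == 50 and all(len(r) == 12 for r in ref)
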