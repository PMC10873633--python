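"""Clonal inference: germline assignment, clustering, founders, clonality."""

import numpy as np
import pytest

import bcrcsf as b
from bcrcsf.clones import (
    Clone,
    GermlineAssignment,
    assign_germline,
    clonality_fraction,
    cluster_clones,
    cluster_tcr_clones,
    identify_founder,
    strip_allele,
)
from bcrcsf.germline import ChainRecord, ReceptorCell, Segment, SegmentLibrary, ValidationError


# -- germline assignment -----------------------------------------------------


def test_assignment_of_exact_concatenation(library):
    v = library.select("IGH", "V")[0]
    j = library.select("IGH", "J")[0]
    chain = ChainRecord("c0", "IGH", v.sequence + j.sequence, junction="")
    asg = assign_germline(chain, library)
    assert asg.v_call == v.segment_id and asg.v_identity == 1.0
    assert asg.j_call == j.segment_id and asg.j_identity == 1.0
    assert not asg.failed


def test_assignment_identity_arithmetic(library):
    v = library.select("IGH", "V")[0]
    j = library.select("IGH", "J")[0]
    seq = list(v.sequence + j.sequence)
    seq[10] = "A" if seq[10] != "A" else "C"
    seq[50] = "A" if seq[50] != "A" else "C"
    asg = assign_germline(ChainRecord("c0", "IGH", "".join(seq), junction=""), library)
    assert asg.v_identity == pytest.approx((len(v.sequence) - 2) / len(v.sequence))


def test_assignment_allele_tie_breaks_lexicographically():
    seq_v = "TGT" + "ACGGCA" * 20
    lib = SegmentLibrary(
        [
            Segment("V9*02", "IGH", "V", seq_v, 0),
            Segment("V9*01", "IGH", "V", seq_v, 0),
            Segment("J1*01", "IGH", "J", "TGGACAACCGGT" * 4, 0),
        ]
    )
    chain = ChainRecord("c0", "IGH", seq_v + "TGGACAACCGGT" * 4, junction="")
    asg = assign_germline(chain, lib)
    assert asg.v_call == "V9*01"


def test_assignment_failure_flag_on_garbage(library):
    chain = ChainRecord("c0", "IGH", "A" * 400, junction="")
    assert assign_germline(chain, library).failed


def test_assignment_requires_minimum_length(library):
    with pytest.raises(ValidationError):
        assign_germline(ChainRecord("c0", "IGH", "ACGT", junction=""), library)


# -- clustering --------------------------------------------------------------


def _cell(cid, junction):
    chain = ChainRecord(cid, "IGH", "ACGT" * 30, junction=junction)
    return ReceptorCell(cell_id=cid, heavy=chain)


def _asg(cell, v="IGHV1-2*01", j="IGHJ4*01"):
    return GermlineAssignment(cell.heavy, v_call=v, j_call=j,
                              v_identity=1.0, j_identity=1.0)


def _cluster(junctions, threshold=6):
    cells = [_cell(f"c{i}", j) for i, j in enumerate(junctions)]
    asgs = {c.cell_id: _asg(c) for c in cells}
    return cells, cluster_clones(cells, asgs, threshold=threshold)


def _mutated(base, k):
    out = list(base)
    for i in range(k):
        out[i] = "A" if out[i] != "A" else "C"
    return "".join(out)


def test_identical_junctions_form_one_clone():
    _, clones = _cluster(["TGTGCAGCATGG", "TGTGCAGCATGG"])
    assert len(clones) == 1 and clones[0].size == 2


def test_hamming_six_is_outside_the_clone():
    # strict < 6: distance exactly 6 must split
    base = "TGTGCAGCATGGACA"
    _, clones = _cluster([base, _mutated(base, 6)])
    assert len(clones) == 2
    _, clones = _cluster([base, _mutated(base, 5)])
    assert len(clones) == 1


def test_single_linkage_transitive_closure():
    # A-B = 3, B-C = 3, A-C = 6: all three chain into one clone
    base = "TGTGCAGCATGGACA"
    a = base
    c = _mutated(base, 6)
    bmid = _mutated(base, 3)
    assert sum(x != y for x, y in zip(a, c)) == 6
    assert sum(x != y for x, y in zip(bmid, c)) == 3
    _, clones = _cluster([a, bmid, c])
    assert len(clones) == 1 and clones[0].size == 3


def test_clustering_is_a_partition_and_order_invariant():
    rng = np.random.default_rng(0)
    base = "TGTGCAGCATGGACAGGT"
    junctions = ["".join(rng.choice(list("ACGT"), len(base))) for _ in range(30)]
    cells, clones = _cluster(junctions)
    members = [m for c in clones for m in c.members]
    assert sorted(members) == sorted(c.cell_id for c in cells)

    perm = rng.permutation(len(junctions))
    cells2 = [_cell(f"c{i}", junctions[i]) for i in perm]
    asgs2 = {c.cell_id: _asg(c) for c in cells2}
    clones2 = cluster_clones(cells2, asgs2)
    assert {frozenset(c.members) for c in clones} == {frozenset(c.members) for c in clones2}


def test_single_linkage_equals_connected_components_oracle():
    import networkx as nx

    rng = np.random.default_rng(1)
    for trial in range(10):
        n = int(rng.integers(5, 50))
        length = 15
        junctions = ["".join(rng.choice(list("ACGT"), length, p=[0.7, 0.1, 0.1, 0.1]))
                     for _ in range(n)]
        cells, clones = _cluster(junctions)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                d = sum(x != y for x, y in zip(junctions[i], junctions[j]))
                if d < 6:
                    g.add_edge(i, j)
        oracle = {frozenset(f"c{i}" for i in comp) for comp in nx.connected_components(g)}
        assert {frozenset(c.members) for c in clones} == oracle


def test_different_vj_or_length_never_cluster():
    cells = [_cell("c0", "TGTGCAGCATGG"), _cell("c1", "TGTGCAGCATGG")]
    asgs = {
        "c0": _asg(cells[0], v="IGHV1-2*01"),
        "c1": _asg(cells[1], v="IGHV3-23*01"),
    }
    assert len(cluster_clones(cells, asgs)) == 2


def test_allele_stripping_merges_alleles():
    assert strip_allele("IGHV3-23*01") == "IGHV3-23"
    cells = [_cell("c0", "TGTGCAGCATGG"), _cell("c1", "TGTGCAGCATGG")]
    asgs = {
        "c0": _asg(cells[0], v="IGHV1-2*01"),
        "c1": _asg(cells[1], v="IGHV1-2*02"),
    }
    assert len(cluster_clones(cells, asgs)) == 1


def test_clone_recovery_matches_truth(library, default_sim, fitted):
    from sklearn.metrics import adjusted_rand_score

    cells, truths = default_sim
    true = {t.cell_id: t.true_clone_id for t in truths}
    inferred = {m: c.clone_id for c in fitted.clones for m in c.members}
    ids = [c.cell_id for c in fitted.cells]
    ari = adjusted_rand_score([true[i] for i in ids], [inferred[i] for i in ids])
    assert ari == 1.0


# -- founder and clonality ---------------------------------------------------


def _clone(members):
    return Clone("x", sorted(members), "IGHV1-2", "IGHJ4", 12)


def test_founder_is_least_mutated():
    assert identify_founder(_clone(["a", "b", "c"]), {"a": 5, "b": 2, "c": 9}) == "b"


def test_founder_tie_breaks_lexicographically():
    assert identify_founder(_clone(["b", "a"]), {"a": 3, "b": 3}) == "a"


def test_founder_of_singleton():
    assert identify_founder(_clone(["only"]), {"only": 7}) == "only"


def test_founder_missing_count_rejected():
    with pytest.raises(ValidationError):
        identify_founder(_clone(["a", "b"]), {"a": 1})


def test_clonality_fraction_examples():
    cells = [_cell(f"c{i}", "TGTGCAGCATGG") for i in range(10)]
    clones = [_clone(["c0", "c1"])] + [_clone([f"c{i}"]) for i in range(2, 10)]
    assert clonality_fraction(cells, clones) == pytest.approx(0.2)
    assert clonality_fraction(cells, [_clone([c.cell_id]) for c in cells]) == 0.0
    assert clonality_fraction(343, n_clonal=37) == pytest.approx(0.108, abs=5e-4)
    with pytest.raises(ValidationError):
        clonality_fraction([], [])


def test_tcr_clones_require_identical_junctions():
    cells = [_cell("c0", "TGTGCAGCATGG"), _cell("c1", "TGTGCAGCATGG"),
             _cell("c2", "TGTGCAGCATGC")]
    clones = cluster_tcr_clones(cells)
    sizes = sorted(c.size for c in clones)
    assert sizes == [1, 2]
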