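"""Anchor bubbles, cross structures and the 4x-evidence untangling rules."""

import numpy as np
import pytest

from diphase._kmer import revcomp
from diphase.dbg import DeBruijnGraph
from diphase.mapping import BarcodeTable, LinkStore
from diphase.untangle import (
    CrossStructure,
    Evidence,
    apply_untangle,
    decide,
    detect_anchor_bubbles,
    find_cross_structures,
    resolve_cross,
    untangle_graph,
)


def _rand(rng, n):
    return "".join(np.frombuffer(b"ACGT", "S1")[rng.integers(0, 4, n)].astype(str))


# ---------------------------------------------------------------------------
# decision rule
# ---------------------------------------------------------------------------


def oracle_decide(a, b, ratio=4):
    """Literal rule: a solution wins iff its score >= max(1, ratio x alt)."""
    win_a = a >= ratio * b and a >= 1
    win_b = b >= ratio * a and b >= 1
    if win_a and not win_b:
        return "a"
    if win_b and not win_a:
        return "b"
    return "unresolved"


def test_decision_rule_matches_oracle_on_all_score_pairs():
    for a in range(21):
        for b in range(21):
            assert decide(a, b) == oracle_decide(a, b), (a, b)


def test_zero_evidence_never_phases():
    assert decide(0, 0) == "unresolved"


# ---------------------------------------------------------------------------
# anchor bubbles
# ---------------------------------------------------------------------------


def _bubble_graph(branch_specs, k=4, rng=None):
    """Chain of simple bubbles: flank J (b1|b2) J flank J (..) ...

    branch_specs: list of (cov1, cov2, length); sequences are arbitrary —
    only the topology and coverages matter for detection.
    """
    rng = rng or np.random.default_rng(0)
    g = DeBruijnGraph(k)
    left = g.add_node(_rand(rng, 30), 30.0)
    for cov1, cov2, ln in branch_specs:
        j1 = g.add_node(_rand(rng, k), 30.0, is_junction=True)
        b1 = g.add_node(_rand(rng, ln), cov1)
        b2 = g.add_node(_rand(rng, ln), cov2)
        j2 = g.add_node(_rand(rng, k), 30.0, is_junction=True)
        right = g.add_node(_rand(rng, 30), 30.0)
        g.add_edge(left, 0, j1, 0)
        g.add_edge(j1, 0, b1, 0)
        g.add_edge(j1, 0, b2, 0)
        g.add_edge(b1, 0, j2, 0)
        g.add_edge(b2, 0, j2, 0)
        g.add_edge(j2, 0, right, 0)
        left = right
    return g


def test_single_bubble_sets_c_hetero_and_retains_anchor():
    g = _bubble_graph([(10.0, 10.0, 100)])
    anchors = detect_anchor_bubbles(g)
    assert anchors.c_hetero == pytest.approx(10.0)
    assert len(anchors) == 1  # 10 <= 1.75 * 10


def test_high_coverage_bubble_excluded_by_weighted_mean():
    # two bubbles: c_hetero = (2*10*100 + 2*40*100) / 400 = 25 -> both kept
    anchors = detect_anchor_bubbles(_bubble_graph(
        [(10.0, 10.0, 100), (40.0, 40.0, 100)]))
    assert anchors.c_hetero == pytest.approx(25.0)
    assert len(anchors) == 2
    # a third low bubble pulls c_hetero to 15 -> the cov-40 bubble drops out
    anchors = detect_anchor_bubbles(_bubble_graph(
        [(10.0, 10.0, 100), (40.0, 40.0, 100), (.0 + 5, 5.0, 200)]))
    assert anchors.c_hetero < 40 / 1.75
    assert len(anchors) == 2


def test_homozygous_graph_has_no_anchors(rng):
    g = DeBruijnGraph(4)
    g.add_node(_rand(rng, 200), 30.0)
    anchors = detect_anchor_bubbles(g)
    assert len(anchors) == 0 and anchors.c_hetero == 0.0


# ---------------------------------------------------------------------------
# cross structures
# ---------------------------------------------------------------------------


def _cross_graph(center_cov=20.0, ext_covs=(10.0, 10.0, 10.0, 10.0),
                 center_len=50, k=4, extra_external=False, rng=None):
    rng = rng or np.random.default_rng(1)
    g = DeBruijnGraph(k)
    e = [g.add_node(_rand(rng, 40), c) for c in ext_covs]
    j1 = g.add_node(_rand(rng, k), 30.0, is_junction=True)
    j2 = g.add_node(_rand(rng, k), 30.0, is_junction=True)
    c = g.add_node(_rand(rng, center_len), center_cov)
    g.add_edge(e[0], 0, j1, 0)
    g.add_edge(e[1], 0, j1, 0)
    g.add_edge(j1, 0, c, 0)
    g.add_edge(c, 0, j2, 0)
    g.add_edge(j2, 0, e[2], 0)
    g.add_edge(j2, 0, e[3], 0)
    if extra_external:
        e5 = g.add_node(_rand(rng, 40), 10.0)
        g.add_edge(e5, 0, j1, 0)
    return g, c, e


def test_cross_detected_when_coverage_conditions_hold():
    g, c, e = _cross_graph(center_cov=20.0)
    [cs] = find_cross_structures(g, c_hetero=10.0)
    assert cs.center == c
    assert {x[0] for x in cs.left} == {e[0], e[1]}
    assert {x[0] for x in cs.right} == {e[2], e[3]}


def test_cross_rejected_when_center_coverage_too_high():
    g, _, _ = _cross_graph(center_cov=40.0)
    assert find_cross_structures(g, c_hetero=10.0) == []  # 40 > 2*1.75*10


def test_cross_requires_one_external_below_threshold():
    g, _, _ = _cross_graph(center_cov=20.0, ext_covs=(20.0, 20.0, 20.0, 20.0))
    assert find_cross_structures(g, c_hetero=10.0) == []


def test_three_externals_is_not_a_cross():
    g, _, _ = _cross_graph(extra_external=True)
    assert find_cross_structures(g, c_hetero=10.0) == []


def test_cross_detection_survives_junction_absorption():
    g, c, e = _cross_graph()
    g.compress()
    [cs] = find_cross_structures(g, c_hetero=10.0)
    assert cs.j_left is None and cs.j_right is None
    assert {x[0] for x in cs.left} == {e[0], e[1]}


# ---------------------------------------------------------------------------
# resolution
# ---------------------------------------------------------------------------


def _cs(center_len=100):
    return CrossStructure(center=9, j_left=None, j_right=None,
                          left=[(1, 0), (2, 0)], right=[(3, 0), (4, 0)],
                          center_len=center_len)


def _links(pairs):
    store = LinkStore()
    for (a, b), n in pairs.items():
        for _ in range(n):
            store.add(a, 1, b, 0, 0, "paired-end")
    return store


@pytest.mark.parametrize("par,cross,expected", [
    (4, 1, "parallel"),    # boundary: 4 >= 4*1
    (3, 1, "unresolved"),  # 3 < 4
    (0, 1, "cross"),       # 1 >= max(1, 0)
    (0, 0, "unresolved"),
])
def test_link_method_decision(par, cross, expected):
    store = _links({(1, 3): par, (2, 4): 0, (1, 4): cross, (2, 3): 0})
    res = resolve_cross(_cs(), Evidence(links=store))
    assert res.decision == expected


def test_barcode_method_skipped_for_long_center():
    table = BarcodeTable({(1, "X"): 10, (3, "X"): 10})
    res = resolve_cross(_cs(center_len=250_000), Evidence(barcodes=table))
    assert res.decision == "unresolved"
    res = resolve_cross(_cs(center_len=100_000), Evidence(barcodes=table))
    assert res.decision == "parallel"


def test_conflicting_methods_leave_unresolved():
    links = _links({(1, 3): 8})
    barcodes = BarcodeTable({(1, "X"): 10, (4, "X"): 10})
    res = resolve_cross(_cs(), Evidence(links=links, barcodes=barcodes))
    assert res.decision == "unresolved"


def test_agreeing_methods_merge():
    links = _links({(1, 3): 8})
    barcodes = BarcodeTable({(2, "X"): 10, (4, "X"): 10})
    res = resolve_cross(_cs(), Evidence(links=links, barcodes=barcodes))
    assert res.decision == "parallel"


# ---------------------------------------------------------------------------
# graph rewriting
# ---------------------------------------------------------------------------


def _node_content(g):
    from diphase._kmer import canonical
    return sorted(canonical(n.seq) for n in g.nodes.values())


def test_untangle_duplicates_center_into_two_paths():
    g, c, e = _cross_graph()
    center_seq = g.nodes[c].seq
    ext_seqs = {i: g.nodes[i].seq for i in e}
    [cs] = find_cross_structures(g, c_hetero=10.0)
    store = _links({(e[0], e[2]): 5, (e[1], e[3]): 5})
    res = resolve_cross(cs, Evidence(links=store))
    assert res.decision == "parallel"
    apply_untangle(g, cs, res)
    # externals untouched, centre duplicated (with its junction bases)
    for i in e:
        assert g.nodes[i].seq == ext_seqs[i]
    copies = [n for n in g.nodes.values() if center_seq in n.seq]
    assert len(copies) == 2
    assert all(n.cov == pytest.approx(10.0) for n in copies)
    # the two paths are e0-copy-e2 and e1-copy-e3
    for a, b in ((e[0], e[2]), (e[1], e[3])):
        nxt = g.successors(a, 0)
        assert len(nxt) == 1
        assert g.successors(*nxt[0]) == [(b, 0)]


def test_untangle_graph_is_fixed_point_when_no_crosses(rng):
    g = DeBruijnGraph(4)
    g.add_node(_rand(rng, 100), 20.0)
    before = _node_content(g)
    n = untangle_graph(g, lambda gg: Evidence(links=LinkStore()), c_hetero=10.0)
    assert n == 0 and _node_content(g) == before


def test_untangle_graph_resolves_and_compresses():
    g, c, e = _cross_graph()
    store = _links({(e[0], e[2]): 5, (e[1], e[3]): 5})
    n = untangle_graph(g, lambda gg: Evidence(links=store), c_hetero=10.0)
    assert n == 1
    # after compression the two haplotype paths are two straight nodes
    assert len(g.straight_nodes()) == 2
    assert not g.junction_nodes()
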