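"""Scaffold graph, scaffold untangling, synteny division and bubble pairing."""

import numpy as np
import pytest

from diphase._kmer import revcomp
from diphase.mapping import LinkStore, NodeIndex
from diphase.scaffold import (
    PhasedBlockSet,
    ScaffoldNode,
    build_scaffold_graph,
    compute_division,
    find_scaffold_crosses,
    join_scaffolds,
    join_with_gap,
    locate_anchors,
    pair_bubbles,
    synteny_correct,
    untangle_scaffold_graph,
)
from diphase.untangle import AnchorBubble, AnchorBubbleSet, Evidence


def _rand(rng, n):
    return "".join(np.frombuffer(b"ACGT", "S1")[rng.integers(0, 4, n)].astype(str))


# ---------------------------------------------------------------------------
# division score (the heart of haplotype synteny-based correction)
# ---------------------------------------------------------------------------


def oracle_division(b, l, b_max=None):
    """Independent brute-force of the dominant-counterpart range.

    B_max maximises the summed length per counterpart id; the corrected
    d_min maximises the forward division score (carry 0 / -l on B_max /
    +l otherwise) when any score is positive, ties to the smallest index;
    d_max uses the mirrored walk restricted to [new_dmin, d_max].
    """
    totals = {}
    for bi, li in zip(b, l):
        if bi:
            totals[bi] = totals.get(bi, 0) + li
    if not totals:
        return None
    if b_max is None:
        best = max(totals.values())
        b_max = min(x for x, v in totals.items() if v == best)
    idx = [i for i, x in enumerate(b) if x == b_max]
    d_min, d_max = min(idx), max(idx)
    scores = []
    s = 0
    for x in range(d_min, d_max + 1):
        s += 0 if b[x] == 0 else (-l[x] if b[x] == b_max else l[x])
        scores.append(s)
    new_min = d_min
    if scores and max(scores) > 0:
        new_min = d_min + scores.index(max(scores))
    scores2 = []
    s = 0
    for x in range(d_max, new_min - 1, -1):
        s += 0 if b[x] == 0 else (-l[x] if b[x] == b_max else l[x])
        scores2.append(s)
    new_max = d_max
    if scores2 and max(scores2) > 0:
        new_max = d_max - scores2.index(max(scores2))
    return b_max, new_min, new_max


@pytest.mark.parametrize("b,l,b_max,expected", [
    # all-negative score: boundaries unchanged
    ([2, 0, 2], [100, 50, 100], None, (2, 0, 2)),
    # length-weighted vote picks counterpart 3 and its range
    ([2, 3, 3, 2, 2], [10, 40, 40, 10, 10], None, (3, 1, 2)),
    # positive score moves d_min to the score maximum (recursion exercised
    # against the fixed counterpart 5; the length vote alone would pick 2)
    ([5, 2, 5], [10, 100, 10], 5, (5, 1, 1)),
])
def test_division_examples(b, l, b_max, expected):
    div = compute_division(b, l, b_max=b_max)
    assert (div.b_max, div.d_min, div.d_max) == expected


def test_division_forward_scores_match_hand_recursion():
    div = compute_division([2, 0, 2], [100, 50, 100])
    assert div.score_min == [-100, -100, -200]
    div = compute_division([5, 2, 5], [10, 100, 10], b_max=5)
    assert div.score_min == [-10, 90, 80]


def test_division_without_counterparts_is_none():
    assert compute_division([0, 0], [10, 10]) is None


def test_division_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(99)
    for _ in range(1000):
        n = int(rng.integers(1, 21))
        b = rng.integers(0, 6, size=n).tolist()
        l = rng.integers(1, 200, size=n).tolist()
        want = oracle_division(b, l)
        div = compute_division(b, l)
        if want is None:
            assert div is None
        else:
            assert (div.b_max, div.d_min, div.d_max) == want, (b, l)


# ---------------------------------------------------------------------------
# scaffold graph
# ---------------------------------------------------------------------------


def _store(edges):
    store = LinkStore()
    for (a, ea, b, eb), gaps in edges.items():
        for g in gaps:
            store.add(a, ea, b, eb, g, "paired-end")
    return store


def test_bundle_below_min_links_dropped(rng):
    nodes = [(1, _rand(rng, 500), 20.0), (2, _rand(rng, 500), 20.0)]
    store = _store({(1, 1, 2, 0): [100]})
    g = build_scaffold_graph(nodes, store, min_links=2)
    assert g.edges == {}
    g = build_scaffold_graph(nodes, store, min_links=1)
    assert len(g.edges) == 1


def test_simulated_two_contig_join_recovers_layout(rng):
    src = _rand(rng, 1300)
    a, b = src[:600], src[700:]  # true gap 100
    nodes = [(1, a, 20.0), (2, b, 20.0)]
    store = _store({(1, 1, 2, 0): [95, 100, 105, 98, 102]})
    g = build_scaffold_graph(nodes, store, min_links=2)
    out, joins = join_scaffolds(g)
    assert joins == 1
    [(nid, seq, cov)] = out
    assert seq == a + "N" * 100 + b


def test_negative_gap_attempts_exact_overlap_merge(rng):
    src = _rand(rng, 1000)
    a, b = src[:600], src[560:]  # 40-base true overlap
    assert join_with_gap(a, b, -40.0) == src
    assert join_with_gap(a, b, -38.0) == src  # tolerant probe window
    c = _rand(rng, 300)
    assert join_with_gap(a, c, -40.0) == a + "N" + c  # no exact overlap


def test_ambiguous_end_prevents_join(rng):
    nodes = [(i, _rand(rng, 500), 20.0) for i in (1, 2, 3)]
    store = _store({(1, 1, 2, 0): [100] * 3, (1, 1, 3, 0): [100] * 3})
    g = build_scaffold_graph(nodes, store, min_links=2)
    out, joins = join_scaffolds(g)
    assert joins == 0 and len(out) == 3


def test_transitive_long_range_bundle_is_reduced(rng):
    # chain 1 -> 2 -> 3; the 1 -> 3 bundle is explained through node 2
    nodes = [(1, _rand(rng, 2000), 20.0), (2, _rand(rng, 2000), 20.0),
             (3, _rand(rng, 2000), 20.0)]
    store = _store({
        (1, 1, 2, 0): [100] * 5,
        (2, 1, 3, 0): [100] * 5,
        (1, 1, 3, 0): [2200] * 5,
    })
    g = build_scaffold_graph(nodes, store, min_links=2)
    out, joins = join_scaffolds(g)
    assert joins == 2
    assert len(out) == 1


def test_short_node_excluded_unless_anchored(rng):
    nodes = [(1, _rand(rng, 500), 20.0), (2, _rand(rng, 5000), 20.0)]
    store = _store({(1, 1, 2, 0): [100] * 5})
    g = build_scaffold_graph(nodes, store, min_links=2, min_node_len=3000)
    assert 1 in g.excluded and not g.edges
    g = build_scaffold_graph(nodes, store, min_links=2, min_node_len=3000,
                             anchored={1})
    assert 1 not in g.excluded and len(g.edges) == 1


# ---------------------------------------------------------------------------
# scaffold-level untangling
# ---------------------------------------------------------------------------


def _scaffold_cross(rng, par_links=8, cross_links=1):
    nodes = [(i, _rand(rng, 4000), 20.0) for i in (1, 2, 3, 4)]
    nodes.append((5, _rand(rng, 4000), 40.0))  # centre
    edges = {
        (1, 1, 5, 0): [100] * 6, (2, 1, 5, 0): [100] * 6,
        (5, 1, 3, 0): [100] * 6, (5, 1, 4, 0): [100] * 6,
    }
    if par_links:
        # split the parallel support over both pairs
        edges[(1, 1, 3, 0)] = [4100] * (par_links - par_links // 2)
        if par_links // 2:
            edges[(2, 1, 4, 0)] = [4100] * (par_links // 2)
    if cross_links:
        edges[(1, 1, 4, 0)] = [4100] * cross_links
    store = _store(edges)
    g = build_scaffold_graph(nodes, store, min_links=1, gap_slack=10_000_000)
    return g, store


def test_scaffold_cross_untangled_with_clear_links(rng):
    g, store = _scaffold_cross(rng, par_links=8, cross_links=1)
    n = untangle_scaffold_graph(g, Evidence(links=store), c_hetero=20.0)
    assert n == 1
    assert len(g.nodes) == 2
    lens = sorted(len(nd.seq) for nd in g.nodes.values())
    assert all(ln >= 12000 for ln in lens)  # e + centre + e plus gaps


def test_scaffold_cross_left_unresolved_below_ratio(rng):
    g, store = _scaffold_cross(rng, par_links=2, cross_links=1)
    n = untangle_scaffold_graph(g, Evidence(links=store), c_hetero=20.0)
    assert n == 0 and len(g.nodes) == 5


# ---------------------------------------------------------------------------
# synteny correction and pairing
# ---------------------------------------------------------------------------


def _anchored_pair(rng, n_anchors=6, block=2000):
    """Two homologous sequences that share nothing except planted anchor
    branches (63 bp, one SNV apart)."""
    bubbles = []
    seq_a, seq_b = [], []
    for i in range(n_anchors):
        branch = _rand(rng, 63)
        alt = list(branch)
        alt[31] = "A" if alt[31] != "A" else "C"
        alt = "".join(alt)
        bubbles.append(AnchorBubble(i + 1, branch, alt, 10.0, 10.0))
        seq_a.append(_rand(rng, block) + branch)
        seq_b.append(_rand(rng, block) + alt)
    anchors = AnchorBubbleSet(bubbles, c_hetero=10.0)
    return "".join(seq_a), "".join(seq_b), anchors


def test_locate_anchors_finds_unique_branches(rng):
    a, b, anchors = _anchored_pair(rng)
    index = NodeIndex([(1, a), (2, b)], seed_lengths=(32,))
    hits = locate_anchors(index, anchors)
    assert len(hits) == len(anchors.bubbles)
    assert all({h.node_a, h.node_b} == {1, 2} for h in hits)


def test_synteny_correct_without_anchors_is_identity(rng):
    nodes = [(1, _rand(rng, 1000), 20.0)]
    out, n = synteny_correct(nodes, AnchorBubbleSet([], 0.0))
    assert out == nodes and n == 0


def test_synteny_division_splits_chimeric_node(rng):
    # node X carries anchors of two different counterparts separated by a
    # gap; the edge-contig rule and division scores must cut it apart
    a1, b1, anchors1 = _anchored_pair(rng, n_anchors=3)
    a2, b2, anchors2 = _anchored_pair(rng, n_anchors=3)
    bubbles = anchors1.bubbles + [
        AnchorBubble(len(anchors1.bubbles) + ab.id, ab.branch_a, ab.branch_b,
                     ab.cov_a, ab.cov_b) for ab in anchors2.bubbles]
    anchors = AnchorBubbleSet(bubbles, c_hetero=10.0)
    chimera = a1 + "N" * 10 + a2  # hapA parts of two loci fused
    nodes = [(1, chimera, 20.0), (2, b1, 20.0), (3, b2, 20.0)]
    out, n_div = synteny_correct(nodes, anchors)
    assert n_div >= 1
    # non-N content is conserved by division
    def non_n(seqs):
        return sum(len(s) - s.count("N") for s in seqs)
    assert non_n([s for _, s, _ in out]) == non_n([s for _, s, _ in nodes])
    # afterwards no node carries anchors of two different counterparts
    index = NodeIndex(sorted((nid, s) for nid, s, _ in out),
                      seed_lengths=(32,))
    hits = locate_anchors(index, anchors)
    per_node = {}
    for h in hits:
        per_node.setdefault(h.node_a, set()).add(h.node_b)
        per_node.setdefault(h.node_b, set()).add(h.node_a)
    assert all(len(v) == 1 for v in per_node.values())


def test_pair_bubbles_primary_by_non_n_count(rng):
    a, b, anchors = _anchored_pair(rng, n_anchors=4)
    b = b + "N" * 50  # Ns do not count toward primary choice
    nodes = [(1, a + "ACGT", 20.0), (2, b, 20.0)]
    blocks = pair_bubbles(nodes, anchors)
    assert len(blocks.bubbles) == 1
    bp = blocks.bubbles[0]
    assert bp.primary_id == 1  # more non-N bases
    assert bp.primary == a + "ACGT"


def test_pair_bubbles_tie_breaks_to_smaller_id(rng):
    a, b, anchors = _anchored_pair(rng, n_anchors=4)
    nodes = [(2, a, 20.0), (7, b + "X" * 0, 20.0)]
    # equal non-N length: pad b to a's length
    nodes[1] = (7, b + "A" * (len(a) - len(b)), 20.0)
    blocks = pair_bubbles(nodes, anchors)
    assert blocks.bubbles[0].primary_id == 2


def test_anchor_free_node_emitted_as_nonbubble(rng):
    a, b, anchors = _anchored_pair(rng, n_anchors=4)
    lone = _rand(rng, 800)
    nodes = [(1, a, 20.0), (2, b, 20.0), (3, lone, 20.0)]
    blocks = pair_bubbles(nodes, anchors)
    assert [nid for nid, _ in blocks.nonbubbles] == [3]


def test_phased_block_fasta_naming(rng):
    blocks = PhasedBlockSet()
    from diphase.scaffold import BubblePair
    blocks.bubbles.append(BubblePair(1, 2, "AAAA", "CCCC", 3))
    blocks.nonbubbles.append((3, "GGGG"))
    names = [n for n, _ in blocks.fasta_records()]
    assert names == ["primary_bubble_1", "secondary_bubble_1", "nonbubble_1"]
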