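"""Seed placement, link evidence, barcode tables and long-read filtering."""

import itertools

import numpy as np
import pytest

from diphase._kmer import revcomp
from diphase.mapping import (
    BarcodeTable,
    LongReadAlignment,
    NodeIndex,
    ReadSeeds,
    count_barcodes,
    filter_long_alignments,
    long_read_links,
    long_read_position,
    map_reads,
    pair_links,
    parse_bx_tag,
    parse_paf,
    single_read_links,
)


def _rand(rng, n):
    return "".join(np.frombuffer(b"ACGT", "S1")[rng.integers(0, 4, n)].astype(str))


@pytest.fixture()
def two_node_index(rng):
    """Two nodes cut from one 700-bp source with a known layout."""
    src = _rand(rng, 700)
    a, b = src[:400], src[380:]  # 20-base true overlap
    return src, NodeIndex([(1, a), (2, b)])


def test_unique_exact_substring_is_placed(two_node_index):
    src, index = two_node_index
    read = src[50:250]
    pl = map_reads(index, ReadSeeds([read]))
    assert pl.node[0] == 1 and pl.pos[0] == 50 and pl.strand[0] == 0


def test_reverse_complement_read_gets_strand_one(two_node_index):
    src, index = two_node_index
    read = revcomp(src[50:250])
    pl = map_reads(index, ReadSeeds([read]))
    assert pl.node[0] == 1 and pl.pos[0] == 50 and pl.strand[0] == 1


def test_planted_duplicate_seed_is_never_placed(rng):
    dup = _rand(rng, 120)
    a = _rand(rng, 100) + dup + _rand(rng, 100)
    b = _rand(rng, 100) + dup + _rand(rng, 100)
    index = NodeIndex([(1, a), (2, b)])
    pl = map_reads(index, ReadSeeds([dup[:100]]))
    assert pl.node[0] == -1


def test_duplicate_on_opposite_strands_is_still_ambiguous(rng):
    dup = _rand(rng, 120)
    a = _rand(rng, 100) + dup + _rand(rng, 100)
    b = _rand(rng, 100) + revcomp(dup) + _rand(rng, 100)
    index = NodeIndex([(1, a), (2, b)])
    pl = map_reads(index, ReadSeeds([dup[:100]]))
    assert pl.node[0] == -1


def test_straddling_read_yields_link_with_layout_gap(rng):
    # true layout: A then B immediately adjacent (gap 0)
    a = _rand(rng, 300)
    b = _rand(rng, 300)
    index = NodeIndex([(1, a), (2, b)])
    read = a[-96:] + b[:96]
    pl = map_reads(index, ReadSeeds([read]))
    store = single_read_links(index, pl)
    [(key, gaps)] = list(store.items())
    assert key == ((1, 1), (2, 0))
    assert gaps == [0]


def test_pair_links_gap_uses_insert_size(rng):
    a = _rand(rng, 500)
    gap = 120
    b = _rand(rng, 500)
    index = NodeIndex([(1, a), (2, b)])
    # innie pair spanning the gap: mate1 forward at a[300:], mate2 is the
    # reverse complement of b[:200]; insert = 200 + gap + 200
    r1 = [a[300:500]]
    r2 = [revcomp(b[0:200])]
    pl1 = map_reads(index, ReadSeeds(r1))
    pl2 = map_reads(index, ReadSeeds(r2))
    insert = 200 + gap + 200
    store, _ = pair_links(index, pl1, pl2, insert, "paired-end")
    [(key, gaps)] = list(store.items())
    assert key == ((1, 1), (2, 0))
    assert gaps == [gap]


def test_same_node_pairs_feed_insert_estimation(rng):
    a = _rand(rng, 2000)
    index = NodeIndex([(1, a)])
    starts = [100, 400, 900]
    insert = 700
    pl1 = map_reads(index, ReadSeeds([a[s : s + 150] for s in starts]))
    pl2 = map_reads(index, ReadSeeds(
        [revcomp(a[s + insert - 150 : s + insert]) for s in starts]))
    _, observed = pair_links(index, pl1, pl2, 500.0, "paired-end")
    assert list(observed) == [insert] * 3


def test_mate_pair_orientation_flip(rng):
    a = _rand(rng, 500)
    b = _rand(rng, 500)
    index = NodeIndex([(1, a), (2, b)])
    # outward-facing library: reads are the reverse complement of the
    # corresponding inward pair
    r1 = [revcomp(a[300:500])]
    r2 = [b[0:200]]
    pl1 = map_reads(index, ReadSeeds(r1))
    pl2 = map_reads(index, ReadSeeds(r2))
    store, _ = pair_links(index, pl1, pl2, 520, "mate-pair", outward=True)
    [(key, gaps)] = list(store.items())
    assert key == ((1, 1), (2, 0))
    assert gaps == [120]


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n_reads,expect_entry", [(3, False), (4, True)])
def test_barcode_minimum_read_filter(rng, n_reads, expect_entry):
    node = _rand(rng, 600)
    index = NodeIndex([(1, node)])
    reads = [node[i * 40 : i * 40 + 150] for i in range(n_reads)]
    pl = map_reads(index, ReadSeeds(reads))
    table = count_barcodes(pl, ["BC1"] * n_reads)
    assert ((1, "BC1") in table.counts) == expect_entry
    if expect_entry:
        assert table.counts[(1, "BC1")] == 4


def test_reads_without_barcodes_give_empty_table(rng, caplog):
    import logging
    node = _rand(rng, 400)
    index = NodeIndex([(1, node)])
    pl = map_reads(index, ReadSeeds([node[:150], node[100:250]]))
    with caplog.at_level(logging.WARNING, logger="diphase"):
        table = count_barcodes(pl, [None, None])
    assert table.counts == {}
    assert any("barcode" in r.message for r in caplog.records)


def test_common_barcode_read_sum():
    table = BarcodeTable({(1, "X"): 5, (2, "X"): 7, (1, "Y"): 4, (2, "Z"): 9})
    assert table.common_barcode_reads(1, 2) == 12


@pytest.mark.parametrize("header,expected", [
    ("read1 BX:Z:ACGT-1", "ACGT-1"),
    ("read1 BX: Z:ACGT-1", "ACGT-1"),  # spaced variant
    ("read1", None),
    ("read1 BX:Z:", None),
])
def test_bx_tag_parsing(header, expected):
    assert parse_bx_tag(header) == expected


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


def aln(q="q", t=1, qs=0, qe=100, matches=90, alen=100, qlen=1000, tlen=1000,
        ts=0, te=100, strand=0):
    return LongReadAlignment(query=q, target=t, qlen=qlen, tlen=tlen,
                             qstart=qs, qend=qe, tstart=ts, tend=te,
                             strand=strand, matches=matches, aln_len=alen)


@pytest.mark.parametrize("matches,alen,qlen,kept", [
    (800, 1000, 10000, True),    # identity exactly 0.8, length exactly 1000
    (425, 500, 1000, False),     # identity 0.85 but short and low coverage
    (425, 500, 550, True),       # short but coverage >= 0.8
    (700, 1000, 10000, False),   # identity below 0.8
])
def test_long_alignment_identity_length_filter(matches, alen, qlen, kept):
    a = aln(matches=matches, alen=alen, qlen=qlen, qe=alen)
    assert (filter_long_alignments([a], k=32) == [a]) == kept


def brute_force_selection(alns, k):
    """Exhaustive subset search maximising total match-sites under the
    pairwise query-overlap < k constraint."""
    best, best_score = [], -1
    for r in range(len(alns) + 1):
        for combo in itertools.combinations(alns, r):
            ok = all(
                min(x.qend, y.qend) - max(x.qstart, y.qstart) < k
                for x, y in itertools.combinations(combo, 2)
                if x.query == y.query)
            if not ok:
                continue
            score = sum(a.matches for a in combo)
            if score > best_score:
                best, best_score = list(combo), score
    return best_score


def test_greedy_selection_drops_overlapping_weaker_alignment():
    a = aln(matches=900, alen=1000, qs=0, qe=1000)
    b = aln(matches=800, alen=1000, qs=900, qe=1900)  # overlap 100 >= k
    sel = filter_long_alignments([a, b], k=32)
    assert sel == [a]


@pytest.mark.parametrize("seed", range(4))
def test_greedy_selection_matches_exhaustive_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    alns = []
    for i in range(int(rng.integers(2, 8))):
        qs = int(rng.integers(0, 3000))
        ln = int(rng.integers(1000, 2500))
        alns.append(aln(qs=qs, qe=qs + ln, alen=ln,
                        matches=int(ln * rng.uniform(0.81, 0.99)),
                        t=int(rng.integers(1, 4))))
    sel = filter_long_alignments(alns, k=32)
    got = sum(a.matches for a in sel)
    best = brute_force_selection(alns, k=32)
    # greedy is the specified rule; it must be feasible and near the optimum
    assert got <= best
    for x, y in itertools.combinations(sel, 2):
        assert min(x.qend, y.qend) - max(x.qstart, y.qstart) < 32


@pytest.mark.parametrize("positions,expected", [
    ([(100, 50)], 100.0),
    ([(0, 100), (1000, 300)], 750.0),
])
def test_weighted_mean_position(positions, expected):
    alns = [aln(ts=p, alen=ln, qe=ln) for p, ln in positions]
    assert long_read_position(alns) == expected


def test_spanning_long_read_emits_link_with_query_gap():
    a = aln(t=1, qs=0, qe=1000, alen=1000, matches=950, te=1000)
    b = aln(t=2, qs=1500, qe=2500, alen=1000, matches=940, ts=0, te=1000)
    store = long_read_links([a, b])
    [(key, gaps)] = list(store.items())
    assert key == ((1, 1), (2, 0))
    assert gaps == [500]
    assert store.weights[key] == 950 + 940


def test_paf_parsing_roundtrip():
    line = ("q1\t5000\t100\t1100\t+\t7\t9000\t200\t1200\t900\t1000\t60\t"
            "NM:i:42\tcs:Z::1000\n")
    [rec] = parse_paf([line])
    assert rec.query == "q1" and rec.target == 7
    assert rec.matches == 900 and rec.aln_len == 1000
    assert rec.identity == 0.9
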