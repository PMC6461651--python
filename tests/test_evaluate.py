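"""Assembly statistics, het 1k-mer pairs, recall/precision, switch errors."""

import numpy as np
import pytest

from diphase._kmer import revcomp
from diphase.evaluate import (
    assembly_stats,
    build_het_pairs,
    count_switch_errors,
    find_reference_absent_bubbles,
    fragment_recall_precision,
    fragment_sequences,
    mask_by_quality,
    phased_pair_rate,
    split_contigs,
)
from diphase.evaluate import HetKmerPair


def _rand(rng, n):
    return "".join(np.frombuffer(b"ACGT", "S1")[rng.integers(0, 4, n)].astype(str))


# ---------------------------------------------------------------------------
# NG50 / LG50
# ---------------------------------------------------------------------------


def oracle_ng(lengths, genome_size):
    acc = 0
    for i, ln in enumerate(sorted(lengths, reverse=True)):
        acc += ln
        if acc > genome_size / 2:
            return ln, i + 1
    return 0, 0


def test_ng50_example():
    seqs = ["A" * n for n in (5, 4, 3, 2, 1)]
    st = assembly_stats(seqs, genome_size=10, min_len=0)
    assert (st.scaffold_ng50, st.scaffold_lg50) == (4, 2)


def test_single_sequence_covers_genome():
    st = assembly_stats(["A" * 100], genome_size=100, min_len=0)
    assert (st.scaffold_ng50, st.scaffold_lg50) == (100, 1)


def test_contig_split_at_n_runs():
    assert split_contigs("AAAANNAAA") == ["AAAA", "AAA"]
    st = assembly_stats(["AAAANNAAA"], genome_size=7, min_len=0)
    assert st.contig_ng50 == 4 and st.pct_gaps == pytest.approx(200 / 9)


def test_ng50_undefined_when_assembly_too_small(caplog):
    import logging
    with caplog.at_level(logging.WARNING, logger="diphase"):
        st = assembly_stats(["A" * 10], genome_size=1000, min_len=0)
    assert st.scaffold_ng50 == 0 and not st.ng50_defined


def test_min_len_filter_drops_short_blocks():
    st = assembly_stats(["A" * 499, "A" * 600], genome_size=1000, min_len=500)
    assert st.total_bp == 600 and st.n_seqs == 1


def test_stats_match_sort_and_scan_oracle_on_random_multisets():
    rng = np.random.default_rng(4)
    for _ in range(1000):
        n = int(rng.integers(1, 40))
        lengths = rng.integers(1, 5000, size=n).tolist()
        gsize = int(rng.integers(1, 60000))
        seqs = ["A" * ln for ln in lengths]
        kept = [ln for ln in lengths if ln >= 500]
        st = assembly_stats(seqs, genome_size=gsize)
        assert (st.scaffold_ng50, st.scaffold_lg50) == oracle_ng(kept, gsize)


# ---------------------------------------------------------------------------
# fragment recall / precision
# ---------------------------------------------------------------------------


def test_identical_blocks_score_perfectly(rng):
    truth = [_rand(rng, 5000), _rand(rng, 5000)]
    pm = fragment_recall_precision(truth, truth, 1000)
    assert pm.recall == 1.0 and pm.precision == 1.0 and pm.f_measure == 1.0


def test_half_coverage_gives_half_recall(rng):
    truth = [_rand(rng, 4000)]
    blocks = [truth[0][:2000]]
    pm = fragment_recall_precision(blocks, truth, 1000)
    assert pm.recall == 0.5 and pm.precision == 1.0


def test_single_mismatch_fails_exact_match(rng):
    truth = [_rand(rng, 1000)]
    mutated = "A" + truth[0][1:] if truth[0][0] != "A" else "C" + truth[0][1:]
    pm = fragment_recall_precision([mutated], truth, 1000)
    assert pm.recall == 0.0


def test_recall_invariant_under_reverse_complement(rng):
    truth = [_rand(rng, 6000), _rand(rng, 6000)]
    blocks = [truth[0], truth[1][:3000]]
    fwd = fragment_recall_precision(blocks, truth, 1000)
    rc = fragment_recall_precision([revcomp(b) for b in blocks], truth, 1000)
    assert fwd.recall == rc.recall and fwd.precision == rc.precision


def test_fragments_drop_trailing_partial_and_n(rng):
    seq = _rand(rng, 2500)
    withn = seq[:500] + "N" + seq[501:]
    frags = fragment_sequences([withn], 1000)
    assert len(frags) == 1  # first fragment has the N, third is partial


# ---------------------------------------------------------------------------
# heterozygous 1k-mer pairs (uses minimap2)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted_haplotypes():
    rng = np.random.default_rng(12)
    hap_a = _rand(rng, 50_000)
    b = list(hap_a)
    positions = list(range(250, 50_000, 500))  # exactly 2 SNVs per kbp
    for p in positions:
        b[p] = "A" if b[p] != "A" else "G"
    return hap_a, "".join(b), positions


def test_het_pairs_match_truth_table(planted_haplotypes):
    hap_a, hap_b, positions = planted_haplotypes
    pairs = build_het_pairs([("A", hap_a), ("B", hap_b)], min_exact=1)
    assert 45 <= len(pairs) <= 50
    for p in pairs:
        n_snv = sum(1 for q in positions if p.pos_a <= q < p.pos_a + 1000)
        assert p.heterozygosity == pytest.approx(n_snv / 1000)
        assert p.seq_a != p.seq_b


def test_identical_sources_yield_no_pairs(planted_haplotypes):
    hap_a, _, _ = planted_haplotypes
    assert build_het_pairs([("A", hap_a), ("A2", hap_a)], min_exact=1) == []


def test_low_identity_sources_yield_no_pairs(rng):
    a = _rand(rng, 5000)
    b = _rand(rng, 5000)  # unrelated: identity far below 0.8
    assert build_het_pairs([("A", a), ("B", b)], min_exact=1) == []


def test_quality_masking():
    assert mask_by_quality("ACGT", [41, 40, 2, 60]) == "ANNT"


# ---------------------------------------------------------------------------
# phased pair rate
# ---------------------------------------------------------------------------


def _pairs_from(positions, hap_a, hap_b):
    return [HetKmerPair(hap_a[p : p + 1000], hap_b[p : p + 1000],
                        "A", "B", p, p, 0.002) for p in positions]


def test_rate_one_when_both_sides_present(rng):
    a, b = _rand(rng, 4000), _rand(rng, 4000)
    pairs = _pairs_from([0, 1000, 2000], a, b)
    rate, windows = phased_pair_rate([a, b], pairs)
    assert rate == 1.0


def test_pair_with_one_side_missing_is_unphased(rng):
    a, b = _rand(rng, 3000), _rand(rng, 3000)
    pairs = _pairs_from([0], a, b)
    rate, _ = phased_pair_rate([a], pairs)  # only haplotype A assembled
    assert rate == 0.0


def test_window_rate_three_of_four(rng):
    a, b = _rand(rng, 6000), _rand(rng, 6000)
    pairs = _pairs_from([0, 1000, 2000, 3000], a, b)
    blocks = [a, b[:3000]]  # fourth pair's B side missing
    rate, windows = phased_pair_rate(blocks, pairs, window=100_000)
    assert rate == 0.75
    assert windows[0].n_pairs == 4 and windows[0].n_phased == 3


def test_bubble_phased_requires_both_sides_of_one_pair(rng):
    a, b = _rand(rng, 2000), _rand(rng, 2000)
    pairs = _pairs_from([0], a, b)
    _, windows = phased_pair_rate([a, b], pairs, bubble_pairs=[(a, b)])
    assert windows[0].n_bubble_phased == 1
    _, windows = phased_pair_rate([a, b], pairs,
                                  bubble_pairs=[(a, _rand(rng, 2000))])
    assert windows[0].n_bubble_phased == 0


# ---------------------------------------------------------------------------
# reference-absent bubbles (uses minimap2)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("case", ["present", "absent", "short"])
def test_reference_absent_bubble_screen(case):
    rng = np.random.default_rng(31)
    reference = _rand(rng, 150_000)
    if case == "present":
        prim = reference[10_000:130_000]
        sec = prim
        truth = [prim]
    elif case == "absent":
        prim = _rand(rng, 120_000)  # novel sequence, absent from reference
        sec = prim
        truth = [prim]
    else:  # short novel bubble: below the 100-kbp pair-length filter
        prim = _rand(rng, 25_000)
        sec = prim
        truth = [prim]
    out = find_reference_absent_bubbles(
        [(prim, sec)], [("ref", reference)], truth)
    if case == "absent":
        assert len(out) == 1 and out[0].unaligned_rate >= 0.25
    else:
        assert out == []


# ---------------------------------------------------------------------------
# switch errors
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def switch_truth():
    rng = np.random.default_rng(9)
    hap_a = _rand(rng, 20_000)
    b = list(hap_a)
    for p in range(100, 20_000, 200):  # 0.5% het, 5 SNVs per fragment
        b[p] = "A" if b[p] != "A" else "T"
    return hap_a, "".join(b)


def test_pure_block_has_no_errors(switch_truth):
    hap_a, hap_b = switch_truth
    counts = count_switch_errors([hap_a[:10_000]], hap_a, hap_b)
    assert counts.switches == 0 and counts.misassemblies == 0
    assert counts.n_assigned > 0


def test_haplotype_chimera_counts_one_switch(switch_truth):
    hap_a, hap_b = switch_truth
    block = hap_a[:5000] + hap_b[5000:10_000]  # same locus, hap flip
    counts = count_switch_errors([block], hap_a, hap_b)
    assert counts.switches == 1
    assert counts.misassemblies == 0


def test_translocated_segment_is_a_misassembly(switch_truth):
    hap_a, hap_b = switch_truth
    block = hap_a[:5000] + hap_a[12_000:15_000] + hap_a[5000:8000]
    counts = count_switch_errors([block], hap_a, hap_b)
    assert counts.misassemblies >= 1 and counts.switches == 0
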