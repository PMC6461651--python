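"""Evaluation statistics for phased assemblies.

Covers the full benchmark toolbox: NG50/LG50 assembly statistics,
heterozygous 1k-mer pairs distilled from a trusted source set, phasing
recall / precision / F-measure over fixed-length fragments, per-window
phased-pair rates, the screen for bubbles absent from a reference genome,
and a switch-error / mis-assembly classifier.

"Exact match" is strand-symmetric throughout: assemblies are
strand-arbitrary, so a fragment matches if either it or its reverse
complement occurs.  Fragmenting always starts at position 0 and the
trailing partial fragment is discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from ._kmer import revcomp
from .paf import PafRecord, align_all_vs_all, align_to, cs_to_alignment

log = logging.getLogger("diphase")


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------


@dataclass
class AssemblyStats:
    total_bp: int
    n_seqs: int
    scaffold_ng50: int
    scaffold_lg50: int
    contig_ng50: int
    contig_lg50: int
    pct_gaps: float
    genome_size: int
    min_len: int
    ng50_defined: bool


def _ng(lengths: list[int], genome_size: int) -> tuple[int, int, bool]:
    """NG50 / LG50 by sort-and-scan (cumulative length must exceed half the
    genome size); (0, 0, False) when half the genome is never passed."""
    acc = 0
    for i, ln in enumerate(sorted(lengths, reverse=True)):
        acc += ln
        if 2 * acc > genome_size:
            return ln, i + 1, True
    return 0, 0, False


def split_contigs(seq: str) -> list[str]:
    """Split a scaffold at every run of one or more Ns."""
    return [p for p in seq.replace("N", " ").split() if p]


def assembly_stats(seqs: list[str], genome_size: int, min_len: int = 500
                   ) -> AssemblyStats:
    """Scaffold and contig NG50/LG50 over sequences of length >= min_len.

    NG50 is the largest length L such that sequences of length >= L sum to
    at least half the genome size; LG50 counts those sequences.  Contig
    statistics are computed after splitting the retained scaffolds at N
    runs.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    kept = [s for s in seqs if len(s) >= min_len]
    lengths = [len(s) for s in kept]
    total = sum(lengths)
    s_ng, s_lg, defined = _ng(lengths, genome_size)
    if not defined:
        log.warning("assembly_stats: total %d bp < half of genome size %d; "
                    "NG50 undefined (reported as 0)", total, genome_size)
    contig_lengths = [len(c) for s in kept for c in split_contigs(s)]
    c_ng, c_lg, _ = _ng(contig_lengths, genome_size)
    n_bases = sum(s.count("N") for s in kept)
    return AssemblyStats(
        total_bp=total, n_seqs=len(kept),
        scaffold_ng50=s_ng, scaffold_lg50=s_lg,
        contig_ng50=c_ng, contig_lg50=c_lg,
        pct_gaps=100.0 * n_bases / total if total else 0.0,
        genome_size=genome_size, min_len=min_len, ng50_defined=defined,
    )


# ---------------------------------------------------------------------------
# fragment-based recall / precision
# ---------------------------------------------------------------------------


@dataclass
class PhasingMetrics:
    recall: float
    precision: float
    f_measure: float
    n_truth_fragments: int = 0
    n_block_fragments: int = 0


def fragment_sequences(seqs: list[str], fragment_len: int) -> list[str]:
    """Non-overlapping fragments from position 0; N-containing and trailing
    partial fragments are dropped."""
    out = []
    for s in seqs:
        for i in range(0, len(s) - fragment_len + 1, fragment_len):
            f = s[i : i + fragment_len]
            if "N" not in f:
                out.append(f)
    return out


def _haystack(seqs: list[str]) -> str:
    return "|".join(seqs)


def _matches(hay: str, fragment: str) -> bool:
    return fragment in hay or revcomp(fragment) in hay


def fragment_recall_precision(blocks: list[str], truth: list[str],
                              fragment_len: int = 1000) -> PhasingMetrics:
    """Exact-match recall and precision of fixed-length fragments.

    Recall: fraction of truth fragments present verbatim (either strand) in
    the blocks.  Precision: fraction of block fragments present in the
    truth.  F-measure is their harmonic mean.
    """
    if fragment_len <= 0:
        raise ValueError("fragment_len must be positive")
    tfrags = fragment_sequences(truth, fragment_len)
    bfrags = fragment_sequences(blocks, fragment_len)
    bhay = _haystack(blocks)
    thay = _haystack(truth)
    rec = (sum(_matches(bhay, f) for f in tfrags) / len(tfrags)) if tfrags else 0.0
    prec = (sum(_matches(thay, f) for f in bfrags) / len(bfrags)) if bfrags else 0.0
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return PhasingMetrics(rec, prec, f, len(tfrags), len(bfrags))


# ---------------------------------------------------------------------------
# heterozygous 1k-mer pairs
# ---------------------------------------------------------------------------


@dataclass
class HetKmerPair:
    seq_a: str  # from the alignment target
    seq_b: str  # from the query
    source_a: str
    source_b: str
    pos_a: int  # start on the target sequence
    pos_b: int
    heterozygosity: float


def mask_by_quality(seq: str, quals: list[int], threshold: int = 40) -> str:
    """Mask bases with quality value <= threshold as N."""
    return "".join("N" if q <= threshold else c for c, q in zip(seq, quals))


def _alignment_blocks(rec: PafRecord, block_bases: int):
    """Split one alignment into blocks where the shorter side has
    ``block_bases`` non-gap bases; yields (t_seq, q_seq, t_start, matches,
    columns)."""
    t_aln, q_aln = cs_to_alignment(rec.cs or "")
    t_nongap = sum(c != "-" for c in t_aln)
    q_nongap = sum(c != "-" for c in q_aln)
    short_is_t = t_nongap <= q_nongap
    tpos = rec.tstart
    count = 0
    t_buf: list[str] = []
    q_buf: list[str] = []
    start_t = tpos
    matches = 0
    cols = 0
    for tc, qc in zip(t_aln, q_aln):
        t_buf.append(tc)
        q_buf.append(qc)
        cols += 1
        if tc == qc and tc != "-":
            matches += 1
        if tc != "-":
            tpos += 1
        count += (tc != "-") if short_is_t else (qc != "-")
        if count == block_bases:
            yield ("".join(t_buf).replace("-", ""),
                   "".join(q_buf).replace("-", ""), start_t, matches, cols)
            t_buf, q_buf = [], []
            count = 0
            matches = 0
            cols = 0
            start_t = tpos


def build_het_pairs(sources: list[tuple[str, str]],
                    qualities: dict[str, list[int]] | None = None,
                    quality_threshold: int = 40,
                    block_bases: int = 1000,
                    min_exact: int = 2,
                    min_identity: float = 0.8,
                    min_aln_len: int = 500) -> list[HetKmerPair]:
    """Distil heterozygous 1k-mer pairs from a trusted sequence set.

    All-vs-all alignment; near-exact alignments (edit distance <= N bases in
    both aligned regions, i.e. same-haplotype or self matches) are
    discarded; per sequence the best remaining hit by match count is kept,
    filtered at identity >= 0.8 and length >= 500, and split into blocks in
    which the shorter side holds ``block_bases`` bases.  Blocks containing N
    or no difference are dropped, and both sides must have at least
    ``min_exact`` exact matches in the source set.
    """
    named = [(n, mask_by_quality(s, qualities[n], quality_threshold)
              if qualities and n in qualities else s) for n, s in sources]
    if not any(len(s) >= block_bases for _, s in named):
        return []
    records = align_all_vs_all(named)
    usable: list[PafRecord] = []
    for rec in records:
        if rec.qname == rec.tname or rec.cs is None:
            continue
        t_aln, q_aln = cs_to_alignment(rec.cs)
        n_bases = t_aln.count("N") + q_aln.count("N")
        nm = rec.edit_distance
        if nm is not None and nm <= n_bases:
            continue  # near-exact: self or same-haplotype alignment
        usable.append(rec)
    best: dict[str, PafRecord] = {}
    for rec in usable:
        cur = best.get(rec.qname)
        if cur is None or (rec.matches, rec.tname) > (cur.matches, cur.tname):
            best[rec.qname] = rec
    hay = _haystack([s for _, s in named])
    pairs: list[HetKmerPair] = []
    for qname in sorted(best):
        rec = best[qname]
        if rec.identity < min_identity or rec.aln_len < min_aln_len:
            continue
        for t_seq, q_seq, t_start, matches, cols in _alignment_blocks(rec, block_bases):
            if "N" in t_seq or "N" in q_seq:
                continue
            if t_seq == q_seq or cols == matches:
                continue  # homozygous block
            het = 1.0 - matches / cols
            def n_exact(s: str) -> int:
                return hay.count(s) + hay.count(revcomp(s))
            if n_exact(t_seq) < min_exact or n_exact(q_seq) < min_exact:
                continue
            pairs.append(HetKmerPair(
                seq_a=t_seq, seq_b=q_seq, source_a=rec.tname,
                source_b=rec.qname, pos_a=t_start, pos_b=-1,
                heterozygosity=het,
            ))
    return pairs


# ---------------------------------------------------------------------------
# phased 1k-mer pair rates
# ---------------------------------------------------------------------------


@dataclass
class WindowRate:
    window: int
    n_pairs: int
    n_phased: int
    n_bubble_phased: int
    mean_heterozygosity: float

    @property
    def rate(self) -> float:
        return self.n_phased / self.n_pairs if self.n_pairs else 0.0


def phased_pair_rate(blocks: list[str], pairs: list[HetKmerPair],
                     window: int = 1_000_000,
                     bubble_pairs: list[tuple[str, str]] | None = None
                     ) -> tuple[float, list[WindowRate]]:
    """Rate of exactly phased pairs, overall and per source window.

    A pair is phased iff both sequences occur exactly (either strand) in the
    block set; it is bubble-phased iff its two sides land in the two members
    of one bubble pair.
    """
    hay = _haystack(blocks)
    per_window: dict[int, list[HetKmerPair]] = defaultdict(list)
    for p in pairs:
        per_window[p.pos_a // window].append(p)
    out = []
    total = phased = 0
    for w in sorted(per_window):
        ps = per_window[w]
        n_ph = 0
        n_bub = 0
        for p in ps:
            ok = _matches(hay, p.seq_a) and _matches(hay, p.seq_b)
            n_ph += ok
            if ok and bubble_pairs:
                for prim, sec in bubble_pairs:
                    ab = _matches(prim, p.seq_a) and _matches(sec, p.seq_b)
                    ba = _matches(prim, p.seq_b) and _matches(sec, p.seq_a)
                    if ab or ba:
                        n_bub += 1
                        break
        het = sum(p.heterozygosity for p in ps) / len(ps)
        out.append(WindowRate(w, len(ps), n_ph, n_bub, het))
        total += len(ps)
        phased += n_ph
    overall = phased / total if total else 0.0
    return overall, out


# ---------------------------------------------------------------------------
# reference-absent bubbles
# ---------------------------------------------------------------------------


@dataclass
class AbsentBubble:
    bubble_index: int
    total_len: int
    n_fragments: int
    n_unaligned: int

    @property
    def unaligned_rate(self) -> float:
        return self.n_unaligned / self.n_fragments if self.n_fragments else 0.0


def find_reference_absent_bubbles(bubble_pairs: list[tuple[str, str]],
                                  reference: list[tuple[str, str]],
                                  truth: list[str],
                                  fragment_len: int = 1000,
                                  min_pair_len: int = 100_000,
                                  min_rate: float = 0.25,
                                  min_aln_len: int = 500,
                                  min_identity: float = 0.9) -> list[AbsentBubble]:
    """Screen phased bubbles for sequence absent from a reference genome.

    Each bubble (primary + secondary) is cut into 1-kbp fragments (N
    fragments dropped); fragments whose best reference alignment is shorter
    than 500 bases or below 0.9 identity are reference-unaligned; those are
    kept only when exactly present in the truth set (ruling out
    mis-assembly).  A bubble is reported when primary+secondary length is
    >= 100 kbp and the confirmed-unaligned fragment rate is >= 0.25.
    """
    thay = _haystack(truth)
    out = []
    for bi, (prim, sec) in enumerate(bubble_pairs, 1):
        frags = fragment_sequences([prim, sec], fragment_len)
        if not frags:
            continue
        named = [(f"b{bi}_f{j}", f) for j, f in enumerate(frags)]
        records = align_to(reference, named) if reference else []
        best: dict[str, PafRecord] = {}
        for rec in records:
            cur = best.get(rec.qname)
            if cur is None or rec.matches > cur.matches:
                best[rec.qname] = rec
        n_unaligned = 0
        for name, frag in named:
            rec = best.get(name)
            aligned = (rec is not None and rec.aln_len >= min_aln_len
                       and rec.identity >= min_identity)
            if not aligned and _matches(thay, frag):
                n_unaligned += 1
        ab = AbsentBubble(bi, len(prim) + len(sec), len(frags), n_unaligned)
        if ab.total_len >= min_pair_len and ab.unaligned_rate >= min_rate:
            out.append(ab)
    return out


# ---------------------------------------------------------------------------
# switch errors
# ---------------------------------------------------------------------------


@dataclass
class SwitchCounts:
    switches: int = 0
    misassemblies: int = 0
    n_fragments: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0  # fragments present in both haplotypes
    n_unassigned: int = 0
    per_block: list = field(default_factory=list)


def _locate(hap: str, frag: str) -> tuple[int, int] | None:
    p = hap.find(frag)
    if p >= 0:
        return p, 0
    p = hap.find(revcomp(frag))
    if p >= 0:
        return p, 1
    return None


def count_switch_errors(blocks: list[str], hap_a: str, hap_b: str,
                        fragment_len: int = 1000,
                        slack: int | None = None,
                        max_edit_frac: float = 0.2) -> SwitchCounts:
    """Count phasing switches and structural mis-assemblies in phased blocks.

    Each block is cut into consecutive fragments and every fragment is
    assigned a haplotype of origin by exact match (falling back to the best
    semi-global alignment when neither haplotype contains it verbatim).
    Fragments matching both haplotypes (homozygous) or neither are excluded
    from adjacency and counted separately.  For each adjacent assigned pair,
    truth positions must advance collinearly by one fragment length (within
    ``slack``, default = fragment_len): a haplotype flip at collinear
    coordinates is a switch error; a collinearity violation (order,
    orientation or distance) is a mis-assembly.
    """
    slack = fragment_len if slack is None else slack
    counts = SwitchCounts()
    for block in blocks:
        assigned = []  # (fragment index, hap, pos, strand)
        frags = [block[i : i + fragment_len]
                 for i in range(0, len(block) - fragment_len + 1, fragment_len)]
        for fi, frag in enumerate(frags):
            counts.n_fragments += 1
            if "N" in frag:
                counts.n_unassigned += 1
                continue
            la = _locate(hap_a, frag)
            lb = _locate(hap_b, frag)
            if la and lb:
                counts.n_ambiguous += 1
                continue
            if la or lb:
                hap = "A" if la else "B"
                pos, strand = la or lb
            else:
                ra = edlib.align(frag, hap_a, mode="HW", task="locations")
                rb = edlib.align(frag, hap_b, mode="HW", task="locations")
                da, db = ra["editDistance"], rb["editDistance"]
                lim = max_edit_frac * fragment_len
                if da == db or min(da, db) > lim:
                    counts.n_unassigned += 1
                    continue
                hap = "A" if da < db else "B"
                loc = (ra if da < db else rb)["locations"][0]
                pos, strand = loc[0], 0
            counts.n_assigned += 1
            assigned.append((fi, hap, pos, strand))
        sw = ma = 0
        for (fi, h1, p1, s1), (fj, h2, p2, s2) in zip(assigned, assigned[1:]):
            expected = (fj - fi) * fragment_len
            if s1 != s2:
                collinear = False
            else:
                delta = (p2 - p1) if s1 == 0 else (p1 - p2)
                collinear = abs(delta - expected) <= slack
            if h1 != h2:
                if collinear:
                    sw += 1
                else:
                    ma += 1
            elif not collinear:
                ma += 1
        counts.switches += sw
        counts.misassemblies += ma
        counts.per_block.append((sw, ma, len(assigned)))
    return counts
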