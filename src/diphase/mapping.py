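"""Placing reads on graph nodes and deriving link evidence.

Short reads are placed by exact, genome-wide-unique matches of fixed-length
seeds (32, 64 and 96 bases), trying the shortest length first to maximise
sensitivity; a seed occurring more than once across the node set never
yields a placement.  Seeds are taken at the front, centre and back of each
read on both strands.  Because homologous bubble branches share their
(k-1)-base flanks, seeds that do not overlap a heterozygous site are
automatically ambiguous between the two haplotypes — placements on branch
nodes are therefore haplotype-specific, which is exactly what the untangling
evidence needs.

Link evidence comes from read pairs whose mates land on different nodes
(gap estimated from the library insert size), from single reads straddling
two adjacent nodes (gap read off the read coordinates), from selected long
read alignments spanning nodes, and from linked-read barcode sharing.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._kmer import encode, pack_windows, rc_codes, revcomp

log = logging.getLogger("diphase")

SEED_LENGTHS = (32, 64, 96)
BARCODE_MIN_READS = 4  # (node, barcode) entries with fewer reads are dropped

_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)


def _mix(x: np.ndarray) -> np.ndarray:
    x = (x ^ (x >> np.uint64(30))) * _C1
    x = (x ^ (x >> np.uint64(27))) * _C2
    return x ^ (x >> np.uint64(31))


def _hash_windows(codes: np.ndarray, length: int) -> np.ndarray:
    """64-bit hash of every window of ``length`` bases (any length >= 1)."""
    n = codes.size
    cnt = n - length + 1
    if cnt <= 0:
        return np.empty(0, dtype=np.uint64)
    h = np.full(cnt, np.uint64(length), dtype=np.uint64)
    off = 0
    while off < length:
        chunk = min(32, length - off)
        w = pack_windows(codes, chunk)[off : off + cnt]
        h = _mix(h ^ _mix(w + np.uint64(off + 1)))
        off += chunk
    return h


@dataclass
class _SeedLevel:
    uniq_hash: np.ndarray
    uniq_node: np.ndarray
    uniq_off: np.ndarray
    uniq_strand: np.ndarray
    dup_hash: np.ndarray

    def lookup(self, q: np.ndarray):
        pos = np.searchsorted(self.uniq_hash, q)
        pos_c = np.minimum(pos, max(len(self.uniq_hash) - 1, 0))
        if len(self.uniq_hash):
            found = self.uniq_hash[pos_c] == q
        else:
            found = np.zeros(len(q), dtype=bool)
        node = np.where(found, self.uniq_node[pos_c] if len(self.uniq_node) else 0, -1)
        off = np.where(found, self.uniq_off[pos_c] if len(self.uniq_off) else 0, 0)
        strand = np.where(found, self.uniq_strand[pos_c] if len(self.uniq_strand) else 0, 0)
        if len(self.dup_hash):
            dpos = np.searchsorted(self.dup_hash, q)
            dpos_c = np.minimum(dpos, len(self.dup_hash) - 1)
            ambig = self.dup_hash[dpos_c] == q
        else:
            ambig = np.zeros(len(q), dtype=bool)
        return found, node.astype(np.int64), off.astype(np.int64), strand.astype(np.int8), ambig


class NodeIndex:
    """Exact-match seed index over both strands of a set of node sequences.

    Windows containing N are never indexed.  For each seed length the index
    records windows that are unique across the whole node set *including
    reverse complements* (hash -> node, forward-strand offset, strand), plus
    the set of duplicated window hashes (ambiguous seeds).  Querying with a
    read window therefore yields the strand directly, and a seed shared by
    two homologous branches is ambiguous no matter how the branches happen
    to be stored.
    """

    def __init__(self, named_seqs: list[tuple[int, str]], seed_lengths=SEED_LENGTHS):
        self.seed_lengths = tuple(seed_lengths)
        self.ids = [nid for nid, _ in named_seqs]
        self.seqs = {nid: s for nid, s in named_seqs}
        self.lengths = {nid: len(s) for nid, s in named_seqs}
        joined = "N".join(s for _, s in named_seqs) if named_seqs else ""
        codes = encode(joined) if joined else np.empty(0, dtype=np.uint8)
        rcodes = rc_codes(codes)
        total = codes.size
        starts = np.zeros(len(named_seqs), dtype=np.int64)
        pos = 0
        for i, (_, s) in enumerate(named_seqs):
            starts[i] = pos
            pos += len(s) + 1
        ids_arr = np.asarray(self.ids, dtype=np.int64)
        self._levels: dict[int, _SeedLevel] = {}
        if codes.size:
            nvalid = np.concatenate([[0], np.cumsum(codes > 3)])
        for L in self.seed_lengths:
            hf = _hash_windows(codes, L)
            if hf.size:
                valid = (nvalid[L:] - nvalid[:-L]) == 0
                wpos = np.nonzero(valid)[0]
                hfv = hf[valid]
                hr = _hash_windows(rcodes, L)[::-1][valid]  # rc of window at wpos
                h = np.concatenate([hfv, hr])
                wp = np.concatenate([wpos, wpos])
                strands = np.concatenate(
                    [np.zeros(len(wpos), np.int8), np.ones(len(wpos), np.int8)]
                )
            else:
                h = np.empty(0, dtype=np.uint64)
                wp = np.empty(0, dtype=np.int64)
                strands = np.empty(0, dtype=np.int8)
            order = np.argsort(h, kind="stable")
            hs = h[order]
            wp = wp[order]
            strands = strands[order]
            dup = np.zeros(len(hs), dtype=bool)
            if len(hs) > 1:
                eq = hs[1:] == hs[:-1]
                dup[1:] |= eq
                dup[:-1] |= eq
            keep = ~dup
            node_i = np.searchsorted(starts, wp[keep], side="right") - 1
            self._levels[L] = _SeedLevel(
                uniq_hash=hs[keep],
                uniq_node=ids_arr[node_i] if keep.any() else np.empty(0, dtype=np.int64),
                uniq_off=wp[keep] - starts[node_i] if keep.any() else np.empty(0, dtype=np.int64),
                uniq_strand=strands[keep],
                dup_hash=np.unique(hs[dup]),
            )

    def lookup(self, L: int, qhash: np.ndarray):
        return self._levels[L].lookup(qhash)

    def find_patterns(self, patterns: list[str]) -> list:
        """Batched :meth:`find_pattern` (one vectorised hash/lookup pass)."""
        L = self.seed_lengths[0]
        probes: list[tuple[int, int]] = []  # (pattern index, probe offset)
        chunks: list[str] = []
        for pi, pat in enumerate(patterns):
            if len(pat) < L:
                continue
            for off in (0, len(pat) - L):
                probes.append((pi, off))
                chunks.append(pat[off : off + L])
        results: list = [None] * len(patterns)
        if not chunks:
            return results
        codes = encode("N".join(chunks))
        h = _hash_windows(codes, L)
        qh = h[np.arange(len(chunks), dtype=np.int64) * (L + 1)]
        found, node, off, strand, ambig = self.lookup(L, qh)
        done = [False] * len(patterns)
        for j, (pi, probe_off) in enumerate(probes):
            if done[pi]:
                continue
            pat = patterns[pi]
            if found[j]:
                done[pi] = True
                nid = int(node[j])
                seq = self.seqs[nid]
                if strand[j] == 0:
                    start = int(off[j]) - probe_off
                    want = pat
                else:
                    start = int(off[j]) - (len(pat) - L - probe_off)
                    want = revcomp(pat)
                if 0 <= start and start + len(pat) <= len(seq) and \
                        seq[start : start + len(pat)] == want:
                    results[pi] = (nid, start, int(strand[j]))
            elif ambig[j] and results[pi] is None:
                results[pi] = "ambiguous"
        return results

    def find_pattern(self, pattern: str) -> tuple[int, int, int] | None | str:
        """Locate a pattern uniquely in the node set (either strand).

        Returns (node, offset, strand) for a verified unique hit — offset on
        the node's stored strand, strand 1 meaning the node holds the
        reverse complement — None when absent, or "ambiguous" when every
        probe seed is duplicated.
        """
        L = self.seed_lengths[0]
        plen = len(pattern)
        if plen < L:
            return None
        ambig_seen = False
        for probe_off in (0, plen - L):
            h = _hash_windows(encode(pattern[probe_off : probe_off + L]), L)
            found, node, off, strand, ambig = self.lookup(L, h)
            if found[0]:
                nid = int(node[0])
                seq = self.seqs[nid]
                if strand[0] == 0:
                    start = int(off[0]) - probe_off
                    want = pattern
                else:
                    start = int(off[0]) - (plen - L - probe_off)
                    want = revcomp(pattern)
                if 0 <= start and start + plen <= len(seq):
                    if seq[start : start + plen] == want:
                        return (nid, start, int(strand[0]))
                return None
            if ambig[0]:
                ambig_seen = True
        return "ambiguous" if ambig_seen else None


class ReadSeeds:
    """Cached per-read seed hashes; reads must share one fixed length."""

    def __init__(self, reads: list[str], seed_lengths=SEED_LENGTHS):
        if not reads:
            raise ValueError("empty read set")
        self.read_length = len(reads[0])
        if any(len(r) != self.read_length for r in reads):
            raise ValueError("short-read mapping requires fixed-length reads")
        self.n = len(reads)
        rl = self.read_length
        self.seed_lengths = tuple(L for L in seed_lengths if L <= rl)
        joined = "\n".join(reads)
        codes = encode(joined)
        stride = rl + 1
        idx = np.arange(self.n, dtype=np.int64) * stride
        # seeds tile the read: offsets 0, L, 2L, ... plus one flush with the
        # read end, so every base lies inside at least one seed window (the
        # strand of a placement comes from the index hit)
        self.hashes: dict[tuple[int, int], np.ndarray] = {}
        self.offsets: dict[int, list[int]] = {}
        nvalid = np.concatenate([[0], np.cumsum(codes > 3)])
        sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
        for L in self.seed_lengths:
            hf = _hash_windows(codes, L)
            bad = (nvalid[L:] - nvalid[:-L]) > 0
            hf = np.where(bad, sentinel, hf)
            offs = list(range(0, rl - L + 1, L))
            if offs[-1] != rl - L:
                offs.append(rl - L)
            self.offsets[L] = offs
            for j, o in enumerate(offs):
                self.hashes[(L, j)] = hf[idx + o]


@dataclass
class Placements:
    """Vectorised read placements on a node set.

    ``pos`` is the start of the aligned copy on the node's stored strand:
    for strand 0 the node contains the read at [pos, pos+len); for strand 1
    it contains its reverse complement there.  front/back give the raw hit
    (node, window offset on the node's forward strand, strand) of the
    first/last seed of the read, used for single-read link evidence.
    """

    node: np.ndarray  # int64, -1 if unplaced
    pos: np.ndarray
    strand: np.ndarray  # 0/1
    front_node: np.ndarray
    front_pos: np.ndarray
    front_strand: np.ndarray
    back_node: np.ndarray
    back_pos: np.ndarray
    back_strand: np.ndarray
    level: np.ndarray  # seed length that placed the read
    read_length: int

    @property
    def placed(self) -> np.ndarray:
        return self.node >= 0

    def slice(self, lo: int, hi: int) -> "Placements":
        return Placements(
            self.node[lo:hi], self.pos[lo:hi], self.strand[lo:hi],
            self.front_node[lo:hi], self.front_pos[lo:hi], self.front_strand[lo:hi],
            self.back_node[lo:hi], self.back_pos[lo:hi], self.back_strand[lo:hi],
            self.level[lo:hi], self.read_length,
        )


def map_reads(index: NodeIndex, seeds: ReadSeeds) -> Placements:
    """Place every read by its shortest exact genome-wide-unique seed.

    At each seed length the front, centre and back seeds are tried in that
    order; a read whose seeds at one length are all either absent or
    duplicated escalates to the next length only if at least one seed was
    duplicated (an absent seed stays absent in any longer seed containing
    it).
    """
    n = seeds.n
    rl = seeds.read_length
    node = np.full(n, -1, dtype=np.int64)
    pos = np.zeros(n, dtype=np.int64)
    strand = np.zeros(n, dtype=np.int8)
    fnode = np.full(n, -1, dtype=np.int64)
    fpos = np.zeros(n, dtype=np.int64)
    fstr = np.zeros(n, dtype=np.int8)
    bnode = np.full(n, -1, dtype=np.int64)
    bpos = np.zeros(n, dtype=np.int64)
    bstr = np.zeros(n, dtype=np.int8)
    lvl = np.zeros(n, dtype=np.int64)
    unresolved = np.ones(n, dtype=bool)

    for L in seeds.seed_lengths:
        if L not in index._levels or not unresolved.any():
            continue
        q = np.nonzero(unresolved)[0]
        offs = seeds.offsets[L]
        hits = [index.lookup(L, seeds.hashes[(L, j)][q]) for j in range(len(offs))]
        known = np.zeros(len(q), dtype=bool)
        any_ambig = np.zeros(len(q), dtype=bool)
        for h in hits:
            known |= h[0]
            any_ambig |= h[4]
        pending = ~known & any_ambig
        # first (leftmost) matching seed decides the placement
        pick_node = np.full(len(q), -1, dtype=np.int64)
        pick_off = np.zeros(len(q), dtype=np.int64)
        pick_str = np.zeros(len(q), dtype=np.int8)
        pick_o = np.zeros(len(q), dtype=np.int64)
        for j in range(len(offs) - 1, -1, -1):
            found, hn, ho, hs, _ = hits[j]
            pick_node = np.where(found, hn, pick_node)
            pick_off = np.where(found, ho, pick_off)
            pick_str = np.where(found, hs, pick_str)
            pick_o = np.where(found, offs[j], pick_o)
        # read-start position on the node's stored strand
        start = np.where(pick_str == 0, pick_off - pick_o,
                         pick_off - (rl - L - pick_o))
        first, last = hits[0], hits[-1]
        ids = q[known]
        node[ids] = pick_node[known]
        pos[ids] = start[known]
        strand[ids] = pick_str[known]
        lvl[ids] = L
        fnode[ids] = np.where(first[0][known], first[1][known], -1)
        fpos[ids] = first[2][known]
        fstr[ids] = first[3][known]
        bnode[ids] = np.where(last[0][known], last[1][known], -1)
        bpos[ids] = last[2][known]
        bstr[ids] = last[3][known]
        unresolved[q[known | ~pending]] = False

    return Placements(node, pos, strand, fnode, fpos, fstr,
                      bnode, bpos, bstr, lvl, rl)


# ---------------------------------------------------------------------------
# link evidence
# ---------------------------------------------------------------------------


@dataclass
class LinkStore:
    """Bundled link evidence between oriented node ends.

    A key ((a, ea), (b, eb)) with (a, ea) <= (b, eb) joins end ``ea`` of node
    a to end ``eb`` of node b (end 1 = right end of the stored strand).
    """

    gaps: dict = field(default_factory=lambda: defaultdict(list))
    sources: dict = field(default_factory=lambda: defaultdict(lambda: defaultdict(int)))
    weights: dict = field(default_factory=lambda: defaultdict(int))

    @staticmethod
    def key(a, ea, b, eb):
        if (b, eb) < (a, ea):
            a, ea, b, eb = b, eb, a, ea
        return ((a, ea), (b, eb))

    def add(self, a, ea, b, eb, gap, source, weight: int = 1):
        k = self.key(a, ea, b, eb)
        self.gaps[k].append(gap)
        self.sources[k][source] += 1
        self.weights[k] += weight

    def support(self, a, ea, b, eb) -> int:
        return len(self.gaps.get(self.key(a, ea, b, eb), ()))

    def gap(self, a, ea, b, eb) -> float:
        g = self.gaps.get(self.key(a, ea, b, eb))
        return float(np.median(g)) if g else 0.0

    def count_between(self, a: int, b: int) -> int:
        """Total link support between two nodes regardless of ends."""
        total = 0
        for ea in (0, 1):
            for eb in (0, 1):
                total += self.support(a, ea, b, eb)
        return total

    def weight_between(self, a: int, b: int) -> int:
        total = 0
        for ea in (0, 1):
            for eb in (0, 1):
                total += self.weights.get(self.key(a, ea, b, eb), 0)
        return total

    def items(self):
        return self.gaps.items()


def _mate_end(length: int, p: int, strand: int, rl: int) -> tuple[int, int]:
    """(node end the mate points at, distance from its 5' end to that end)."""
    if strand == 0:
        return 1, length - p
    return 0, p + rl


def pair_links(index: NodeIndex, pl1: Placements, pl2: Placements,
               insert_mean: float, source: str, outward: bool = False,
               store: LinkStore | None = None) -> tuple[LinkStore, np.ndarray]:
    """Derive paired links and same-node insert observations.

    For outward-facing (mate-pair) libraries the mate orientations are
    flipped before the node ends are computed.
    """
    store = store if store is not None else LinkStore()
    rl = pl1.read_length
    both = pl1.placed & pl2.placed
    s1 = pl1.strand.copy()
    s2 = pl2.strand.copy()
    if outward:
        s1 ^= 1
        s2 ^= 1
    same = both & (pl1.node == pl2.node)
    idx = np.nonzero(same)[0]
    opp = s1[idx] != s2[idx]
    pp = np.where(s1[idx] == 0, pl1.pos[idx], pl2.pos[idx])
    pm = np.where(s1[idx] == 0, pl2.pos[idx], pl1.pos[idx])
    span = pm + rl - pp
    inserts = span[opp & (span > 0)]
    cross = both & (pl1.node != pl2.node)
    max_dist = insert_mean * 1.5  # a mate cannot sit further from the node
    # end than the insert reaches; interior-interior hits are junk
    for i in np.nonzero(cross)[0]:
        a, b = int(pl1.node[i]), int(pl2.node[i])
        ea, d1 = _mate_end(index.lengths[a], int(pl1.pos[i]), int(s1[i]), rl)
        eb, d2 = _mate_end(index.lengths[b], int(pl2.pos[i]), int(s2[i]), rl)
        if d1 > max_dist or d2 > max_dist:
            continue
        gap = insert_mean - d1 - d2
        store.add(a, ea, b, eb, gap, source)
    return store, np.asarray(inserts, dtype=np.int64)


def single_read_links(index: NodeIndex, pl: Placements, source: str = "single-read",
                      store: LinkStore | None = None) -> LinkStore:
    """Links from single reads whose front and back seeds hit different nodes."""
    store = store if store is not None else LinkStore()
    rl = pl.read_length
    mask = pl.placed & (pl.front_node >= 0) & (pl.back_node >= 0) & (
        pl.front_node != pl.back_node
    )
    for i in np.nonzero(mask)[0]:
        nf, nb = int(pl.front_node[i]), int(pl.back_node[i])
        pf, pb = int(pl.front_pos[i]), int(pl.back_pos[i])
        sf, sb = int(pl.front_strand[i]), int(pl.back_strand[i])
        L = int(pl.level[i])
        # read coordinates at which the read leaves nf and enters nb; the
        # front seed occupies read coords [0, L), the back seed [rl-L, rl)
        if sf == 0:
            exit_a, ea = index.lengths[nf] - pf, 1
        else:
            exit_a, ea = L + pf, 0
        if sb == 0:
            entry_b, eb = (rl - L) - pb, 0
        else:
            entry_b, eb = rl + pb - index.lengths[nb], 1
        gap = entry_b - exit_a
        if abs(gap) > rl:  # a single read cannot imply a longer gap/overlap
            continue
        store.add(nf, ea, nb, eb, gap, source)
    return store


@dataclass
class BarcodeTable:
    """Read counts per (node, barcode); entries below the minimum are dropped."""

    counts: dict[tuple[int, str], int] = field(default_factory=dict)

    def barcodes_of(self, node: int) -> dict[str, int]:
        return {bc: c for (n, bc), c in self.counts.items() if n == node}

    def common_barcode_reads(self, a: int, b: int) -> int:
        """Sum of read counts over barcodes shared by nodes a and b."""
        ba = self.barcodes_of(a)
        bb = self.barcodes_of(b)
        return sum(ba[bc] + bb[bc] for bc in ba.keys() & bb.keys())


def parse_bx_tag(header: str) -> str | None:
    """Extract a linked-read barcode from a "BX:Z:" style tag (with or
    without a space after the colon)."""
    for token in header.replace("BX: Z:", "BX:Z:").split():
        if token.startswith("BX:Z:"):
            value = token[5:]
            return value or None
    return None


def count_barcodes(pl: Placements, barcodes: list[str | None],
                   min_reads: int = BARCODE_MIN_READS) -> BarcodeTable:
    raw: dict[tuple[int, str], int] = defaultdict(int)
    skipped = 0
    for i in np.nonzero(pl.placed)[0]:
        bc = barcodes[i]
        if not bc:
            skipped += 1
            continue
        raw[(int(pl.node[i]), bc)] += 1
    if skipped:
        log.warning("count_barcodes: %d placed reads without a barcode tag", skipped)
    table = BarcodeTable({k: c for k, c in raw.items() if c >= min_reads})
    if not table.counts:
        log.warning("count_barcodes: no (node, barcode) entry passed the "
                    ">= %d reads filter", min_reads)
    return table


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------


@dataclass
class LongReadAlignment:
    query: str
    target: int
    qlen: int
    tlen: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: int  # 0 = same strand, 1 = reverse
    matches: int
    aln_len: int

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0

    @property
    def coverage(self) -> float:
        m = min(self.qlen, self.tlen)
        return self.aln_len / m if m else 0.0


def filter_long_alignments(alns: list[LongReadAlignment], k: int) -> list[LongReadAlignment]:
    """Identity/length filter followed by greedy non-overlap selection.

    Keep an alignment iff identity >= 0.8 and (alignment length >= 1000 or
    alignment coverage >= 0.8); then select greedily in decreasing order of
    matched sites such that no two selected alignments of the same query
    overlap by >= k bases on the query.
    """
    cands = [a for a in alns
             if a.identity >= 0.8 and (a.aln_len >= 1000 or a.coverage >= 0.8)]
    cands.sort(key=lambda a: (-a.matches, a.query, a.qstart, a.target))
    selected: list[LongReadAlignment] = []
    for a in cands:
        ok = True
        for s in selected:
            if s.query != a.query:
                continue
            overlap = min(a.qend, s.qend) - max(a.qstart, s.qstart)
            if overlap >= k:
                ok = False
                break
        if ok:
            selected.append(a)
    return selected


def long_read_position(alns: list[LongReadAlignment]) -> float:
    """Length-weighted mean target position over one query-target pair."""
    if not alns:
        raise ValueError("no alignments")
    w = sum(a.aln_len for a in alns)
    return sum(a.tstart * a.aln_len for a in alns) / w


def long_read_links(selected: list[LongReadAlignment], source: str = "long-read",
                    store: LinkStore | None = None) -> LinkStore:
    """Spanning link evidence from queries aligned to multiple nodes.

    The link weight carries the summed matched sites of the two alignments so
    the match-site untangling method can reuse the store.
    """
    store = store if store is not None else LinkStore()
    by_query: dict[str, list[LongReadAlignment]] = defaultdict(list)
    for a in selected:
        by_query[a.query].append(a)
    for query in sorted(by_query):
        chain = sorted(by_query[query], key=lambda a: a.qstart)
        for prev, nxt in zip(chain, chain[1:]):
            if prev.target == nxt.target:
                continue
            gap = nxt.qstart - prev.qend
            ea = 1 if prev.strand == 0 else 0
            eb = 0 if nxt.strand == 0 else 1
            store.add(prev.target, ea, nxt.target, eb, gap, source,
                      weight=prev.matches + nxt.matches)
    return store


def parse_paf(path_or_lines, name_to_id=None) -> list[LongReadAlignment]:
    """Parse PAF records into LongReadAlignment objects.

    ``name_to_id`` optionally maps target names to integer node ids; unmapped
    targets keep a hash of their name.
    """
    if isinstance(path_or_lines, str):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    out = []
    for line in lines:
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            continue
        tname = f[5]
        if name_to_id is not None:
            target = name_to_id[tname]
        else:
            target = int(tname) if tname.isdigit() else abs(hash(tname)) % (1 << 31)
        out.append(LongReadAlignment(
            query=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
            strand=0 if f[4] == "+" else 1,
            target=target, tlen=int(f[6]), tstart=int(f[7]), tend=int(f[8]),
            matches=int(f[9]), aln_len=int(f[10]),
        ))
    return out
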