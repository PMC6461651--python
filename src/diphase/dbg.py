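"""(Gapped) de Bruijn graph construction and the increasing-k iteration.

The graph distinguishes *straight nodes* — maximal non-branching paths,
i.e. contigs — from *junction nodes*, single k-mers with more than one edge
in the same direction.  Adjacent nodes overlap by exactly (k-1) bases.
Bubbles are deliberately never removed: the two branches of a heterozygous
bubble stay in the graph as separate straight nodes and are the raw material
for phasing.  After the first scaffolding round node sequences may contain N
(a "gapped" graph); N acts as a hard break for k-mer extraction.

Orientation convention: orientation 0 is the stored sequence, 1 its reverse
complement.  An edge ((u, ou) -> (v, ov)) means the last (k-1) bases of u in
orientation ou equal the first (k-1) bases of v in orientation ov; the
symmetric edge ((v, 1-ov) -> (u, 1-ou)) is always stored as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmer import (
    KmerTable,
    canonical_kmer_counts,
    count_kmers,
    initial_cutoff,
    revcomp,
)

log = logging.getLogger("diphase")

#: default k schedule parameters
K_INITIAL = 32
K_STEP = 20


@dataclass
class Node:
    id: int
    seq: str
    cov: float
    is_junction: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def oriented(self, o: int) -> str:
        return self.seq if o == 0 else revcomp(self.seq)


class DeBruijnGraph:
    """Bidirected sequence graph with (k-1)-overlap edges."""

    def __init__(self, k: int):
        self.k = k
        self.nodes: dict[int, Node] = {}
        self.adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
        self._next_id = 1
        self.version = 0  # bumped on any node change (cache invalidation)

    # -- construction ------------------------------------------------------
    def add_node(self, seq: str, cov: float, is_junction: bool = False) -> int:
        nid = self._next_id
        self._next_id += 1
        self.version += 1
        self.nodes[nid] = Node(nid, seq, cov, is_junction)
        self.adj[(nid, 0)] = []
        self.adj[(nid, 1)] = []
        return nid

    def add_edge(self, u: int, ou: int, v: int, ov: int) -> None:
        if (v, ov) not in self.adj[(u, ou)]:
            self.adj[(u, ou)].append((v, ov))
        if (u, 1 - ou) not in self.adj[(v, 1 - ov)]:
            self.adj[(v, 1 - ov)].append((u, 1 - ou))

    def remove_node(self, nid: int) -> None:
        self.version += 1
        for o in (0, 1):
            for v, ov in list(self.adj.get((nid, o), [])):
                lst = self.adj.get((v, 1 - ov))
                if lst is not None:
                    self.adj[(v, 1 - ov)] = [e for e in lst if e[0] != nid]
        self.adj.pop((nid, 0), None)
        self.adj.pop((nid, 1), None)
        del self.nodes[nid]

    # -- queries -----------------------------------------------------------
    def successors(self, nid: int, o: int) -> list[tuple[int, int]]:
        """Oriented nodes following (nid, o) through its 3' end."""
        return self.adj[(nid, o)]

    def predecessors(self, nid: int, o: int) -> list[tuple[int, int]]:
        return [(v, 1 - ov) for v, ov in self.adj[(nid, 1 - o)]]

    def straight_nodes(self) -> list[Node]:
        return [n for n in self.nodes.values() if not n.is_junction]

    def junction_nodes(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.is_junction]

    def sequences(self) -> list[str]:
        return [n.seq for n in self.straight_nodes()]

    def total_bases(self) -> int:
        return sum(len(n) for n in self.nodes.values())

    # -- simplification ----------------------------------------------------
    def compress(self) -> int:
        """Merge straight-node chains joined by unique mutual edges.

        Junction nodes with exactly one edge per side (left over after
        untangling removed their other neighbours) are absorbed as well.
        Returns the number of merges performed.
        """
        merged = 0
        changed = True
        while changed:
            changed = False
            for nid in sorted(self.nodes):
                if nid not in self.nodes:
                    continue
                node = self.nodes[nid]
                for o in (0, 1):
                    nxt = self.adj[(nid, o)]
                    if len(nxt) != 1:
                        continue
                    v, ov = nxt[0]
                    if v == nid:
                        continue
                    if len(self.predecessors(v, ov)) != 1:
                        continue
                    vnode = self.nodes[v]
                    # merge v into nid along orientation o
                    useq = node.oriented(o)
                    vseq = vnode.oriented(ov)
                    newseq = useq + vseq[self.k - 1 :]
                    w = len(node) + len(vnode)
                    newcov = (node.cov * len(node) + vnode.cov * len(vnode)) / w
                    after = list(self.adj[(v, ov)])
                    self.remove_node(v)
                    node.seq = newseq if o == 0 else revcomp(newseq)
                    node.cov = newcov
                    node.is_junction = False
                    self.adj[(nid, o)] = []
                    for w2, ow2 in after:
                        if w2 == v:  # self-loop collapsed away
                            continue
                        self.add_edge(nid, o, w2, ow2)
                    merged += 1
                    changed = True
                    break
        return merged

    # -- dump / load -------------------------------------------------------
    def dump_gfa(self, path: str) -> None:
        """GFA-like tab-separated dump (segments with coverage, links)."""
        with open(path, "w") as fh:
            fh.write(f"H\tVN:Z:1.0\tkm:i:{self.k}\n")
            for nid in sorted(self.nodes):
                n = self.nodes[nid]
                kind = "J" if n.is_junction else "S"
                fh.write(f"S\t{nid}\t{n.seq}\tdp:f:{n.cov:.3f}\tnk:A:{kind}\n")
            seen = set()
            for (u, ou), targets in sorted(self.adj.items()):
                for v, ov in targets:
                    key = ((u, ou), (v, ov))
                    rkey = ((v, 1 - ov), (u, 1 - ou))
                    if rkey in seen:
                        continue
                    seen.add(key)
                    fh.write(
                        f"L\t{u}\t{'+' if ou == 0 else '-'}\t{v}\t"
                        f"{'+' if ov == 0 else '-'}\t{self.k - 1}M\n"
                    )

    @classmethod
    def load_gfa(cls, path: str) -> "DeBruijnGraph":
        graph = None
        ids: dict[int, int] = {}
        links = []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "H":
                    k = int(next(p.split(":")[2] for p in parts[1:] if p.startswith("km")))
                    graph = cls(k)
                elif parts[0] == "S":
                    cov = float(next(p.split(":")[2] for p in parts if p.startswith("dp")))
                    kind = next(p.split(":")[2] for p in parts if p.startswith("nk"))
                    ids[int(parts[1])] = graph.add_node(parts[2], cov, kind == "J")
                elif parts[0] == "L":
                    links.append(parts)
        for parts in links:
            graph.add_edge(
                ids[int(parts[1])],
                0 if parts[2] == "+" else 1,
                ids[int(parts[3])],
                0 if parts[4] == "+" else 1,
            )
        return graph


# ---------------------------------------------------------------------------
# graph construction from a k-mer table
# ---------------------------------------------------------------------------


_DECODE_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_HASH_BASE = 0x9E3779B97F4A7C15


def build_graph(table: KmerTable, cutoff: int = 1) -> DeBruijnGraph:
    """Assemble the de Bruijn graph from k-mers with occurrence >= cutoff.

    Maximal non-branching paths become straight nodes; k-mers with more than
    one edge in the same direction become junction nodes.  Per-node coverage
    is the mean occurrence of the constituent k-mers.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    kept = table.filtered(cutoff)
    k = table.k
    if len(kept) == 0:
        log.warning("k-mer table empty after cutoff %d; returning empty graph", cutoff)
        return DeBruijnGraph(k)
    return _graph_from_words(kept.words, kept.counts, k)


def _graph_from_words(words: np.ndarray, counts: np.ndarray, k: int) -> DeBruijnGraph:
    """Vectorised unitig construction over the doubled (both-strand) k-mer set.

    k-mer adjacency is resolved through a 64-bit polynomial rolling hash of
    the full k-mer; with well under 2^32 distinct k-mers the collision
    probability is negligible.
    """
    from ._kmer import decode_matrix

    m = len(counts)
    codes_f = decode_matrix(words, k)
    codes = np.vstack([codes_f, (3 - codes_f)[:, ::-1]])
    counts2 = np.concatenate([counts, counts]).astype(np.float64)
    m2 = 2 * m
    partner = np.concatenate([np.arange(m) + m, np.arange(m)])

    base = np.uint64(_HASH_BASE)
    h = np.zeros(m2, dtype=np.uint64)
    for j in range(k):
        h = h * base + codes[:, j]
    order = np.argsort(h, kind="stable")
    hs = h[order]
    bk1 = np.uint64(pow(_HASH_BASE, k - 1, 1 << 64))
    shifted = (h - codes[:, 0].astype(np.uint64) * bk1) * base
    succ = np.full((m2, 4), -1, dtype=np.int64)
    for b in range(4):
        q = shifted + np.uint64(b)
        pos = np.searchsorted(hs, q)
        posc = np.minimum(pos, m2 - 1)
        hit = hs[posc] == q
        succ[:, b] = np.where(hit, order[posc], -1)
    outdeg = (succ >= 0).sum(axis=1)
    indeg = outdeg[partner]
    junction = (outdeg > 1) | (indeg > 1)

    # chain links between consecutive non-junction k-mers
    usucc = succ.max(axis=1)
    nxt = np.where((outdeg == 1) & ~junction, usucc, -1)
    ok = nxt >= 0
    tgt = nxt[ok]
    good = (~junction[tgt]) & (indeg[tgt] == 1)
    nxt[np.nonzero(ok)[0][~good]] = -1
    prev = np.full(m2, -1, dtype=np.int64)
    prev[nxt[nxt >= 0]] = np.nonzero(nxt >= 0)[0]
    prev[junction] = -1

    # head of each chain by pointer doubling; break cycles at their smallest row
    rows = np.arange(m2)
    p = np.where(prev >= 0, prev, rows)
    niter = max(int(np.ceil(np.log2(max(m2, 2)))) + 1, 1)
    for _ in range(niter):
        p2 = p[p]
        if np.array_equal(p2, p):
            break
        p = p2
    else:
        # cycles remain: break each at its minimum row id (circular unitigs)
        cyc = np.nonzero(p != p[p])[0]
        for r in cyc.tolist():
            cur, seen = r, [r]
            while prev[cur] >= 0 and prev[cur] != r:
                cur = prev[cur]
                seen.append(cur)
                if len(seen) > m2:
                    break
            head = min(seen)
            if prev[head] >= 0:
                nxt[prev[head]] = -1
                prev[head] = -1
        p = np.where(prev >= 0, prev, rows)
        for _ in range(niter):
            p = p[p]
    head = p
    # distance from head by doubling
    dist = (prev >= 0).astype(np.int64)
    hop = np.where(prev >= 0, prev, rows)
    for _ in range(niter):
        dist = dist + np.where(hop != rows, dist[hop], 0)
        hop = hop[hop]

    graph = DeBruijnGraph(k)
    tail_chars = _DECODE_ASCII[codes[:, k - 1]]
    start_of_row: dict[int, tuple[int, int]] = {}
    end_row: dict[tuple[int, int], int] = {}

    nonj = np.nonzero(~junction)[0]
    order2 = nonj[np.lexsort((dist[nonj], head[nonj]))]
    heads_sorted = head[order2]
    bounds = np.nonzero(np.concatenate([[True], heads_sorted[1:] != heads_sorted[:-1]]))[0]
    bounds = np.append(bounds, len(order2))
    blob = _DECODE_ASCII[codes].tobytes().decode("ascii")
    tails = tail_chars.tobytes().decode("ascii")
    seen_pair = set()
    for bi in range(len(bounds) - 1):
        chain = order2[bounds[bi] : bounds[bi + 1]]
        first, last = int(chain[0]), int(chain[-1])
        pair_key = min(first, int(partner[last]))
        if pair_key in seen_pair:
            continue  # reverse-complement copy of an emitted unitig
        seen_pair.add(pair_key)
        seq = blob[first * k : (first + 1) * k] + "".join(tails[int(r)] for r in chain[1:])
        cov = float(counts2[chain].mean())
        nid = graph.add_node(seq, cov, is_junction=False)
        start_of_row[first] = (nid, 0)
        start_of_row[int(partner[last])] = (nid, 1)
        end_row[(nid, 0)] = last
        end_row[(nid, 1)] = int(partner[first])

    for r in np.nonzero(junction)[0].tolist():
        pr = int(partner[r])
        if pr < r and junction[pr]:
            continue
        nid = graph.add_node(blob[r * k : (r + 1) * k], float(counts2[r]),
                             is_junction=True)
        start_of_row[r] = (nid, 0)
        start_of_row[pr] = (nid, 1)
        end_row[(nid, 0)] = r
        end_row[(nid, 1)] = pr

    for (nid, o), last in sorted(end_row.items()):
        for b in range(4):
            s = int(succ[last, b])
            if s < 0:
                continue
            target = start_of_row.get(s)
            if target is not None:
                graph.add_edge(nid, o, target[0], target[1])
    return graph


def contig_graph(reads: list[str], k: int = K_INITIAL, cutoff: int | None = None) -> tuple[DeBruijnGraph, int]:
    """Count k-mers, estimate the coverage cutoff and build the graph."""
    table, hist = count_kmers(reads, k)
    if cutoff is None:
        cutoff = initial_cutoff(hist)
    graph = build_graph(table, cutoff)
    log.info("k=%d: %d k-mers, cutoff %d, %d straight / %d junction nodes",
             k, len(table), cutoff, len(graph.straight_nodes()), len(graph.junction_nodes()))
    return graph, cutoff


def raise_k(graph: DeBruijnGraph, reads: list[str], k_new: int,
            cutoff: int | None = None) -> DeBruijnGraph:
    """Rebuild the graph at a larger k from reads plus previous contigs.

    k-mers from the previous straight nodes are kept even below the coverage
    cutoff so that low-coverage heterozygous paths survive; their occurrence
    is taken from the reads (minimum 1).  The local-minimum scan is meant
    for the error peak of the initial histogram; at larger k callers should
    pass a cutoff scaled from the initial one by the k-mer sampling ratio
    (the default here is a conservative 1).
    """
    if k_new <= graph.k:
        raise ValueError(f"k_new={k_new} must exceed current k={graph.k}")
    contigs = [n.seq for n in graph.straight_nodes() if len(n.seq) >= k_new]
    table, hist = count_kmers(reads, k_new)
    if cutoff is None:
        cutoff = 1
    cwords, _ = canonical_kmer_counts(contigs, k_new)
    keep = table.counts >= cutoff
    if len(cwords):
        # rows of the read table matching a contig k-mer are always kept
        merged = np.vstack([table.words, cwords])
        tags = np.concatenate([np.zeros(len(table.words), np.int8),
                               np.ones(len(cwords), np.int8)])
        rows = np.arange(len(merged))
        order = np.lexsort((tags,) + tuple(merged.T[::-1]))
        srt = merged[order]
        same_as_prev = np.zeros(len(srt), dtype=bool)
        same_as_prev[1:] = (srt[1:] == srt[:-1]).all(axis=1)
        src = tags[order]
        idx = rows[order]
        # a contig row preceded by an equal read row -> mark that read row kept
        dup_contig = same_as_prev & (src == 1)
        read_rows = idx[np.nonzero(dup_contig)[0] - 1]
        keep[read_rows] = True
        # contig k-mers absent from the reads enter with occurrence 1
        absent = (src == 1) & ~same_as_prev
        extra_words = srt[absent]
        extra_counts = np.ones(absent.sum(), dtype=np.int64)
        words = np.vstack([table.words[keep], extra_words])
        counts = np.concatenate([table.counts[keep], extra_counts])
    else:
        words, counts = table.words[keep], table.counts[keep]
    if len(counts) == 0:
        return DeBruijnGraph(k_new)
    return _graph_from_words(words, counts, k_new)


def normalize_coverage(graph: DeBruijnGraph, read_length: int) -> None:
    """Rescale mean k-mer occurrences to base-coverage units (in place).

    A read of length L yields L - k + 1 k-mers, so k-mer occurrence
    understates base depth by (L - k + 1) / L; comparing node coverages
    across graphs built at different k requires this correction.
    """
    span = max(read_length - graph.k + 1, 1)
    factor = read_length / span
    for node in graph.nodes.values():
        node.cov *= factor


def k_schedule(read_length: int, k_initial: int = K_INITIAL, k_step: int = K_STEP,
               k_max: int | None = None) -> list[int]:
    """Increasing-k schedule: k_initial, +k_step, ..., ending exactly at k_max.

    The default cap is half the read length.  A read of length L samples each
    k-mer position with probability (L - k + 1) / L, so pushing k close to L
    starves heterozygous paths (half the homozygous depth) of k-mers and
    fragments the graph; k = L/2 keeps per-haplotype k-mer depth at roughly
    half the base depth.  The last step is clipped to land on k_max.
    """
    cap = k_max if k_max is not None else read_length // 2
    ks = [k_initial]
    while ks[-1] + k_step < cap:
        ks.append(ks[-1] + k_step)
    if cap > ks[-1]:
        ks.append(cap)
    return ks


def assemble_contigs(reads: list[str], k_initial: int = K_INITIAL, k_step: int = K_STEP,
                     k_max: int | None = None) -> tuple[DeBruijnGraph, DeBruijnGraph]:
    """Full contig-assembly iteration.

    Returns (initial_graph, final_graph): the k_initial graph (substrate for
    anchor-bubble detection) and the graph at the final k of the schedule.
    """
    read_length = max((len(r) for r in reads), default=0)
    ks = k_schedule(read_length, k_initial, k_step, k_max)
    graph, cutoff0 = contig_graph(reads, ks[0])
    initial = graph
    span0 = max(read_length - ks[0] + 1, 1)
    for k in ks[1:]:
        # scale the initial cutoff by the k-mer sampling ratio at this k
        cut = max(1, int(round(cutoff0 * (read_length - k + 1) / span0)))
        graph = raise_k(graph, reads, k, cutoff=cut)
        log.info("raise_k -> k=%d (cutoff %d): %d straight / %d junction nodes",
                 k, cut, len(graph.straight_nodes()), len(graph.junction_nodes()))
    return initial, graph
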