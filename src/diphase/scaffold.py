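"""Scaffold graph construction, scaffold untangling, haplotype synteny-based
correction, and bubble pairing.

Scaffold nodes are sequences (possibly containing N gaps) with integer
scaffold-IDs.  Link evidence from read mapping is bundled per oriented node
end; bundles below the minimum-link threshold are dropped, transitively
explained long-range bundles are reduced away, and mutually unambiguous
ends are chained into scaffolds with the consensus gap rendered as Ns
(negative gaps attempt an exact overlap merge first).

Haplotype synteny-based correction assumes chromosome-scale synteny between
homologous scaffolds: anchor bubbles assign to every contig of a node the
scaffold-ID of its homologous counterpart (b_i), the dominant counterpart
B_max is found by length-weighted vote, and a division score walks the
contig list to cut away edge regions that disagree with B_max.  Nodes are
finally paired into primary/secondary bubbles ("megabubble" output).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._kmer import revcomp
from .mapping import LinkStore, NodeIndex
from .untangle import (
    AnchorBubbleSet,
    CrossStructure,
    EVIDENCE_RATIO,
    Evidence,
    R_UPPER_THRESHOLD,
    Resolution,
    resolve_cross,
)

log = logging.getLogger("diphase")

MIN_LINK_THRESHOLD = 2
GAP_SLACK = 500  # tolerance when deciding whether one bundle explains another


@dataclass
class ScaffoldNode:
    id: int
    seq: str
    cov: float = 0.0

    def __len__(self) -> int:
        return len(self.seq)

    def oriented(self, o: int) -> str:
        return self.seq if o == 0 else revcomp(self.seq)

    def non_n(self) -> int:
        return len(self.seq) - self.seq.count("N")

    def contigs(self) -> list[tuple[int, int]]:
        """Half-open (start, end) intervals of the N-free contigs, in order."""
        out = []
        start = None
        for i, ch in enumerate(self.seq):
            if ch == "N":
                if start is not None:
                    out.append((start, i))
                    start = None
            elif start is None:
                start = i
        if start is not None:
            out.append((start, len(self.seq)))
        return out


@dataclass
class ScaffoldEdge:
    support: int
    gap: float
    sources: dict = field(default_factory=dict)


class ScaffoldGraph:
    """Scaffold nodes plus bundled link edges between oriented node ends."""

    def __init__(self, min_links: int = MIN_LINK_THRESHOLD):
        self.nodes: dict[int, ScaffoldNode] = {}
        self.edges: dict[tuple, ScaffoldEdge] = {}
        self.excluded: set[int] = set()  # short, anchor-free nodes
        self.min_links = min_links
        self._next_id = 1

    def add_node(self, seq: str, cov: float = 0.0, nid: int | None = None) -> int:
        if nid is None:
            nid = self._next_id
        self._next_id = max(self._next_id, nid + 1)
        self.nodes[nid] = ScaffoldNode(nid, seq, cov)
        return nid

    def end_edges(self, nid: int, end: int) -> list[tuple]:
        out = []
        for key in self.edges:
            (a, ea), (b, eb) = key
            if (a, ea) == (nid, end) or (b, eb) == (nid, end):
                out.append(key)
        return out

    def other_end(self, key: tuple, nid: int, end: int) -> tuple[int, int]:
        (a, ea), (b, eb) = key
        return (b, eb) if (a, ea) == (nid, end) else (a, ea)


def build_scaffold_graph(nodes: list[tuple[int, str, float]], store: LinkStore,
                         min_links: int = MIN_LINK_THRESHOLD,
                         min_node_len: int = 0,
                         anchored: set[int] | None = None,
                         gap_slack: int = GAP_SLACK) -> ScaffoldGraph:
    """Bundle link evidence into scaffold edges.

    Nodes shorter than ``min_node_len`` are excluded from the graph unless
    they contain an anchor bubble.  Bundles below ``min_links`` are dropped;
    a bundle whose gap places its target beyond a nearer bundled neighbour
    (within ``gap_slack``) is transitively reduced away.
    """
    anchored = anchored or set()
    g = ScaffoldGraph(min_links)
    for nid, seq, cov in nodes:
        g.add_node(seq, cov, nid)
        if len(seq) < min_node_len and nid not in anchored:
            g.excluded.add(nid)
    raw: dict[tuple, ScaffoldEdge] = {}
    for key, gaps in sorted(store.items()):
        (a, ea), (b, eb) = key
        if a not in g.nodes or b not in g.nodes or a == b:
            continue
        if a in g.excluded or b in g.excluded:
            continue
        if len(gaps) < min_links:
            continue
        raw[key] = ScaffoldEdge(len(gaps), float(np.median(gaps)),
                                dict(store.sources[key]))
    # transitive reduction per end
    drop: set[tuple] = set()
    by_end: dict[tuple[int, int], list[tuple]] = defaultdict(list)
    for key in raw:
        (a, ea), (b, eb) = key
        by_end[(a, ea)].append(key)
        by_end[(b, eb)].append(key)
    for end, keys in sorted(by_end.items()):
        if len(keys) < 2:
            continue
        nid, e = end
        keys_sorted = sorted(keys, key=lambda kk: raw[kk].gap)
        nearest = keys_sorted[0]
        bn, _ = (nearest[1] if nearest[0] == end else nearest[0])
        near_gap = raw[nearest].gap
        blen = g.nodes[bn].non_n()
        # the slack never exceeds half the in-between node, so an
        # equal-distance sibling (the homologous branch) is never reduced
        slack = min(gap_slack, blen // 2)
        for kk in keys_sorted[1:]:
            if raw[kk].gap >= near_gap + blen - slack:
                drop.add(kk)
    g.edges = {k: v for k, v in raw.items() if k not in drop}
    return g


def _try_overlap_join(a: str, b: str, gap: float, probe: int = 60) -> str | None:
    """Exact suffix/prefix merge for a negative gap estimate."""
    target = int(round(-gap))
    lo = max(8, target - probe)
    hi = min(len(a), len(b), target + probe)
    for ov in sorted(range(lo, hi + 1), key=lambda x: abs(x - target)):
        if a[-ov:] == b[:ov]:
            return a + b[ov:]
    return None


def join_with_gap(a: str, b: str, gap: float) -> str:
    """Concatenate two sequences across an estimated gap.

    Negative gaps try an exact overlap merge; otherwise the gap is rendered
    as max(gap, 1) Ns so the join stays visible in FASTA output.
    """
    if gap < 0:
        merged = _try_overlap_join(a, b, gap)
        if merged is not None:
            return merged
    return a + "N" * max(int(round(gap)), 1) + b


def _mutual_partners(g: ScaffoldGraph) -> dict[tuple[int, int], tuple]:
    """End -> edge for ends whose single unreduced bundle is reciprocal."""
    cand: dict[tuple[int, int], tuple | None] = {}
    by_end: dict[tuple[int, int], list[tuple]] = defaultdict(list)
    for key in g.edges:
        (a, ea), (b, eb) = key
        by_end[(a, ea)].append(key)
        by_end[(b, eb)].append(key)
    for end, keys in by_end.items():
        cand[end] = keys[0] if len(keys) == 1 else None
    partners = {}
    for end, key in cand.items():
        if key is None:
            continue
        other = g.other_end(key, *end)
        if cand.get(other) == key:
            partners[end] = key
    return partners


def join_scaffolds(g: ScaffoldGraph) -> tuple[list[tuple[int, str, float]], int]:
    """Chain mutually unambiguous ends into scaffolds.

    Returns the new node list (id, seq, cov) and the number of joins made.
    Node identity: a chain keeps the id of its largest member.
    """
    partners = _mutual_partners(g)
    used: set[int] = set()
    out: list[tuple[int, str, float]] = []
    joins = 0
    for nid in sorted(g.nodes):
        if nid in used:
            continue
        # walk left from (nid, 0) to find the chain start
        cur, orient = nid, 0
        seen = {nid}
        while True:
            back_end = (cur, 0 if orient == 0 else 1)
            key = partners.get(back_end)
            if key is None:
                break
            (pn, pe) = g.other_end(key, *back_end)
            if pn in seen:
                break  # circular chain
            seen.add(pn)
            cur, orient = pn, 0 if pe == 1 else 1
        # walk right collecting members
        chain = [(cur, orient)]
        gaps = []
        seen = {cur}
        while True:
            tail = chain[-1]
            fwd_end = (tail[0], 1 if tail[1] == 0 else 0)
            key = partners.get(fwd_end)
            if key is None:
                break
            nn, ne = g.other_end(key, *fwd_end)
            if nn in seen:
                break
            seen.add(nn)
            chain.append((nn, 0 if ne == 0 else 1))
            gaps.append(g.edges[key].gap)
        members = [c[0] for c in chain]
        used.update(members)
        if len(chain) == 1:
            node = g.nodes[nid]
            out.append((nid, node.seq, node.cov))
            continue
        seq = g.nodes[chain[0][0]].oriented(chain[0][1])
        for (nn, no), gap in zip(chain[1:], gaps):
            seq = join_with_gap(seq, g.nodes[nn].oriented(no), gap)
        joins += len(chain) - 1
        w = sum(len(g.nodes[nn]) for nn, _ in chain)
        cov = sum(g.nodes[nn].cov * len(g.nodes[nn]) for nn, _ in chain) / max(w, 1)
        keep_id = max(members, key=lambda x: (len(g.nodes[x]), x))
        out.append((keep_id, seq, cov))
    return sorted(out), joins


# ---------------------------------------------------------------------------
# scaffold-graph untangling
# ---------------------------------------------------------------------------


def find_scaffold_crosses(g: ScaffoldGraph, c_hetero: float,
                          r_upper: float = R_UPPER_THRESHOLD) -> list[CrossStructure]:
    """Cross structures whose edges are link bundles rather than overlaps.

    The externals' orientations are chosen so that ``left`` externals flow
    into the centre and ``right`` externals flow out of it, matching the
    de Bruijn convention; gaps are recorded on the structure for sequence
    assembly.
    """
    crosses = []
    for cid in sorted(g.nodes):
        if cid in g.excluded:
            continue
        cnode = g.nodes[cid]
        if c_hetero > 0 and cnode.cov > 2 * r_upper * c_hetero:
            continue
        sides = []
        ok = True
        for end in (0, 1):
            keys = g.end_edges(cid, end)
            if len(keys) != 2:
                ok = False
                break
            ext = []
            for key in keys:
                e, ee = g.other_end(key, cid, end)
                if len(g.end_edges(e, ee)) != 1:
                    ok = False
                    break
                ext.append((e, ee, g.edges[key].gap))
            if not ok or len({x[0] for x in ext}) != 2:
                ok = False
                break
            sides.append(sorted(ext))
        if not ok:
            continue
        ids = [x[0] for x in sides[0] + sides[1]]
        if len(set(ids)) != 4 or cid in ids:
            continue
        if c_hetero > 0 and min(g.nodes[x].cov for x in ids) > r_upper * c_hetero:
            continue
        # left: external end ee faces the centre, so the external is oriented
        # with that end on its right; right: that end on its left
        left = [(e, 0 if ee == 1 else 1) for e, ee, _ in sides[0]]
        right = [(e, 0 if ee == 0 else 1) for e, ee, _ in sides[1]]
        cs = CrossStructure(center=cid, j_left=None, j_right=None,
                            left=left, right=right,
                            center_len=len(cnode), center_cov=cnode.cov)
        cs.gaps = {  # type: ignore[attr-defined]
            (e, "L"): gp for e, _, gp in sides[0]
        } | {(e, "R"): gp for e, _, gp in sides[1]}
        crosses.append(cs)
    return crosses


def apply_scaffold_untangle(g: ScaffoldGraph, cs: CrossStructure,
                            res: Resolution) -> list[int]:
    """Duplicate the centre scaffold into the two decided paths."""
    cnode = g.nodes[cs.center]
    pairs = cs.parallel if res.decision == "parallel" else cs.cross
    new_ids = []
    for (eid, eo), (fid, fo) in pairs:
        gl = cs.gaps[(eid, "L")]  # type: ignore[attr-defined]
        gr = cs.gaps[(fid, "R")]  # type: ignore[attr-defined]
        # centre orientation: left externals enter end 0 of the centre
        seq = join_with_gap(g.nodes[eid].oriented(eo), cnode.seq, gl)
        seq = join_with_gap(seq, g.nodes[fid].oriented(fo), gr)
        w = len(g.nodes[eid]) + len(cnode) + len(g.nodes[fid])
        cov = (g.nodes[eid].cov * len(g.nodes[eid]) + cnode.cov / 2 * len(cnode)
               + g.nodes[fid].cov * len(g.nodes[fid])) / w
        keep = max((eid, fid), key=lambda x: (len(g.nodes[x]), x))
        new_ids.append((keep, seq, cov))
    for nid in {cs.center, cs.left[0][0], cs.left[1][0],
                cs.right[0][0], cs.right[1][0]}:
        del g.nodes[nid]
        g.excluded.discard(nid)
        for key in [k for k in g.edges
                    if k[0][0] == nid or k[1][0] == nid]:
            del g.edges[key]
    out = []
    for keep, seq, cov in new_ids:
        out.append(g.add_node(seq, cov, keep))
    return out


def untangle_scaffold_graph(g: ScaffoldGraph, evidence: Evidence,
                            c_hetero: float,
                            r_upper: float = R_UPPER_THRESHOLD,
                            ratio: float = EVIDENCE_RATIO,
                            decision_log: list | None = None) -> int:
    """One round of cross-structure untangling on the scaffold graph."""
    crosses = find_scaffold_crosses(g, c_hetero, r_upper)
    used: set[int] = set()
    n = 0
    for cs in crosses:
        if cs.node_ids & used:
            continue
        if any(x not in g.nodes for x in cs.node_ids):
            continue
        res = resolve_cross(cs, evidence, ratio)
        if decision_log is not None:
            decision_log.append(("scaffold", cs.center, res.method,
                                 res.winning_score, res.alt_score, res.decision))
        if res.decision == "unresolved":
            continue
        apply_scaffold_untangle(g, cs, res)
        used |= cs.node_ids
        n += 1
    return n


# ---------------------------------------------------------------------------
# anchor location and haplotype synteny-based correction
# ---------------------------------------------------------------------------


@dataclass
class AnchorHit:
    anchor_id: int
    node_a: int
    pos_a: int
    node_b: int
    pos_b: int
    length: int


def locate_anchors(index: NodeIndex, anchors: AnchorBubbleSet) -> list[AnchorHit]:
    """Find the unique occurrence of both branches of every anchor bubble.

    Anchors whose branches are absent, ambiguous, or land on the same node
    are skipped (a same-node hit means the bubble was never phased apart).
    """
    patterns: list[str] = []
    for ab in anchors.bubbles:
        patterns.append(ab.branch_a)
        patterns.append(ab.branch_b)
    located = index.find_patterns(patterns)
    hits = []
    for i, ab in enumerate(anchors.bubbles):
        la, lb = located[2 * i], located[2 * i + 1]
        if not isinstance(la, tuple) or not isinstance(lb, tuple):
            continue
        if la[0] == lb[0]:
            continue
        hits.append(AnchorHit(ab.id, la[0], la[1], lb[0], lb[1],
                              int(ab.mean_length)))
    return hits


def annotate_contigs(node: ScaffoldNode, hits_here: list[tuple[int, int]]
                     ) -> tuple[list[int], list[int]]:
    """Per-contig counterpart scaffold-IDs b_i and lengths l_i.

    ``hits_here`` is [(position on node, counterpart scaffold-ID)].  When a
    contig carries anchors voting for different counterparts the majority
    (by count, ties to the smaller ID) wins for b_i; the minority votes then
    surface through the division score of Eq-style correction.
    """
    contigs = node.contigs()
    b = []
    l = []
    for start, end in contigs:
        votes: dict[int, int] = defaultdict(int)
        for pos, cp in hits_here:
            if start <= pos < end:
                votes[cp] += 1
        if votes:
            b.append(min(votes, key=lambda x: (-votes[x], x)))
        else:
            b.append(0)
        l.append(end - start)
    return b, l


@dataclass
class SyntenyDivision:
    node: int
    b_max: int
    d_min: int  # 0-based contig indices, inclusive
    d_max: int
    score_min: list[float]
    score_max: list[float]
    corrected: bool


def compute_division(b: list[int], l: list[int], node_id: int = 0,
                     b_max: int | None = None) -> SyntenyDivision | None:
    """Dominant-counterpart range of a node with score-based correction.

    B_max maximises the summed contig length L_sum(x) over counterpart IDs
    x != 0 (ties to the smaller ID); pass ``b_max`` to exercise the score
    recursion against a fixed counterpart.  d_min/d_max are the first/last
    contigs annotated B_max.  The division score S walks d_min..d_max
    (base 0; -l_x on B_max contigs, +l_x on other-counterpart contigs,
    carry on anchor-free contigs); a positive maximum moves d_min to its
    argmax (ties to the smaller index), and a mirrored pass over
    [new d_min, d_max] moves d_max.  The corrected boundary contig is
    retained even when it is not itself a B_max anchor.
    Returns None when no contig has a counterpart.
    """
    if len(b) != len(l):
        raise ValueError("b and l must have equal length")
    lsum: dict[int, float] = defaultdict(float)
    for bi, li in zip(b, l):
        if bi != 0:
            lsum[bi] += li
    if not lsum:
        return None
    if b_max is None:
        b_max = min(lsum, key=lambda x: (-lsum[x], x))
    idx = [i for i, bi in enumerate(b) if bi == b_max]
    if not idx:
        return None
    d_min, d_max = min(idx), max(idx)

    def walk(rng) -> list[float]:
        s = []
        prev = 0.0
        for x in rng:
            if b[x] == 0:
                cur = prev
            elif b[x] == b_max:
                cur = prev - l[x]
            else:
                cur = prev + l[x]
            s.append(cur)
            prev = cur
        return s

    s_min = walk(range(d_min, d_max + 1))
    corrected = False
    new_min = d_min
    if s_min and max(s_min) > 0:
        new_min = d_min + int(np.argmax(s_min))  # first maximum
        corrected = True
    s_max = walk(range(d_max, new_min - 1, -1))
    new_max = d_max
    if s_max and max(s_max) > 0:
        new_max = d_max - int(np.argmax(s_max))
        corrected = True
    return SyntenyDivision(node_id, b_max, new_min, new_max, s_min, s_max,
                           corrected)


def synteny_correct(nodes: list[tuple[int, str, float]],
                    anchors: AnchorBubbleSet,
                    max_rounds: int = 20,
                    division_log: list | None = None
                    ) -> tuple[list[tuple[int, str, float]], int]:
    """Iteratively divide nodes that violate haplotype synteny.

    Each round re-locates the anchors, trims every node to its corrected
    [d_min, d_max] contig range (out-of-range pieces become new nodes), and
    additionally divides nodes at internal contigs whose counterpart contigs
    sit at the edge of another node.  Stops when a round makes no division.
    """
    if not anchors.bubbles:
        return nodes, 0
    nodes = list(nodes)
    next_id = max((nid for nid, _, _ in nodes), default=0) + 1
    total = 0
    for _ in range(max_rounds):
        index = NodeIndex(sorted((nid, seq) for nid, seq, _ in nodes),
                          seed_lengths=(32,))
        hits = locate_anchors(index, anchors)
        per_node: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for h in hits:
            per_node[h.node_a].append((h.pos_a, h.node_b))
            per_node[h.node_b].append((h.pos_b, h.node_a))
        sn = {nid: ScaffoldNode(nid, seq, cov) for nid, seq, cov in nodes}
        # contig index of each anchor position, for the edge-contig rule
        contig_idx: dict[tuple[int, int], int] = {}
        ncontigs: dict[int, int] = {}
        for nid, node in sn.items():
            cts = node.contigs()
            ncontigs[nid] = len(cts)
            for ci, (s, e) in enumerate(cts):
                for pos, _ in per_node.get(nid, []):
                    if s <= pos < e:
                        contig_idx[(nid, pos)] = ci
        divisions = 0
        out: list[tuple[int, str, float]] = []
        for nid, seq, cov in nodes:
            node = sn[nid]
            ann = per_node.get(nid)
            if not ann:
                out.append((nid, seq, cov))
                continue
            b, l = annotate_contigs(node, ann)
            div = compute_division(b, l, nid)
            cts = node.contigs()
            cut_points: set[int] = set()
            if div is not None and (div.d_min > 0 or div.d_max < len(cts) - 1):
                if div.d_min > 0:
                    cut_points.add(div.d_min)
                if div.d_max < len(cts) - 1:
                    cut_points.add(div.d_max + 1)
            # edge-contig rule: divide at internal contigs whose counterpart
            # is the edge contig of another node
            for pos, cp in ann:
                ci = contig_idx.get((nid, pos))
                if ci is None or ci == 0 or ci == len(cts) - 1:
                    continue
                # find the counterpart contig index
                for cpos, back in per_node.get(cp, []):
                    if back != nid:
                        continue
                    cci = contig_idx.get((cp, cpos))
                    if cci is not None and ncontigs[cp] > 1 and (
                            cci == 0 or cci == ncontigs[cp] - 1):
                        cut_points.add(ci)
                        break
            cut_points = {c for c in cut_points if 0 < c < len(cts)}
            if not cut_points:
                out.append((nid, seq, cov))
                continue
            divisions += len(cut_points)
            if division_log is not None:
                division_log.append((nid, sorted(cut_points),
                                     div.b_max if div else 0))
            bounds = [0] + sorted(cut_points) + [len(cts)]
            for piece_i in range(len(bounds) - 1):
                clo, chi = bounds[piece_i], bounds[piece_i + 1]
                lo = cts[clo][0]
                hi = cts[chi - 1][1]
                piece = seq[lo:hi]
                if piece_i == 0:
                    out.append((nid, piece, cov))
                else:
                    out.append((next_id, piece, cov))
                    next_id += 1
        nodes = out
        total += divisions
        log.info("synteny round: %d divisions", divisions)
        if divisions == 0:
            break
    return nodes, total


# ---------------------------------------------------------------------------
# bubble pairing
# ---------------------------------------------------------------------------


@dataclass
class BubblePair:
    primary_id: int
    secondary_id: int
    primary: str
    secondary: str
    n_anchors: int


@dataclass
class PhasedBlockSet:
    bubbles: list[BubblePair] = field(default_factory=list)
    nonbubbles: list[tuple[int, str]] = field(default_factory=list)

    def all_sequences(self) -> list[str]:
        out = []
        for bp in self.bubbles:
            out.append(bp.primary)
            out.append(bp.secondary)
        out.extend(seq for _, seq in self.nonbubbles)
        return out

    def fasta_records(self) -> list[tuple[str, str]]:
        recs = []
        for i, bp in enumerate(self.bubbles, 1):
            recs.append((f"primary_bubble_{i}", bp.primary))
            recs.append((f"secondary_bubble_{i}", bp.secondary))
        for j, (_, seq) in enumerate(self.nonbubbles, 1):
            recs.append((f"nonbubble_{j}", seq))
        return recs

    def pairing_table(self) -> list[tuple[int, int, int, int, int]]:
        return [(i, bp.primary_id, bp.secondary_id, len(bp.primary),
                 len(bp.secondary)) for i, bp in enumerate(self.bubbles, 1)]


def pair_bubbles(nodes: list[tuple[int, str, float]],
                 anchors: AnchorBubbleSet) -> PhasedBlockSet:
    """Pair anchor-containing nodes into primary/secondary bubbles.

    Nodes whose dominant counterparts are reciprocal become a bubble; the
    member with more non-N bases is the primary (ties to the smaller
    scaffold-ID).  Everything else is emitted as non-bubble sequence.
    """
    index = NodeIndex(sorted((nid, seq) for nid, seq, _ in nodes),
                      seed_lengths=(32,))
    hits = locate_anchors(index, anchors) if anchors.bubbles else []
    votes: dict[int, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for h in hits:
        votes[h.node_a][h.node_b] += h.length
        votes[h.node_b][h.node_a] += h.length
    best = {nid: min(v, key=lambda x: (-v[x], x)) for nid, v in votes.items()}
    blocks = PhasedBlockSet()
    seqs = {nid: seq for nid, seq, _ in nodes}
    paired: set[int] = set()
    for nid in sorted(best):
        if nid in paired:
            continue
        cp = best[nid]
        if best.get(cp) != nid:
            log.info("node %d counterpart %d is not reciprocal — non-bubble",
                     nid, cp)
            continue
        paired.add(nid)
        paired.add(cp)
        a, bseq = seqs[nid], seqs[cp]
        na = len(a) - a.count("N")
        nb = len(bseq) - bseq.count("N")
        if na > nb or (na == nb and nid < cp):
            pid, sid, pseq, sseq = nid, cp, a, bseq
        else:
            pid, sid, pseq, sseq = cp, nid, bseq, a
        blocks.bubbles.append(BubblePair(pid, sid, pseq, sseq,
                                         int(sum(1 for h in hits
                                                 if {h.node_a, h.node_b} == {nid, cp}))))
    for nid, seq, _ in sorted(nodes):
        if nid not in paired:
            blocks.nonbubbles.append((nid, seq))
    return blocks
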