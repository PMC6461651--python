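"""Anchor-bubble detection and cross-structure untangling.

A *simple bubble* is two straight branch nodes between two junction nodes
(four edges); in a diploid graph most simple bubbles are heterozygous allele
pairs.  The length-weighted mean coverage of all simple-bubble branches,
``c_hetero``, estimates the per-haplotype depth of non-repetitive sequence;
bubbles whose branches stay below ``r_upper_threshold * c_hetero`` are kept
as *anchor bubbles* for the later haplotype-synteny correction.

A *cross structure* is a straight centre node whose two flanking junctions
each fan out to two external straight nodes — the signature of a collapsed
homozygous segment between heterozygous flanks.  Untangling duplicates the
centre into the two haplotype paths when one pairing of externals (parallel
or cross) collects at least four times the link / match-site / barcode
evidence of the alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .dbg import DeBruijnGraph
from .mapping import BarcodeTable, LinkStore

log = logging.getLogger("diphase")

R_UPPER_THRESHOLD = 1.75
EVIDENCE_RATIO = 4
UNTANGLE_MAX_ITERS = 5
BARCODE_CENTER_MAX_LEN = 200_000  # barcode method skipped at / above this


@dataclass
class AnchorBubble:
    id: int
    branch_a: str  # sequence of one branch, oriented along the bubble
    branch_b: str
    cov_a: float
    cov_b: float

    @property
    def mean_length(self) -> float:
        return (len(self.branch_a) + len(self.branch_b)) / 2


@dataclass
class AnchorBubbleSet:
    bubbles: list[AnchorBubble]
    c_hetero: float
    r_upper_threshold: float = R_UPPER_THRESHOLD
    n_simple_bubbles: int = 0

    def __len__(self) -> int:
        return len(self.bubbles)


def _simple_bubbles(graph: DeBruijnGraph):
    """Yield (j1, o1, (b1, ob1), (b2, ob2), j2, oj2) for each simple bubble."""
    seen = set()
    for j1 in sorted(graph.nodes):
        node = graph.nodes[j1]
        if not node.is_junction:
            continue
        for o1 in (0, 1):
            succ = graph.successors(j1, o1)
            if len(succ) != 2:
                continue
            (b1, ob1), (b2, ob2) = sorted(succ)
            if b1 == b2:
                continue
            n1, n2 = graph.nodes[b1], graph.nodes[b2]
            if n1.is_junction or n2.is_junction:
                continue
            ok = True
            ends = []
            for b, ob in ((b1, ob1), (b2, ob2)):
                if len(graph.predecessors(b, ob)) != 1:
                    ok = False
                    break
                nxt = graph.successors(b, ob)
                if len(nxt) != 1:
                    ok = False
                    break
                ends.append(nxt[0])
            if not ok or ends[0] != ends[1]:
                continue
            j2, oj2 = ends[0]
            if not graph.nodes[j2].is_junction or j2 == j1:
                continue
            if len(graph.predecessors(j2, oj2)) != 2:
                continue
            key = frozenset((b1, b2))
            if key in seen:
                continue
            seen.add(key)
            yield j1, o1, (b1, ob1), (b2, ob2), j2, oj2


def detect_anchor_bubbles(graph: DeBruijnGraph,
                          r_upper: float = R_UPPER_THRESHOLD) -> AnchorBubbleSet:
    """Estimate c_hetero from all simple bubbles and keep the anchors.

    c_hetero is the length-weighted mean coverage over the branch nodes of
    every simple bubble; a bubble is an anchor iff both branch coverages are
    <= r_upper * c_hetero.
    """
    wsum = 0.0
    lsum = 0.0
    raw = []
    for j1, o1, (b1, ob1), (b2, ob2), j2, oj2 in _simple_bubbles(graph):
        n1, n2 = graph.nodes[b1], graph.nodes[b2]
        wsum += n1.cov * len(n1) + n2.cov * len(n2)
        lsum += len(n1) + len(n2)
        raw.append(((b1, ob1), (b2, ob2)))
    if lsum == 0:
        log.warning("no simple bubbles found; c_hetero undefined — "
                    "haplotype synteny correction will be disabled")
        return AnchorBubbleSet([], 0.0, r_upper, 0)
    c_het = wsum / lsum
    anchors = []
    for (b1, ob1), (b2, ob2) in raw:
        n1, n2 = graph.nodes[b1], graph.nodes[b2]
        if n1.cov <= r_upper * c_het and n2.cov <= r_upper * c_het:
            anchors.append(AnchorBubble(
                id=len(anchors) + 1,
                branch_a=n1.oriented(ob1), branch_b=n2.oriented(ob2),
                cov_a=n1.cov, cov_b=n2.cov,
            ))
    log.info("anchor bubbles: %d/%d retained, c_hetero=%.2f",
             len(anchors), len(raw), c_het)
    return AnchorBubbleSet(anchors, c_het, r_upper, len(raw))


@dataclass
class CrossStructure:
    """A centre straight node (merged with its two junctions) plus four
    external straight nodes, two per side.  j_left / j_right are None when
    the junction k-mers have already been absorbed into the centre."""

    center: int
    j_left: tuple[int, int] | None  # (junction id, orientation into centre)
    j_right: tuple[int, int] | None
    left: list  # [(node, orient pointing into the cross)], sorted, len 2
    right: list  # [(node, orient pointing out of the cross)], sorted, len 2
    center_len: int = 0
    center_cov: float = 0.0

    @property
    def node_ids(self) -> set[int]:
        ids = {self.center,
               self.left[0][0], self.left[1][0],
               self.right[0][0], self.right[1][0]}
        if self.j_left:
            ids.add(self.j_left[0])
        if self.j_right:
            ids.add(self.j_right[0])
        return ids

    @property
    def parallel(self):
        return ((self.left[0], self.right[0]), (self.left[1], self.right[1]))

    @property
    def cross(self):
        return ((self.left[0], self.right[1]), (self.left[1], self.right[0]))


def _cross_side(graph: DeBruijnGraph, cid: int, into: bool):
    """Resolve one side of a candidate centre node.

    Returns (externals, junction_or_None) where externals are the two
    oriented straight nodes on that side, or None when the shape does not
    match.  Handles both the explicit form (centre — junction — externals)
    and the compressed form in which the junction k-mer has already been
    absorbed into the centre.
    """
    around = graph.predecessors(cid, 0) if into else graph.successors(cid, 0)
    if len(around) == 1:
        j, oj = around[0]
        if not graph.nodes[j].is_junction or j == cid:
            return None
        if into:
            if sorted(graph.successors(j, oj)) != [(cid, 0)]:
                return None
            ext = sorted(graph.predecessors(j, oj))
            attach = (j, oj)
            exclusive = lambda e, oe: graph.successors(e, oe) == [attach]
        else:
            if sorted(graph.predecessors(j, oj)) != [(cid, 0)]:
                return None
            ext = sorted(graph.successors(j, oj))
            attach = (j, oj)
            exclusive = lambda e, oe: graph.predecessors(e, oe) == [attach]
        junction = (j, oj)
    elif len(around) == 2:
        ext = sorted(around)
        junction = None
        if into:
            exclusive = lambda e, oe: graph.successors(e, oe) == [(cid, 0)]
        else:
            exclusive = lambda e, oe: graph.predecessors(e, oe) == [(cid, 0)]
    else:
        return None
    if len(ext) != 2 or ext[0][0] == ext[1][0]:
        return None
    for e, oe in ext:
        if e == cid or graph.nodes[e].is_junction:
            return None
        if not exclusive(e, oe):
            return None
    return ext, junction


def find_cross_structures(graph: DeBruijnGraph, c_hetero: float,
                          r_upper: float = R_UPPER_THRESHOLD) -> list[CrossStructure]:
    """All cross structures passing the coverage conditions:
    centre <= 2 r c_hetero and min(externals) <= r c_hetero."""
    if c_hetero <= 0:
        raise ValueError("c_hetero must be positive")
    out = []
    for cid in sorted(graph.nodes):
        cnode = graph.nodes[cid]
        if cnode.is_junction:
            continue
        lhs = _cross_side(graph, cid, into=True)
        rhs = _cross_side(graph, cid, into=False)
        if lhs is None or rhs is None:
            continue
        left, jl = lhs
        right, jr = rhs
        ids = [n for n, _ in left + right]
        involved = {cid}
        if jl:
            involved.add(jl[0])
        if jr:
            involved.add(jr[0])
        if len(set(ids)) != 4 or involved & set(ids):
            continue
        if jl and jr and jl[0] == jr[0]:
            continue
        if cnode.cov > 2 * r_upper * c_hetero:
            continue
        if min(graph.nodes[n].cov for n in ids) > r_upper * c_hetero:
            continue
        clen = len(cnode) + (1 if jl else 0) + (1 if jr else 0)
        out.append(CrossStructure(
            center=cid, j_left=jl, j_right=jr, left=left, right=right,
            center_len=clen, center_cov=cnode.cov,
        ))
    return out


@dataclass
class Evidence:
    """Evidence bundle for untangling decisions.

    ``links`` counts paired/mate-pair/single-read links; ``long_links``
    carries summed match-sites as weights; ``barcodes`` is the linked-read
    table."""

    links: LinkStore | None = None
    long_links: LinkStore | None = None
    barcodes: BarcodeTable | None = None


@dataclass
class Resolution:
    decision: str  # parallel | cross | unresolved
    winning_score: float = 0.0
    alt_score: float = 0.0
    method: str = ""
    method_calls: dict = field(default_factory=dict)


def decide(score_a: float, score_b: float, ratio: float = EVIDENCE_RATIO) -> str:
    """One solution wins iff its score >= max(1, ratio * alternative)."""
    if score_a >= max(1.0, ratio * score_b):
        return "a"
    if score_b >= max(1.0, ratio * score_a):
        return "b"
    return "unresolved"


def _pair_score(cs: CrossStructure, fn) -> tuple[float, float]:
    def side(pairs):
        return sum(fn(a[0], b[0]) for a, b in pairs)

    return side(cs.parallel), side(cs.cross)


def resolve_cross(cs: CrossStructure, evidence: Evidence,
                  ratio: float = EVIDENCE_RATIO,
                  barcode_center_max: int = BARCODE_CENTER_MAX_LEN) -> Resolution:
    """Apply the three evidence methods and merge their verdicts.

    Methods agreeing (or a single decisive method) resolve the cross;
    conflicting verdicts leave it unresolved.  The barcode method is skipped
    when the centre node is >= 200 kbp (linked-read fragments cannot span it).
    """
    calls: dict[str, tuple[str, float, float]] = {}
    if evidence.links is not None:
        p, c = _pair_score(cs, evidence.links.count_between)
        calls["links"] = (decide(p, c, ratio), p, c)
    if evidence.long_links is not None:
        p, c = _pair_score(cs, evidence.long_links.weight_between)
        calls["match-sites"] = (decide(p, c, ratio), p, c)
    if evidence.barcodes is not None:
        if cs.center_len >= barcode_center_max:
            calls["barcodes"] = ("unresolved", 0.0, 0.0)
        else:
            p, c = _pair_score(cs, evidence.barcodes.common_barcode_reads)
            calls["barcodes"] = (decide(p, c, ratio), p, c)
    verdicts = {d for d, _, _ in calls.values() if d != "unresolved"}
    if len(verdicts) != 1:
        if len(verdicts) > 1:
            log.info("cross %d: conflicting evidence %s — left unresolved",
                     cs.center, calls)
        return Resolution("unresolved", 0.0, 0.0, "", calls)
    verdict = verdicts.pop()
    method, (d, p, c) = next((m, v) for m, v in calls.items() if v[0] == verdict)
    win, alt = (p, c) if verdict == "a" else (c, p)
    return Resolution("parallel" if verdict == "a" else "cross", win, alt,
                      method, calls)


def apply_untangle(graph: DeBruijnGraph, cs: CrossStructure, res: Resolution) -> None:
    """Duplicate the centre (with its junctions) into the two decided paths.

    Each copy inherits half the original centre coverage."""
    cnode = graph.nodes[cs.center]
    head = tail = ""
    if cs.j_left:
        jl, ojl = cs.j_left
        head = graph.nodes[jl].oriented(ojl)[0]
    if cs.j_right:
        jr, ojr = cs.j_right
        tail = graph.nodes[jr].oriented(ojr)[-1]
    center_seq = head + cnode.seq + tail
    pairs = cs.parallel if res.decision == "parallel" else cs.cross
    for (eid, eo), (fid, fo) in pairs:
        x = graph.add_node(center_seq, cnode.cov / 2, is_junction=False)
        graph.add_edge(eid, eo, x, 0)
        graph.add_edge(x, 0, fid, fo)
    graph.remove_node(cs.center)
    if cs.j_left:
        graph.remove_node(cs.j_left[0])
    if cs.j_right:
        graph.remove_node(cs.j_right[0])


def untangle_graph(graph: DeBruijnGraph, evidence_provider, c_hetero: float,
                   r_upper: float = R_UPPER_THRESHOLD,
                   ratio: float = EVIDENCE_RATIO,
                   max_iters: int = UNTANGLE_MAX_ITERS,
                   decision_log: list | None = None) -> int:
    """Iteratively untangle resolvable cross structures (in place).

    ``evidence_provider(graph)`` returns an :class:`Evidence` bundle for the
    current node set (typically by re-mapping the reads).  Iteration stops
    after ``max_iters`` rounds or when a round unt angles nothing.

    Returns the total number of untangled crosses.
    """
    if c_hetero <= 0:
        return 0
    total = 0
    for it in range(max_iters):
        evidence = evidence_provider(graph)
        crosses = find_cross_structures(graph, c_hetero, r_upper)
        used: set[int] = set()
        n_round = 0
        for cs in crosses:
            if cs.node_ids & used:
                continue
            if any(n not in graph.nodes for n in cs.node_ids):
                continue
            res = resolve_cross(cs, evidence, ratio)
            if decision_log is not None:
                decision_log.append((it + 1, cs.center, res.method,
                                     res.winning_score, res.alt_score,
                                     res.decision))
            if res.decision == "unresolved":
                continue
            apply_untangle(graph, cs, res)
            used |= cs.node_ids
            n_round += 1
        graph.compress()
        total += n_round
        log.info("untangle round %d: %d crosses found, %d untangled",
                 it + 1, len(crosses), n_round)
        if n_round == 0:
            break
    return total
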