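"""Gap closing by local assembly and consensus-scaffold construction.

Gap closing maps reads back onto the phased blocks (unique seed hits only,
so reads from sequence present in both haplotype blocks are never used and
phase information survives), assigns each read pair whose unique placement
falls near a gap to that gap, and replaces the N run iff a local de Bruijn
walk over the assigned reads connects the two flank anchors through a
single unbranched path.

Consensus scaffolds concatenate primary bubbles and non-bubble sequences
through exact (k-1)-base end overlaps; a pair is connected only when the
overlap is unique on both sides.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from ._kmer import revcomp
from .mapping import NodeIndex, ReadSeeds, map_reads

log = logging.getLogger("diphase")


@dataclass
class GapReport:
    node: int
    start: int
    length: int
    closed: bool
    inserted: int
    n_reads: int


def _n_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def _local_walk(pool: list[str], left: str, right: str, k: int,
                limit: int) -> str | None:
    """Walk unique successors from ``left`` to ``right`` over pool k-mers.

    Returns the sequence between the anchors (exclusive) or None when the
    walk dead-ends, branches, or exceeds ``limit`` extension steps.
    """
    present: set[str] = set()
    for r in pool:
        for i in range(len(r) - k + 1):
            w = r[i : i + k]
            if "N" in w:
                continue
            present.add(w)
            present.add(revcomp(w))
    if left not in present or right not in present:
        return None
    cur = left
    out: list[str] = []
    for _ in range(limit):
        succ = [cur[1:] + b for b in "ACGT" if cur[1:] + b in present]
        if len(succ) != 1:
            return None
        cur = succ[0]
        if cur == right:
            # the walk's tail overlaps the right anchor by k-1 bases
            joined = "".join(out)
            return joined[: max(len(joined) - (k - 1), 0)]
        out.append(cur[-1])
    return None


def close_gaps(nodes: list[tuple[int, str, float]],
               libs: list[dict],
               k_local: int,
               report: list[GapReport] | None = None
               ) -> tuple[list[tuple[int, str, float]], int]:
    """Close N gaps in ``nodes`` by local assembly of uniquely mapped reads.

    ``libs`` entries carry {"seeds": ReadSeeds over r1+r2, "reads": list,
    "insert": mean insert}.  A pair is assigned to a gap when either mate's
    unique placement lies within one insert size of the gap on that node.
    The walk is bounded at 10x the gap estimate (plus anchor slack).
    """
    if not any(("N" in seq) for _, seq, _ in nodes):
        return nodes, 0
    index = NodeIndex(sorted((nid, seq) for nid, seq, _ in nodes))
    # gap pools
    pools: dict[tuple[int, int], list[str]] = defaultdict(list)
    gaps_by_node: dict[int, list[tuple[int, int]]] = {}
    for nid, seq, _ in nodes:
        runs = _n_runs(seq)
        if runs:
            gaps_by_node[nid] = runs
    for lib in libs:
        seeds: ReadSeeds = lib["seeds"]
        reads: list[str] = lib["reads"]
        insert = int(lib.get("insert", 500))
        pl = map_reads(index, seeds)
        n = len(reads) // 2
        for i in range(n):
            for j in (i, i + n):
                if pl.node[j] < 0:
                    continue
                nid = int(pl.node[j])
                runs = gaps_by_node.get(nid)
                if not runs:
                    continue
                p = int(pl.pos[j])
                for g in runs:
                    if g[0] - insert <= p <= g[1] + insert:
                        pools[(nid, g[0])].append(reads[i])
                        pools[(nid, g[0])].append(reads[i + n])
    out = []
    n_closed = 0
    for nid, seq, cov in sorted(nodes):
        runs = gaps_by_node.get(nid)
        if not runs:
            out.append((nid, seq, cov))
            continue
        for start, end in reversed(runs):
            pool = pools.get((nid, start), [])
            glen = end - start
            closed = False
            inserted = 0
            if pool and start >= k_local and end + k_local <= len(seq):
                left = seq[start - k_local : start]
                right = seq[end : end + k_local]
                if "N" not in left and "N" not in right:
                    limit = 10 * glen + 2 * k_local + 200
                    mid = _local_walk(pool, left, right, k_local, limit)
                    if mid is not None:
                        seq = seq[:start] + mid + seq[end:]
                        closed = True
                        inserted = len(mid)
                        n_closed += 1
            if report is not None:
                report.append(GapReport(nid, start, glen, closed, inserted,
                                        len(pool) // 2))
        out.append((nid, seq, cov))
    log.info("gap closing: %d gaps closed", n_closed)
    return out, n_closed


def write_gap_report(path: str, report: list[GapReport]) -> None:
    with open(path, "w") as fh:
        fh.write("node\tgap_start\tgap_len\tclosed\tinserted\tn_read_pairs\n")
        for r in report:
            fh.write(f"{r.node}\t{r.start}\t{r.length}\t{int(r.closed)}\t"
                     f"{r.inserted}\t{r.n_reads}\n")


# ---------------------------------------------------------------------------
# consensus scaffolds
# ---------------------------------------------------------------------------


def overlap_join(seqs: list[str], k: int) -> list[str]:
    """Join sequences by exact, mutually unique (k-1)-base end overlaps.

    A suffix may connect to a prefix only when that suffix matches exactly
    one prefix in the set and that prefix is matched by exactly one suffix
    ("without overlapping other sequences").
    """
    ov = k - 1
    items = [(i, s) for i, s in enumerate(seqs) if len(s) >= ov]
    pref: dict[str, list[tuple[int, int]]] = defaultdict(list)
    suff: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for i, s in items:
        pref[s[:ov]].append((i, 0))
        pref[revcomp(s)[:ov]].append((i, 1))
        suff[s[-ov:]].append((i, 0))
        suff[revcomp(s)[-ov:]].append((i, 1))
    partner: dict[tuple[int, int, int], tuple[int, int]] = {}
    for i, s in items:
        for o in (0, 1):
            os_ = s if o == 0 else revcomp(s)
            tail = os_[-ov:]
            cands = pref.get(tail, [])
            # the suffix must match exactly one prefix (not our own) and
            # that prefix must be reached by exactly one suffix
            if len(cands) != 1 or cands[0][0] == i:
                continue
            if len(suff.get(tail, [])) != 1:
                continue
            partner[(i, o, 1)] = cands[0]
    used: set[int] = set()
    out: list[str] = []
    for i, s in items:
        if i in used:
            continue
        # walk left
        cur, orient = i, 0
        seen = {i}
        while True:
            # incoming: who connects into (cur, orient) start?  that is the
            # partner of (cur, 1-orient) forward direction reversed
            key = (cur, 1 - orient, 1)
            prev = partner.get(key)
            if prev is None:
                break
            pn, po = prev
            if pn in seen:
                break
            seen.add(pn)
            cur, orient = pn, 1 - po
        chain = [(cur, orient)]
        seen = {cur}
        while True:
            tail_n, tail_o = chain[-1]
            nxt = partner.get((tail_n, tail_o, 1))
            if nxt is None:
                break
            nn, no = nxt
            if nn in seen:
                break
            seen.add(nn)
            chain.append((nn, no))
        used.update(n for n, _ in chain)
        seq = seqs[chain[0][0]] if chain[0][1] == 0 else revcomp(seqs[chain[0][0]])
        for nn, no in chain[1:]:
            nxt_seq = seqs[nn] if no == 0 else revcomp(seqs[nn])
            seq = seq + nxt_seq[ov:]
        out.append(seq)
    out.extend(s for i, s in enumerate(seqs) if len(s) < ov and i not in used)
    return out


def build_consensus(primary: list[str], nonbubble: list[str], k: int) -> list[str]:
    """Consensus scaffolds from primary bubbles plus non-bubble sequences.

    Secondary bubbles are deliberately excluded.  The result of the overlap
    joining is returned; callers may feed it through the scaffolding
    procedure for additional link-based joins.
    """
    return overlap_join(list(primary) + list(nonbubble), k)
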