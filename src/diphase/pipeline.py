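"""End-to-end haplotype-aware assembly workflow.

contig assembly -> [untangle the (gapped) de Bruijn graph -> scaffold ->
untangle the scaffold graph -> haplotype synteny correction -> gap closing]
x outer iterations -> bubble pairing -> optional consensus.

Libraries are used individually in ascending order of insert sizes and then
all together in every untangling phase; each phase re-maps the reads to the
current node set.  All stage counters are collected in
``PipelineResult.counters`` — these are the primary observables for tests.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import dbg, finishing, scaffold as sc, untangle as ut
from .mapping import (
    LinkStore,
    LongReadAlignment,
    NodeIndex,
    ReadSeeds,
    count_barcodes,
    filter_long_alignments,
    long_read_links,
    map_reads,
    pair_links,
    single_read_links,
)
from .simulate import SimulatedLibrary

log = logging.getLogger("diphase")


@dataclass
class PipelineConfig:
    k_initial: int = 32
    k_step: int = 20
    k_max: int | None = None  # default: half the paired-end read length
    r_upper_threshold: float = 1.75
    evidence_ratio: float = 4.0
    barcode_min_reads: int = 4
    untangle_max_iters: int = 5
    outer_iterations: int = 2
    min_link_threshold: int = 2
    min_node_len: int | None = None  # default: largest library insert mean
    gap_slack: int = 500
    build_consensus: bool = True
    genome_size: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.outer_iterations < 1:
            raise ValueError("outer iterations must be >= 1")
        for v in (self.r_upper_threshold, self.evidence_ratio,
                  self.barcode_min_reads, self.untangle_max_iters,
                  self.min_link_threshold):
            if v <= 0:
                raise ValueError("thresholds must be positive")


@dataclass
class ReadLibrary:
    """Runtime view of one sequencing library."""

    kind: str  # paired-end | mate-pair | linked | long
    reads1: list[str]
    reads2: list[str] | None
    insert_mean: float
    name: str = ""
    barcodes: list[str | None] | None = None

    _seeds: ReadSeeds | None = None

    @classmethod
    def from_simulated(cls, sim: SimulatedLibrary) -> "ReadLibrary":
        return cls(kind=sim.spec.kind, reads1=sim.reads1, reads2=sim.reads2,
                   insert_mean=sim.spec.insert_mean,
                   name=sim.spec.name or sim.spec.kind,
                   barcodes=sim.barcodes)

    @property
    def all_reads(self) -> list[str]:
        return self.reads1 + (self.reads2 or [])

    @property
    def n_pairs(self) -> int:
        return len(self.reads1) if self.reads2 is not None else 0

    def seeds(self) -> ReadSeeds:
        if self._seeds is None:
            self._seeds = ReadSeeds(self.all_reads)
        return self._seeds

    @property
    def outward(self) -> bool:
        return self.kind == "mate-pair"


@dataclass
class PipelineResult:
    blocks: sc.PhasedBlockSet
    consensus: list[str]
    nodes: list[tuple[int, str, float]]
    counters: dict
    decision_log: list
    anchors: ut.AnchorBubbleSet
    gap_reports: list = None


def _long_read_evidence(index: NodeIndex, lib: ReadLibrary,
                        store: LinkStore) -> None:
    """Align a long-read library to the node set and add spanning links.

    Alignments come from minimap2; the identity/length filter and the
    greedy match-site selection are applied before links are drawn.
    """
    from .paf import align_to, minimap2_available

    if not minimap2_available():
        log.warning("minimap2 not on PATH; long-read library %s ignored",
                    lib.name)
        return
    target = [(str(nid), index.seqs[nid]) for nid in sorted(index.seqs)]
    query = [(f"lr{i}", r) for i, r in enumerate(lib.reads1)]
    records = align_to(target, query, options=["-c", "-k15"])
    alns = [LongReadAlignment(
        query=r.qname, target=int(r.tname), qlen=r.qlen, tlen=r.tlen,
        qstart=r.qstart, qend=r.qend, tstart=r.tstart, tend=r.tend,
        strand=0 if r.strand == "+" else 1, matches=r.matches,
        aln_len=r.aln_len) for r in records]
    selected = filter_long_alignments(alns, k=32)
    long_read_links(selected, store=store)


def _evidence_for(index: NodeIndex, libs: list[ReadLibrary],
                  barcode_min: int) -> ut.Evidence:
    """Map every library to the indexed node set and bundle the evidence."""
    store = LinkStore()
    long_store = None
    barcode_tables = []
    for lib in libs:
        if lib.kind == "long":
            long_store = long_store if long_store is not None else LinkStore()
            _long_read_evidence(index, lib, long_store)
            continue
        pl = map_reads(index, lib.seeds())
        if lib.reads2 is not None:
            n = lib.n_pairs
            pair_links(index, pl.slice(0, n), pl.slice(n, 2 * n),
                       lib.insert_mean, lib.kind, outward=lib.outward,
                       store=store)
        single_read_links(index, pl, store=store)
        if lib.kind == "linked" and lib.barcodes is not None:
            bcs = list(lib.barcodes) + list(lib.barcodes)
            barcode_tables.append(count_barcodes(pl, bcs, barcode_min))
    barcodes = None
    if barcode_tables:
        merged = barcode_tables[0]
        for t in barcode_tables[1:]:
            merged.counts.update(t.counts)
        barcodes = merged
    return ut.Evidence(links=store, long_links=long_store, barcodes=barcodes)


def estimate_insert_sizes(libs: list[ReadLibrary],
                          nodes: list[tuple[int, str, float]]) -> None:
    """Refine declared insert means from pairs co-placed on one node."""
    index = NodeIndex(sorted((nid, seq) for nid, seq, _ in nodes))
    for lib in libs:
        if lib.reads2 is None:
            continue
        pl = map_reads(index, lib.seeds())
        n = lib.n_pairs
        _, inserts = pair_links(index, pl.slice(0, n), pl.slice(n, 2 * n),
                                lib.insert_mean, lib.kind, outward=lib.outward)
        if len(inserts) >= 20:
            est = float(np.median(inserts))
            log.info("library %s: insert estimated %.0f (declared %.0f) "
                     "from %d pairs", lib.name, est, lib.insert_mean,
                     len(inserts))
            lib.insert_mean = est


def _sorted_libs(libs: list[ReadLibrary]) -> list[ReadLibrary]:
    return sorted(libs, key=lambda l: (l.insert_mean, l.name))


def gapped_graph_from_nodes(nodes: list[tuple[int, str, float]],
                            k: int) -> tuple[dbg.DeBruijnGraph, dict[int, int]]:
    """Rebuild a (gapped) de Bruijn graph view over scaffold sequences.

    Nodes become straight nodes; edges are exact (k-1)-base end overlaps.
    """
    g = dbg.DeBruijnGraph(k)
    ids = {}
    for nid, seq, cov in sorted(nodes):
        ids[nid] = g.add_node(seq, cov)
    ov = k - 1
    pref: dict[str, list[tuple[int, int]]] = defaultdict(list)
    from ._kmer import revcomp

    for nid, seq, _ in sorted(nodes):
        if len(seq) < ov or "N" in seq[:ov] or "N" in seq[-ov:]:
            continue
        pref[seq[:ov]].append((ids[nid], 0))
        pref[revcomp(seq)[:ov]].append((ids[nid], 1))
    for nid, seq, _ in sorted(nodes):
        if len(seq) < ov:
            continue
        for o, oseq in ((0, seq), (1, revcomp(seq))):
            tail = oseq[-ov:]
            if "N" in tail:
                continue
            for v, ov2 in pref.get(tail, []):
                if v == ids[nid] and ov2 == o:
                    continue
                g.add_edge(ids[nid], o, v, ov2)
    return g, {v: k_ for k_, v in ids.items()}


def run_pipeline(libraries: list[ReadLibrary | SimulatedLibrary],
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full phasing workflow on in-memory libraries."""
    config = config or PipelineConfig()
    config.validate()
    libs = [ReadLibrary.from_simulated(l) if isinstance(l, SimulatedLibrary)
            else l for l in libraries]
    pe_libs = [l for l in libs if l.kind == "paired-end"]
    if not pe_libs:
        raise ValueError("the workflow requires at least one paired-end library")
    if any(not l.reads1 for l in libs):
        raise ValueError("empty read set in input libraries")
    short_libs = [l for l in libs if l.kind in ("paired-end", "mate-pair", "linked")]
    counters: dict = defaultdict(int)
    decision_log: list = []
    gap_reports: list = []

    # ---- contig assembly (paired-end reads only) -------------------------
    contig_reads = [r for l in pe_libs for r in l.all_reads]
    pe_rl = max(len(r) for r in contig_reads)
    initial, graph = dbg.assemble_contigs(
        contig_reads, config.k_initial, config.k_step, config.k_max)
    dbg.normalize_coverage(initial, pe_rl)
    dbg.normalize_coverage(graph, pe_rl)
    counters["initial_straight_nodes"] = len(initial.straight_nodes())
    counters["final_k"] = graph.k

    # ---- anchors ---------------------------------------------------------
    anchors = ut.detect_anchor_bubbles(initial, config.r_upper_threshold)
    counters["simple_bubbles"] = anchors.n_simple_bubbles
    counters["anchor_bubbles"] = len(anchors)
    c_het = anchors.c_hetero
    if c_het <= 0:
        log.warning("no heterozygous bubbles: running in near-homozygous mode")

    min_node_len = (config.min_node_len if config.min_node_len is not None
                    else int(max(l.insert_mean for l in short_libs)))

    index_cache: dict = {}

    def dbg_evidence_provider(active: list[ReadLibrary]):
        def provider(gg: dbg.DeBruijnGraph) -> ut.Evidence:
            if index_cache.get("version") != (id(gg), gg.version):
                index_cache["index"] = NodeIndex(
                    [(nd.id, nd.seq) for nd in
                     sorted(gg.straight_nodes(), key=lambda x: x.id)])
                index_cache["version"] = (id(gg), gg.version)
            return _evidence_for(index_cache["index"], active,
                                 config.barcode_min_reads)
        return provider

    nodes: list[tuple[int, str, float]] = []
    for outer in range(1, config.outer_iterations + 1):
        log.info("=== outer iteration %d ===", outer)
        # -- untangle the (gapped) de Bruijn graph -------------------------
        if outer == 1:
            work_graph = graph
            id_map = None
        else:
            work_graph, id_map = gapped_graph_from_nodes(nodes, graph.k)
        if c_het > 0:
            for group in [[l] for l in _sorted_libs(libs)] + [libs]:
                tag = "+".join(l.name or l.kind for l in group)
                log.info("dbg untangle with library group: %s", tag)
                n = ut.untangle_graph(
                    work_graph, dbg_evidence_provider(group),
                    c_het, config.r_upper_threshold, config.evidence_ratio,
                    config.untangle_max_iters, decision_log)
                counters[f"untangled_dbg_iter{outer}"] += n
        else:
            work_graph.compress()
        nodes = [(nd.id, nd.seq, nd.cov) for nd in
                 sorted(work_graph.straight_nodes(), key=lambda x: x.id)]
        if outer == 1:
            estimate_insert_sizes(libs, nodes)

        # -- scaffolding and scaffold untangling ---------------------------
        anchored = _anchored_ids(nodes, anchors)
        for round_i in range(config.untangle_max_iters):
            index = NodeIndex(sorted((nid, seq) for nid, seq, _ in nodes))
            changed = 0
            for group in [[l] for l in _sorted_libs(libs)] + [libs]:
                ev = _evidence_for(index, group, config.barcode_min_reads)
                g = sc.build_scaffold_graph(
                    nodes, ev.links, config.min_link_threshold,
                    min_node_len, anchored, config.gap_slack)
                n_unt = sc.untangle_scaffold_graph(
                    g, ev, c_het, config.r_upper_threshold,
                    config.evidence_ratio, decision_log)
                if n_unt:
                    counters[f"untangled_scaffold_iter{outer}"] += n_unt
                    changed += n_unt
                    nodes = sorted((nid, nd.seq, nd.cov)
                                   for nid, nd in g.nodes.items())
                    index = NodeIndex(sorted((nid, seq)
                                             for nid, seq, _ in nodes))
            ev = _evidence_for(index, libs, config.barcode_min_reads)
            g = sc.build_scaffold_graph(
                nodes, ev.links, config.min_link_threshold,
                min_node_len, anchored, config.gap_slack)
            new_nodes, joins = sc.join_scaffolds(g)
            counters[f"scaffold_joins_iter{outer}"] += joins
            nodes = new_nodes
            anchored = _anchored_ids(nodes, anchors)
            if changed == 0 and joins == 0:
                break

        # -- haplotype synteny-based correction ----------------------------
        if anchors.bubbles:
            nodes, divisions = sc.synteny_correct(nodes, anchors,
                                                  division_log=decision_log)
            counters[f"synteny_divisions_iter{outer}"] += divisions

        # -- gap closing ---------------------------------------------------
        gap_libs = [{"seeds": l.seeds(), "reads": l.all_reads,
                     "insert": l.insert_mean}
                    for l in short_libs if l.reads2 is not None]
        nodes, n_closed = finishing.close_gaps(nodes, gap_libs,
                                               k_local=max(graph.k // 2, 21),
                                               report=gap_reports)
        counters[f"gaps_closed_iter{outer}"] += n_closed

    # ---- bubble pairing --------------------------------------------------
    blocks = sc.pair_bubbles(nodes, anchors)
    counters["bubble_pairs"] = len(blocks.bubbles)
    counters["nonbubble_sequences"] = len(blocks.nonbubbles)

    consensus: list[str] = []
    if config.build_consensus:
        consensus = finishing.build_consensus(
            [b.primary for b in blocks.bubbles],
            [s for _, s in blocks.nonbubbles], graph.k)
        counters["consensus_sequences"] = len(consensus)

    return PipelineResult(blocks=blocks, consensus=consensus, nodes=nodes,
                          counters=dict(counters), decision_log=decision_log,
                          anchors=anchors, gap_reports=gap_reports)


def _anchored_ids(nodes: list[tuple[int, str, float]],
                  anchors: ut.AnchorBubbleSet) -> set[int]:
    if not anchors.bubbles:
        return set()
    index = NodeIndex(sorted((nid, seq) for nid, seq, _ in nodes),
                      seed_lengths=(32,))
    hits = sc.locate_anchors(index, anchors)
    out: set[int] = set()
    for h in hits:
        out.add(h.node_a)
        out.add(h.node_b)
    return out
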