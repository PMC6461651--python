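"""Synthetic diploid genomes and sequencing libraries with truth tracking.

The generator emulates realistic benchmark conditions at desk scale: a
diploid genome derived from one random haplotype by background heterozygosity
(SNVs at 0.1-5%, optional small indels), embedded highly divergent regions
(HDRs, divergence > 5%, optionally inverted), and short-read libraries in
the four supported flavours (inward paired-end, outward mate-pair, barcoded
linked reads, error-prone long reads).  Every variant and read placement is
recorded so that phasing output can be scored against the truth.

All randomness flows through one ``numpy`` generator per call; the same seed
reproduces byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmer import revcomp

log = logging.getLogger("diphase")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class HDRSpec:
    """A highly divergent region: interval on haplotype A with its own
    divergence rate and an optional inversion of the counterpart."""

    start: int
    length: int
    divergence: float = 0.05
    inversion: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class RepeatSpec:
    copies: int
    length: int
    identity: float = 1.0


@dataclass
class DiploidGenomeSpec:
    length: int
    snv_rate: float = 0.01
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0  # geometric
    hdrs: list[HDRSpec] = field(default_factory=list)
    repeats: RepeatSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        for r in (self.snv_rate, self.indel_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("variant rates must lie in [0, 0.2]")
        last_end = 0
        for h in sorted(self.hdrs, key=lambda h: h.start):
            if h.start < last_end:
                raise ValueError("HDR intervals must be disjoint")
            if h.start < 0 or h.end > self.length:
                raise ValueError("HDR interval out of bounds")
            if not 0.0 <= h.divergence <= 0.2:
                raise ValueError("HDR divergence must lie in [0, 0.2]")
            last_end = h.end


@dataclass
class Variant:
    pos: int  # position on haplotype A (0-based)
    kind: str  # snv | ins | del | inversion
    ref: str
    alt: str


@dataclass
class DiploidTruth:
    hap_a: str
    hap_b: str
    variants: list[Variant]
    hdrs: list[HDRSpec]

    def variant_table(self) -> list[tuple[int, str, str, str]]:
        return [(v.pos, v.kind, v.ref, v.alt) for v in self.variants]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def simulate_diploid(spec: DiploidGenomeSpec) -> DiploidTruth:
    """Generate haplotype A, derive haplotype B, and record every variant.

    Haplotype B is produced by Bernoulli per-base SNVs at the background rate
    (elevated to the HDR divergence inside HDR intervals), geometric small
    indels at the indel rate, and an optional inversion of each HDR.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hap_a = _random_sequence(rng, spec.length)
    if spec.repeats is not None and spec.repeats.copies > 1:
        rep = spec.repeats
        unit = _random_sequence(rng, rep.length)
        positions = rng.choice(
            max(spec.length - rep.length, 1), size=rep.copies, replace=False
        )
        buf = bytearray(hap_a.encode())
        for p in sorted(int(x) for x in positions):
            copy = list(unit)
            if rep.identity < 1.0:
                nmut = rng.binomial(rep.length, 1.0 - rep.identity)
                for q in rng.choice(rep.length, size=nmut, replace=False):
                    copy[q] = _other_base(rng, copy[q])
            buf[p : p + rep.length] = "".join(copy).encode()
        hap_a = buf.decode()

    rate = np.full(spec.length, spec.snv_rate)
    for h in spec.hdrs:
        rate[h.start : h.end] = h.divergence
    snv_mask = rng.random(spec.length) < rate
    indel_mask = (
        rng.random(spec.length) < spec.indel_rate
        if spec.indel_rate > 0
        else np.zeros(spec.length, dtype=bool)
    )

    variants: list[Variant] = []
    out: list[str] = []
    hdr_at = {h.start: h for h in spec.hdrs}
    hdr_b_span: dict[int, list[int]] = {}
    i = 0
    b_len = 0
    active_hdr: HDRSpec | None = None
    geom_p = 1.0 / max(spec.indel_mean_len, 1.0)
    while i < len(hap_a):
        h = hdr_at.get(i)
        if h is not None:
            active_hdr = h
            hdr_b_span[h.start] = [b_len, b_len]
        if active_hdr is not None and i >= active_hdr.end:
            hdr_b_span[active_hdr.start][1] = b_len
            active_hdr = None
        if indel_mask[i]:
            size = int(rng.geometric(geom_p))
            if rng.random() < 0.5:  # insertion before A[i]
                ins = _random_sequence(rng, size)
                out.append(ins)
                b_len += size
                variants.append(Variant(i, "ins", "", ins))
            else:  # deletion of A[i:i+size], clipped at HDR/sequence end
                stop = active_hdr.end if active_hdr is not None else len(hap_a)
                size = min(size, stop - i)
                variants.append(Variant(i, "del", hap_a[i : i + size], ""))
                i += size
                continue
        base = hap_a[i]
        if snv_mask[i]:
            alt = _other_base(rng, base)
            variants.append(Variant(i, "snv", base, alt))
            out.append(alt)
        else:
            out.append(base)
        b_len += len(out[-1])
        i += 1
    if active_hdr is not None:
        hdr_b_span[active_hdr.start][1] = b_len

    hap_b = "".join(out)
    for h in spec.hdrs:
        if h.inversion:
            lo, hi = hdr_b_span[h.start]
            hap_b = hap_b[:lo] + revcomp(hap_b[lo:hi]) + hap_b[hi:]
            variants.append(Variant(h.start, "inversion", f"{h.start}-{h.end}", ""))
    variants.sort(key=lambda v: (v.pos, v.kind))
    return DiploidTruth(hap_a, hap_b, variants, list(spec.hdrs))


def reconstruct_hap_b(hap_a: str, variants: list[Variant]) -> str:
    """Rebuild haplotype B from haplotype A and the truth table (round-trip)."""
    edits = {(v.pos, v.kind): v for v in variants if v.kind != "inversion"}
    out: list[str] = []
    spans: dict[int, list[int]] = {}
    inversions = [v for v in variants if v.kind == "inversion"]
    starts = {}
    for v in inversions:
        a_lo, a_hi = (int(x) for x in v.ref.split("-"))
        starts[a_lo] = a_hi
    b_len = 0
    i = 0
    open_inv: tuple[int, int] | None = None
    while i < len(hap_a):
        if i in starts:
            open_inv = (i, b_len)
            spans[i] = [b_len, b_len]
        if open_inv is not None and i >= starts[open_inv[0]]:
            spans[open_inv[0]][1] = b_len
            open_inv = None
        v = edits.get((i, "ins"))
        if v is not None:
            out.append(v.alt)
            b_len += len(v.alt)
        v = edits.get((i, "del"))
        if v is not None:
            i += len(v.ref)
            continue
        v = edits.get((i, "snv"))
        out.append(v.alt if v is not None else hap_a[i])
        b_len += 1
        i += 1
    if open_inv is not None:
        spans[open_inv[0]][1] = b_len
    hap_b = "".join(out)
    for a_lo in sorted(starts, reverse=True):
        lo, hi = spans[a_lo]
        hap_b = hap_b[:lo] + revcomp(hap_b[lo:hi]) + hap_b[hi:]
    return hap_b


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class LibrarySpec:
    kind: str  # paired-end | mate-pair | linked | long
    coverage: float
    read_length: int = 100  # for "long": mean read length
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    error_rate: float = 0.0
    fragment_length: int = 50_000  # linked only
    reads_per_fragment: int = 20  # linked pairs per fragment
    name: str = ""

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.kind in ("paired-end", "mate-pair") and self.insert_mean < self.read_length:
            raise ValueError("insert mean below read length")
        if self.kind not in ("paired-end", "mate-pair", "linked", "long"):
            raise ValueError(f"unknown library kind {self.kind!r}")


@dataclass
class ReadPlacement:
    read: str
    hap: int
    pos: int
    strand: int


@dataclass
class SimulatedLibrary:
    spec: LibrarySpec
    reads1: list[str]
    reads2: list[str] | None  # None for long reads
    names: list[str]
    barcodes: list[str | None] | None
    placements: list[ReadPlacement]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float,
                  indels: bool = False) -> str:
    if rate <= 0:
        return seq
    out = []
    errs = rng.random(len(seq))
    kinds = rng.integers(0, 3, size=len(seq))
    for i, ch in enumerate(seq):
        if errs[i] >= rate:
            out.append(ch)
            continue
        kind = kinds[i] if indels else 0
        if kind == 0:  # substitution
            out.append(_other_base(rng, ch))
        elif kind == 1:  # insertion
            out.append(ch)
            out.append("ACGT"[int(rng.integers(0, 4))])
        # kind == 2: deletion — emit nothing
    return "".join(out)


def simulate_reads(haplotypes: tuple[str, str], lib: LibrarySpec,
                   seed: int = 0) -> SimulatedLibrary:
    """Simulate one library; fragments alternate between the haplotypes.

    Paired-end reads face inward, mate-pairs outward; linked reads are
    paired-end reads grouped under a shared barcode per long source fragment
    (tagged BX:Z: in FASTQ output); long reads carry i.i.d. substitution,
    insertion and deletion errors in equal parts.
    """
    lib.validate()
    if not haplotypes or not all(haplotypes):
        raise ValueError("haplotypes must be non-empty")
    rng = np.random.default_rng(seed)
    glen = len(haplotypes[0])
    rl = lib.read_length
    name = lib.name or lib.kind
    reads1: list[str] = []
    reads2: list[str] = []
    names: list[str] = []
    barcodes: list[str | None] = []
    placements: list[ReadPlacement] = []

    def draw_pair(hap_i: int, lo: int, hi: int, rid: str, barcode=None):
        hap = haplotypes[hap_i]
        hi = min(hi, len(hap))
        insert = int(round(rng.normal(lib.insert_mean, lib.insert_sd)))
        insert = max(rl, min(insert, hi - lo))
        start = int(rng.integers(lo, max(hi - insert, lo) + 1))
        frag = hap[start : start + insert]
        r1, r2 = frag[:rl], revcomp(frag[-rl:])
        strand = int(rng.integers(0, 2))
        if strand:
            r1, r2 = r2, r1
        if lib.kind == "mate-pair":
            r1, r2 = revcomp(r1), revcomp(r2)
        if lib.error_rate > 0:
            r1 = _apply_errors(rng, r1, lib.error_rate)
            r2 = _apply_errors(rng, r2, lib.error_rate)
        reads1.append(r1)
        reads2.append(r2)
        names.append(rid)
        barcodes.append(barcode)
        placements.append(ReadPlacement(rid, hap_i, start, strand))

    if lib.kind in ("paired-end", "mate-pair"):
        n_pairs = int(np.ceil(lib.coverage * glen / (2 * rl)))
        for i in range(n_pairs):
            draw_pair(i % 2, 0, glen, f"{name}_{i}")
        return SimulatedLibrary(lib, reads1, reads2, names, None, placements)

    if lib.kind == "linked":
        n_pairs = int(np.ceil(lib.coverage * glen / (2 * rl)))
        n_frags = int(np.ceil(n_pairs / lib.reads_per_fragment))
        for f in range(n_frags):
            hap_i = f % 2
            hap = haplotypes[hap_i]
            flen = min(lib.fragment_length, len(hap))
            fstart = int(rng.integers(0, len(hap) - flen + 1))
            bc = f"BC{f:06d}"
            for j in range(lib.reads_per_fragment):
                draw_pair(hap_i, fstart, fstart + flen, f"{name}_{f}_{j}", bc)
        return SimulatedLibrary(lib, reads1, reads2, names, barcodes, placements)

    # long reads
    n_reads = int(np.ceil(lib.coverage * glen / rl))
    longs: list[str] = []
    for i in range(n_reads):
        hap_i = i % 2
        hap = haplotypes[hap_i]
        length = int(rng.integers(rl // 2, rl * 3 // 2 + 1))
        length = min(length, len(hap))
        start = int(rng.integers(0, len(hap) - length + 1))
        frag = hap[start : start + length]
        strand = int(rng.integers(0, 2))
        if strand:
            frag = revcomp(frag)
        frag = _apply_errors(rng, frag, lib.error_rate, indels=True)
        longs.append(frag)
        names.append(f"{name}_{i}")
        placements.append(ReadPlacement(f"{name}_{i}", hap_i, start, strand))
    return SimulatedLibrary(lib, longs, None, names, None, placements)


def benchmark_scenario(seed: int, length: int = 200_000,
                       het: float = 0.01) -> tuple[DiploidGenomeSpec,
                                                   LibrarySpec, LibrarySpec]:
    """The standard benchmark conditions for phasing-recovery experiments.

    A diploid genome of 200 kbp at 1% background heterozygosity with one
    10-kbp highly divergent region (5% divergence, inverted) in the middle,
    sequenced error-free with a 40x paired-end library (250-bp reads,
    400 +/- 40 insert — rapid-run HiSeq-class data, whose long reads let
    mates jointly cover any het-site spacing up to the insert size) and a
    40x mate-pair library (100-bp reads, 3000 +/- 300 insert) for
    long-range links.
    """
    genome = DiploidGenomeSpec(
        length=length, snv_rate=het,
        hdrs=[HDRSpec(length // 2, 10_000, 0.05, inversion=True)],
        seed=seed)
    pe = LibrarySpec("paired-end", coverage=40, read_length=250,
                     insert_mean=400, insert_sd=40, name="pe")
    mp = LibrarySpec("mate-pair", coverage=40, read_length=100,
                     insert_mean=3000, insert_sd=300, name="mp")
    return genome, pe, mp


def haplotype_chunks(truth: DiploidTruth, chunk: int = 10_000
                     ) -> list[tuple[str, str]]:
    """Split both haplotypes into contig-sized pieces for het-pair mining.

    The heterozygous 1k-mer pair procedure expects a redundant set of
    long contigs (its best-hit step keeps one alignment per sequence), so
    whole chromosomes are chunked first.
    """
    out = []
    for tag, seq in (("hapA", truth.hap_a), ("hapB", truth.hap_b)):
        for i in range(0, len(seq) - chunk + 1, chunk):
            out.append((f"{tag}_{i}", seq[i : i + chunk]))
    return out


# ---------------------------------------------------------------------------
# plain-text output
# ---------------------------------------------------------------------------


def write_fasta(path: str, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, sim: SimulatedLibrary, mate: int = 1) -> None:
    reads = sim.reads1 if mate == 1 else sim.reads2
    if reads is None:
        raise ValueError("library has no second mate")
    suffix = "" if sim.reads2 is None else f"/{mate}"
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            tag = f" BX:Z:{sim.barcodes[i]}" if sim.barcodes and sim.barcodes[i] else ""
            fh.write(f"@{sim.names[i]}{suffix}{tag}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_tables(prefix: str, truth: DiploidTruth) -> None:
    with open(prefix + ".variants.tsv", "w") as fh:
        fh.write("pos\tkind\tref\talt\n")
        for v in truth.variants:
            fh.write(f"{v.pos}\t{v.kind}\t{v.ref}\t{v.alt}\n")
    with open(prefix + ".hdrs.tsv", "w") as fh:
        fh.write("start\tend\tdivergence\tinversion\n")
        for h in truth.hdrs:
            fh.write(f"{h.start}\t{h.end}\t{h.divergence}\t{int(h.inversion)}\n")


def write_placements(path: str, sim: SimulatedLibrary) -> None:
    with open(path, "w") as fh:
        fh.write("read\thaplotype\tposition\tstrand\n")
        for p in sim.placements:
            fh.write(f"{p.read}\t{p.hap}\t{p.pos}\t{'-' if p.strand else '+'}\n")
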