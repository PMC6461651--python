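"""2-bit k-mer packing, canonicalisation and counting.

Sequences are encoded as uint8 code arrays (A=0, C=1, G=2, T=3, anything else,
including N, = 4).  A window of up to 32 bases packs exactly into one uint64
(2 bits per base, first base most significant), so a k-mer is a fixed-width
tuple of uint64 words and lexicographic order on the words equals
lexicographic order on the strings.  Windows containing a code >= 4 are
invalid and never counted; this makes N a hard break for k-mer extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("diphase")

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def rc_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes < 4, 3 - codes, codes)
    return np.ascontiguousarray(out[::-1])


def pack_windows(codes: np.ndarray, length: int) -> np.ndarray:
    """Pack every window of ``length`` bases (<= 32) into a uint64.

    Returns an array of n - length + 1 values; the window starting at i packs
    codes[i:i+length] with the first base most significant.  Invalid codes
    (>= 4) corrupt the value, so callers must mask with :func:`valid_windows`.
    """
    if not 1 <= length <= 32:
        raise ValueError("packable window length must be in 1..32")
    n = codes.size
    if n < length:
        return np.empty(0, dtype=np.uint64)

    def doubling(arr: np.ndarray, m: int) -> np.ndarray:
        cache: dict[int, np.ndarray] = {1: (arr & np.uint8(3)).astype(np.uint64)}

        def pk(mm: int) -> np.ndarray:
            got = cache.get(mm)
            if got is not None:
                return got
            half = mm // 2
            a, b = pk(half), pk(mm - half)
            cnt = arr.size - mm + 1
            out = (a[:cnt] << np.uint64(2 * (mm - half))) + b[half : half + cnt]
            cache[mm] = out
            return out

        return pk(m)

    if length == 32 or n < 64:
        return doubling(codes, length)
    # an L<32 window is the top 2L bits of the 32-window at the same start;
    # only the last (32 - L) window positions need direct computation
    p32 = doubling(codes, 32)
    head = p32 >> np.uint64(2 * (32 - length))
    tail_codes = codes[n - 31 :]
    tail = doubling(tail_codes, length)[-(32 - length):]
    return np.concatenate([head, tail])


def _word_layout(k: int) -> list[tuple[int, int]]:
    """(offset, chunk_length) pairs splitting a k-mer into <=32-base words."""
    nwords = (k + 31) // 32
    sizes = [32] * (nwords - 1) + [k - 32 * (nwords - 1)]
    layout, off = [], 0
    for s in sizes:
        layout.append((off, s))
        off += s
    return layout


def kmer_words(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-windows of ``codes`` as an (N, nwords) uint64 array."""
    n = codes.size
    cnt = max(n - k + 1, 0)
    layout = _word_layout(k)
    out = np.empty((cnt, len(layout)), dtype=np.uint64)
    if cnt == 0:
        return out
    packs: dict[int, np.ndarray] = {}
    for j, (off, size) in enumerate(layout):
        if size not in packs:
            packs[size] = pack_windows(codes, size)
        out[:, j] = packs[size][off : off + cnt]
    return out


def valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over k-windows that contain no invalid (non-ACGT) code."""
    cz = np.concatenate([[0], np.cumsum(codes > 3)])
    return (cz[k:] - cz[:-k]) == 0


def canonicalize(fwd: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Elementwise lexicographic min of word-tuples (canonical k-mer form)."""
    nwords = fwd.shape[1]
    take_rc = np.zeros(len(fwd), dtype=bool)
    decided = np.zeros(len(fwd), dtype=bool)
    for j in range(nwords):
        lt = rc[:, j] < fwd[:, j]
        gt = rc[:, j] > fwd[:, j]
        take_rc |= lt & ~decided
        decided |= lt | gt
    return np.where(take_rc[:, None], rc, fwd)


def sequence_kmers(seqs: list[str], k: int, canonical_form: bool = True) -> np.ndarray:
    """Packed (canonical) k-mer words of every valid window in ``seqs``."""
    if not seqs:
        return np.empty((0, len(_word_layout(k))), dtype=np.uint64)
    joined = "N".join(seqs)
    codes = encode(joined)
    words = kmer_words(codes, k)
    mask = valid_windows(codes, k)
    words = words[mask]
    if canonical_form and len(words):
        rcc = rc_codes(codes)
        rwords = np.ascontiguousarray(kmer_words(rcc, k)[::-1])[mask]
        words = canonicalize(words, rwords)
    return words


def pack_code_matrix(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack an (M, k) code matrix into (M, nwords) uint64 rows."""
    m = len(codes)
    layout = _word_layout(k)
    out = np.zeros((m, len(layout)), dtype=np.uint64)
    for j, (off, size) in enumerate(layout):
        acc = np.zeros(m, dtype=np.uint64)
        for b in range(size):
            acc = (acc << np.uint64(2)) + codes[:, off + b]
        out[:, j] = acc
    return out


def rc_rows(words: np.ndarray, k: int) -> np.ndarray:
    """Reverse complement of each packed k-mer row."""
    codes = decode_matrix(words, k)
    rcc = np.ascontiguousarray((3 - codes)[:, ::-1])
    return pack_code_matrix(rcc, k)


def canonical_kmer_counts(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Unique canonical k-mers of ``seqs`` with occurrence counts.

    Counts forward-strand windows first and canonicalises the (much smaller)
    unique row set afterwards, merging each k-mer with its reverse
    complement.
    """
    if not seqs:
        return (np.empty((0, len(_word_layout(k))), dtype=np.uint64),
                np.empty(0, dtype=np.int64))
    words = sequence_kmers(seqs, k, canonical_form=False)
    u, c = unique_counts(words)
    if len(u) == 0:
        return u, c
    cu = canonicalize(u, rc_rows(u, k))
    key = _row_hash(np.ascontiguousarray(cu))
    order = np.argsort(key, kind="stable")
    srt = cu[order]
    change = np.ones(len(srt), dtype=bool)
    change[1:] = (srt[1:] != srt[:-1]).any(axis=1)
    starts = np.nonzero(change)[0]
    counts = np.add.reduceat(c[order], starts)
    return srt[starts], counts


_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _row_hash(arr: np.ndarray) -> np.ndarray:
    """64-bit mixing hash of each row of a packed uint64 matrix."""
    h = np.full(len(arr), np.uint64(arr.shape[1]), dtype=np.uint64)
    for j in range(arr.shape[1]):
        x = arr[:, j] * _MIX1
        x ^= x >> np.uint64(31)
        x *= _MIX2
        h = (h ^ x) * _MIX1
    return h


def unique_counts(words: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique rows of a packed k-mer array with occurrence counts.

    Rows are grouped by a 64-bit mixing hash (single-key sort) with full-row
    comparison at group boundaries, so distinct rows are never merged; a
    vanishingly unlikely hash collision can only split one row's count into
    two entries.
    """
    if len(words) == 0:
        return words, np.empty(0, dtype=np.int64)
    arr = np.ascontiguousarray(words)
    if arr.shape[1] == 1:
        key = arr[:, 0]
    else:
        key = _row_hash(arr)
    order = np.argsort(key, kind="stable")
    srt = arr[order]
    change = np.ones(len(srt), dtype=bool)
    change[1:] = (srt[1:] != srt[:-1]).any(axis=1)
    starts = np.nonzero(change)[0]
    counts = np.diff(np.append(starts, len(srt)))
    return srt[starts], counts


def decode_matrix(words: np.ndarray, k: int) -> np.ndarray:
    """Unpack k-mer words into an (M, k) uint8 code matrix."""
    m = len(words)
    codes = np.empty((m, k), dtype=np.uint8)
    for j, (off, size) in enumerate(_word_layout(k)):
        col = words[:, j]
        for b in range(size):
            codes[:, off + b] = (col >> np.uint64(2 * (size - 1 - b))).astype(np.uint8) & 3
    return codes


def words_to_strings(words: np.ndarray, k: int) -> list[str]:
    """Decode packed k-mer words back into DNA strings."""
    m = len(words)
    if m == 0:
        return []
    blob = _DECODE[decode_matrix(words, k)].tobytes().decode("ascii")
    return [blob[i * k : (i + 1) * k] for i in range(m)]


@dataclass
class KmerHistogram:
    """Occurrence distribution of distinct canonical k-mers.

    ``counts[m]`` is the number of distinct k-mers observed exactly m times;
    occurrences form the contiguous range 1..max (zeros allowed).
    """

    k: int
    counts: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_occurrences(cls, k: int, occ: np.ndarray) -> "KmerHistogram":
        if len(occ) == 0:
            return cls(k=k, counts={})
        bc = np.bincount(occ.astype(np.int64))
        return cls(k=k, counts={m: int(bc[m]) for m in range(1, len(bc))})

    @property
    def max_occurrence(self) -> int:
        return max(self.counts) if self.counts else 0

    def total_windows(self) -> int:
        return sum(m * c for m, c in self.counts.items())


@dataclass
class KmerTable:
    """Distinct canonical k-mers (packed) with their occurrence counts."""

    k: int
    words: np.ndarray  # (M, nwords) uint64
    counts: np.ndarray  # (M,) int64

    def __len__(self) -> int:
        return len(self.counts)

    def histogram(self) -> KmerHistogram:
        return KmerHistogram.from_occurrences(self.k, self.counts)

    def filtered(self, cutoff: int) -> "KmerTable":
        keep = self.counts >= cutoff
        return KmerTable(self.k, self.words[keep], self.counts[keep])

    def to_dict(self) -> dict[str, int]:
        return dict(zip(words_to_strings(self.words, self.k), self.counts.tolist()))


def count_kmers(reads: list[str], k: int) -> tuple[KmerTable, KmerHistogram]:
    """Count every valid k-window of ``reads`` under canonical form.

    Raises ``ValueError`` when k exceeds every read length (nothing countable).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if reads and all(len(r) < k for r in reads):
        raise ValueError(f"k={k} larger than every read")
    uniq, counts = canonical_kmer_counts(reads, k)
    table = KmerTable(k, uniq, counts)
    return table, table.histogram()


def initial_cutoff(hist: KmerHistogram) -> int:
    """Coverage cutoff = floor(leftmost-local-minimum-occurrence / 2).

    The local minimum is scanned on the unsmoothed histogram from occurrence 2
    upward; the first m with counts(m) <= counts(m-1) and counts(m) <=
    counts(m+1) wins (ties resolve to the smallest occurrence).  The minimum
    must also lie at or below the occurrence-1 count: the rule separates an
    error peak (which towers at occurrence 1) from the coverage peak, and a
    dip that exceeds counts(1) is sampling noise inside the signal — as
    happens with error-free reads — not an error valley.  A histogram with
    no qualifying minimum yields cutoff 1 with a warning.
    """
    if not hist.counts and hist.max_occurrence == 0:
        raise ValueError("empty histogram")
    top = hist.max_occurrence
    get = lambda m: hist.counts.get(m, 0)
    for m in range(2, top):
        if get(m) <= get(m - 1) and get(m) <= get(m + 1):
            if get(m) <= get(1):
                return max(1, m // 2)
            log.warning("leftmost local minimum at occurrence %d exceeds the "
                        "occurrence-1 count (no error peak); using cutoff 1", m)
            return 1
    log.warning("k-mer histogram has no local minimum; using cutoff 1")
    return 1
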