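"""Minimal PAF handling and a minimap2 subprocess wrapper.

Only the fields the evaluation procedures need are modelled: coordinates,
match counts, the NM edit-distance tag and the cs long-form difference
string, from which both aligned sequences can be reconstructed without
touching the source FASTA.
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    matches: int
    aln_len: int
    mapq: int
    tags: dict = field(default_factory=dict)

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0

    @property
    def edit_distance(self) -> int | None:
        v = self.tags.get("NM")
        return int(v) if v is not None else None

    @property
    def cs(self) -> str | None:
        return self.tags.get("cs")


def parse_paf_line(line: str) -> PafRecord | None:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        return None
    tags = {}
    for t in f[12:]:
        parts = t.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return PafRecord(
        qname=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
        strand=f[4], tname=f[5], tlen=int(f[6]), tstart=int(f[7]),
        tend=int(f[8]), matches=int(f[9]), aln_len=int(f[10]),
        mapq=int(f[11]), tags=tags,
    )


def parse_paf_file(path: str) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = parse_paf_line(line)
            if rec is not None:
                out.append(rec)
    return out


_CS_TOKEN = re.compile(r"(=[A-Za-z]+|\*[A-Za-z][A-Za-z]|\+[A-Za-z]+|-[A-Za-z]+|:\d+)")


def cs_to_alignment(cs: str) -> tuple[str, str]:
    """Reconstruct (target_aln, query_aln) with '-' gaps from a cs string.

    Long-form tokens carry the bases; the short-form ":N" match run is
    rendered as N placeholder matches ('M') since the bases are not recorded.
    """
    t, q = [], []
    for tok in _CS_TOKEN.findall(cs):
        op, body = tok[0], tok[1:]
        if op == "=":
            t.append(body.upper())
            q.append(body.upper())
        elif op == ":":
            t.append("M" * int(body))
            q.append("M" * int(body))
        elif op == "*":
            t.append(body[0].upper())
            q.append(body[1].upper())
        elif op == "+":
            t.append("-" * len(body))
            q.append(body.upper())
        elif op == "-":
            t.append(body.upper())
            q.append("-" * len(body))
    return "".join(t), "".join(q)


def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


def run_minimap2(target_fa: str, query_fa: str, options: list[str]) -> list[PafRecord]:
    """Run minimap2 and parse its PAF output."""
    if not minimap2_available():
        raise RuntimeError("minimap2 executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        out = os.path.join(tmp, "out.paf")
        with open(out, "w") as fh:
            subprocess.run(["minimap2", *options, target_fa, query_fa],
                           stdout=fh, stderr=subprocess.DEVNULL, check=True)
        return parse_paf_file(out)


def align_all_vs_all(seqs: list[tuple[str, str]],
                     options: list[str] | None = None) -> list[PafRecord]:
    """All-vs-all self alignment of named sequences (skipping self hits)."""
    options = options or ["-c", "-k19", "-p0", "-X", "--cs=long"]
    with tempfile.TemporaryDirectory() as tmp:
        fa = os.path.join(tmp, "seqs.fa")
        with open(fa, "w") as fh:
            for name, seq in seqs:
                fh.write(f">{name}\n{seq}\n")
        return run_minimap2(fa, fa, options)


def align_to(target: list[tuple[str, str]], query: list[tuple[str, str]],
             options: list[str] | None = None) -> list[PafRecord]:
    options = options or ["-c", "-k19", "-p1", "--cs=long"]
    with tempfile.TemporaryDirectory() as tmp:
        tfa = os.path.join(tmp, "target.fa")
        qfa = os.path.join(tmp, "query.fa")
        for path, recs in ((tfa, target), (qfa, query)):
            with open(path, "w") as fh:
                for name, seq in recs:
                    fh.write(f">{name}\n{seq}\n")
        return run_minimap2(tfa, qfa, options)
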