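"""PAF alignment records with cigar support.

PAF is the 12-column pairwise-mapping format produced by minimap2; the cigar
travels in the ``cg:Z:`` tag. Coordinates are 0-based half-open. Records
produced by external aligners are first-class inputs everywhere in this
package; only the handful of cigar operations the analyses require are
interpreted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops that consume query / target sequence
QUERY_OPS = frozenset("MIS=X")
TARGET_OPS = frozenset("MDN=X")
ALIGNED_OPS = frozenset("M=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in CIGAR_RE.findall(cigar)]
    if sum(len(f"{n}{op}") for n, op in ops) != len(cigar):
        raise ValueError(f"malformed cigar: {cigar!r}")
    return ops


def cigar_spans(ops: Iterable[tuple[int, str]]) -> tuple[int, int]:
    """(query_consumed, target_consumed) for a cigar op list."""
    q = sum(n for n, op in ops if op in QUERY_OPS)
    t = sum(n for n, op in ops if op in TARGET_OPS)
    return q, t


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
    block_len: int
    mapq: int = 60
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def cigar(self) -> list[tuple[int, str]] | None:
        cg = self.tags.get("cg")
        return parse_cigar(cg) if cg is not None else None

    def validate(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query interval in {self.qname}->{self.tname}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target interval in {self.qname}->{self.tname}")
        if self.matches > self.block_len:
            raise ValueError("matches exceed alignment block length")
        ops = self.cigar
        if ops is not None:
            q, t = cigar_spans(ops)
            if q != self.qend - self.qstart or t != self.tend - self.tstart:
                raise ValueError(
                    f"cigar spans ({q},{t}) disagree with coordinates of "
                    f"{self.qname}->{self.tname}"
                )

    def to_line(self) -> str:
        cols = [
            self.qname, self.qlen, self.qstart, self.qend, self.strand,
            self.tname, self.tlen, self.tstart, self.tend,
            self.matches, self.block_len, self.mapq,
        ]
        tagcols = []
        for key, val in self.tags.items():
            typ = "i" if key in ("NM", "AS") else "Z"
            tagcols.append(f"{key}:{typ}:{val}")
        return "\t".join(map(str, cols + tagcols))


def read_paf(path: str | Path) -> list[PafRecord]:
    return list(iter_paf(path))


def iter_paf(path: str | Path) -> Iterator[PafRecord]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            tags = {}
            for col in f[12:]:
                key, _typ, val = col.split(":", 2)
                tags[key] = val
            yield PafRecord(
                qname=f[0], qlen=int(f[1]), qstart=int(f[2]), qend=int(f[3]),
                strand=f[4], tname=f[5], tlen=int(f[6]), tstart=int(f[7]),
                tend=int(f[8]), matches=int(f[9]), block_len=int(f[10]),
                mapq=int(f[11]), tags=tags,
            )


def write_paf(records: Iterable[PafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
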