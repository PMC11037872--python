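"""FLNC read filtering, paralog assignment, and normalized expression.

Full-length non-chimeric (FLNC) cDNA reads carry a per-read predicted
accuracy. The pipeline keeps reads of >= 1000 bp and >= 99.9% accuracy,
calls a paralog *expressed* when at least one read aligns to it at >= 99.9%
identity, assigns each read to the paralog group whose best alignment score
beats every other group's best by at least 10 score units (otherwise the
read is ambiguous), and summarizes expression per group normalized by the
median per-haplotype copy number of that group.

Score dialect: when alignments come from SAM/PAF the ``AS`` tag is used
unchanged; the internal scorer reports the negated edit distance of a
global alignment, which lives on the same raw-score scale for the margin
rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd


@dataclass
class FlncRead:
    id: str
    sequence: str
    accuracy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError(f"read {self.id}: accuracy outside [0, 1]")

    @property
    def length(self) -> int:
        return len(self.sequence)


def filter_flnc(
    reads: Iterable[FlncRead],
    min_length: int = 1000,
    min_accuracy: float = 0.999,
) -> tuple[list[FlncRead], list[FlncRead]]:
    """(kept, filtered): keep iff length >= 1000 bp and accuracy >= 99.9%."""
    kept, filtered = [], []
    for read in reads:
        ok = read.length >= min_length and read.accuracy >= min_accuracy
        (kept if ok else filtered).append(read)
    return kept, filtered


@dataclass
class ScoredAlignment:
    """One scored alignment of a read against one paralog copy."""

    read_id: str
    copy_id: str
    score: float
    identity: float | None = None


def score_read(read_seq: str, template_seq: str) -> ScoredAlignment:
    """Internal scorer: negated global (NW) edit distance."""
    res = edlib.align(read_seq, template_seq, mode="NW", task="distance")
    dist = res["editDistance"]
    identity = 1.0 - dist / max(len(read_seq), len(template_seq))
    return ScoredAlignment(read_id="", copy_id="", score=-float(dist),
                           identity=identity)


def align_to_copies(
    reads: Sequence[FlncRead], copy_sequences: Mapping[str, str]
) -> list[ScoredAlignment]:
    """Score every read against every paralog copy with the internal scorer."""
    out = []
    for read in reads:
        for copy_id, seq in copy_sequences.items():
            sa = score_read(read.sequence, seq)
            sa.read_id, sa.copy_id = read.id, copy_id
            out.append(sa)
    return out


def expressed_paralogs(
    alignments: Iterable[ScoredAlignment], min_identity: float = 0.999
) -> set[str]:
    """Paralog copies with at least one read aligned at >= 99.9% identity."""
    return {a.copy_id for a in alignments
            if a.identity is not None and a.identity >= min_identity}


ASSIGNED = "ASSIGNED"
AMBIGUOUS = "AMBIGUOUS"
UNMAPPED = "UNMAPPED"
FILTERED = "FILTERED"


@dataclass
class ReadAssignment:
    read_id: str
    status: str
    group: str | None = None
    best_score: float | None = None
    margin: float | None = None


def assign_reads(
    read_alignments: Iterable[ScoredAlignment],
    copy_to_group: Mapping[str, str],
    score_margin: float = 10.0,
    read_ids: Sequence[str] | None = None,
) -> list[ReadAssignment]:
    """Assign reads to paralog groups by best-score margin.

    Per read the best score of each group is taken; the read is ASSIGNED to
    the top group iff its best beats the runner-up group's best by at least
    ``score_margin``, AMBIGUOUS otherwise. Reads aligned to copies of a
    single group are ASSIGNED with infinite margin; reads without
    alignments (listed via ``read_ids``) are UNMAPPED. Output order and
    content are independent of alignment record order.
    """
    per_read: dict[str, dict[str, float]] = {}
    for aln in read_alignments:
        if aln.copy_id not in copy_to_group:
            raise KeyError(f"copy {aln.copy_id!r} has no group mapping")
        group = copy_to_group[aln.copy_id]
        scores = per_read.setdefault(aln.read_id, {})
        if group not in scores or aln.score > scores[group]:
            scores[group] = aln.score
    ids = list(read_ids) if read_ids is not None else sorted(per_read)
    out = []
    for rid in ids:
        scores = per_read.get(rid)
        if not scores:
            out.append(ReadAssignment(rid, UNMAPPED))
            continue
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        best_group, best = ranked[0]
        if len(ranked) == 1:
            out.append(ReadAssignment(rid, ASSIGNED, best_group, best,
                                      float("inf")))
            continue
        margin = best - ranked[1][1]
        if margin >= score_margin:
            out.append(ReadAssignment(rid, ASSIGNED, best_group, best,
                                      margin))
        else:
            out.append(ReadAssignment(rid, AMBIGUOUS, None, best, margin))
    return out


@dataclass
class IsoformModel:
    """A collapsed isoform: identical-intron-chain reads plus its ORF span
    on the transcript/genome coordinate system of the caller."""

    id: str
    read_ids: list[str]
    orf_start: int
    orf_end: int


def isoform_support(
    models: Iterable[IsoformModel],
    canonical_start: int,
    canonical_stop: int,
    min_reads: int = 3,
    anchor_slop_bp: int = 100,
) -> list[IsoformModel]:
    """Keep isoforms with >= 3 supporting reads whose ORF endpoints fall
    within 100 bp of the canonical start and stop."""
    kept = []
    for model in models:
        if len(model.read_ids) < min_reads:
            continue
        if abs(model.orf_start - canonical_start) > anchor_slop_bp:
            continue
        if abs(model.orf_end - canonical_stop) > anchor_slop_bp:
            continue
        kept.append(model)
    return kept


@dataclass
class ExpressionSummary:
    raw_counts: dict[str, int]
    median_copies: dict[str, float]
    normalized_counts: dict[str, float]
    normalized_fractions: dict[str, float]
    raw_fractions: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "raw_counts": self.raw_counts,
            "median_copies": self.median_copies,
            "normalized_counts": self.normalized_counts,
            "normalized_fractions": self.normalized_fractions,
            "raw_fractions": self.raw_fractions,
        }


def expression_summary(
    assignments: Sequence[ReadAssignment],
    copies_per_haplotype: pd.DataFrame,
) -> ExpressionSummary:
    """Copy-number-normalized expression per paralog group.

    ``copies_per_haplotype`` is a group x haplotype table of copy counts.
    The normalized count of a group is its raw ASSIGNED-read count divided
    by the median over haplotypes of the group's copy number (enforced
    >= 1); fractions are over the normalized (and raw) totals.
    """
    raw: dict[str, int] = {}
    for asn in assignments:
        if asn.status == ASSIGNED and asn.group is not None:
            raw[asn.group] = raw.get(asn.group, 0) + 1
    med: dict[str, float] = {}
    norm: dict[str, float] = {}
    for group, count in raw.items():
        if group not in copies_per_haplotype.index:
            raise KeyError(f"group {group!r} missing from copy table")
        copies = copies_per_haplotype.loc[group].to_numpy(dtype=float)
        m = float(np.median(copies))
        if m <= 0:
            raise ValueError(f"group {group!r} has zero median copy number")
        med[group] = max(m, 1.0)
        norm[group] = count / med[group]
    norm_total = sum(norm.values())
    raw_total = sum(raw.values())
    return ExpressionSummary(
        raw_counts=raw,
        median_copies=med,
        normalized_counts=norm,
        normalized_fractions={g: v / norm_total for g, v in norm.items()}
        if norm_total else {},
        raw_fractions={g: v / raw_total for g, v in raw.items()}
        if raw_total else {},
    )


def conservation_check(
    n_input: int,
    filtered: Sequence[FlncRead],
    assignments: Sequence[ReadAssignment],
) -> bool:
    """filter -> assign conserves reads: every input read ends in exactly
    one of FILTERED / UNMAPPED / AMBIGUOUS / ASSIGNED."""
    return n_input == len(filtered) + len(assignments)
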