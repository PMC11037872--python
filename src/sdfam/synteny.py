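"""Synteny blocks and the breakpoint-proximity permutation test.

Pairwise chromosome alignments are chained into colinear synteny blocks
(defaults: max_gap 200 kbp, min_block_size 1 Mbp, min_subblock_size
50 kbp); block boundaries are the synteny breaks. The permutation test asks
whether a set of genomic features (duplication-cluster mappings) sits closer
to synteny breaks than chance: each of ``n_perm`` permutations (default
5000) redraws the same number of ~11 kbp blocks uniformly along the
chromosome — optionally restricted to given intervals, e.g. segmental
duplications — and recomputes the median feature-to-break distance. The
empirical p-value uses the add-one estimator (r+1)/(n+1), so it is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .paf import PafRecord


@dataclass
class SyntenyParams:
    max_gap: int = 200_000
    min_block_size: int = 1_000_000
    min_subblock_size: int = 50_000

    def __post_init__(self) -> None:
        if min(self.max_gap, self.min_block_size, self.min_subblock_size) <= 0:
            raise ValueError("all synteny parameters must be positive")
        if self.min_subblock_size > self.min_block_size:
            raise ValueError("min_subblock_size exceeds min_block_size")


@dataclass
class SyntenyBlock:
    tstart: int
    tend: int
    qname: str
    qstart: int
    qend: int
    orientation: str  # "+" | "-"
    members: list[int] = field(default_factory=list)  # input record indices

    @property
    def target_span(self) -> int:
        return self.tend - self.tstart


def _colinear(prev: PafRecord, nxt: PafRecord, params: SyntenyParams) -> bool:
    """Can ``nxt`` extend a chain ending in ``prev``? Both genomes must
    advance in the block's orientation with gaps within max_gap."""
    if nxt.qname != prev.qname or nxt.strand != prev.strand:
        return False
    tgap = nxt.tstart - prev.tend
    if tgap < 0 or tgap > params.max_gap:
        return False
    if prev.strand == "+":
        qgap = nxt.qstart - prev.qend
    else:  # query runs backwards along the target
        qgap = prev.qstart - nxt.qend
    return 0 <= qgap <= params.max_gap


def chain_synteny(
    alignments: Sequence[PafRecord], params: SyntenyParams | None = None
) -> list[SyntenyBlock]:
    """Chain colinear alignments on one target chromosome into blocks.

    Alignments below ``min_subblock_size`` (target span) are discarded
    before chaining; chains whose target span falls below
    ``min_block_size`` are discarded after. Returned blocks are ordered and
    non-overlapping on the target (overlap is trimmed from the later,
    smaller block).
    """
    params = params or SyntenyParams()
    if not alignments:
        return []
    tnames = {rec.tname for rec in alignments}
    if len(tnames) > 1:
        raise ValueError(f"alignments span multiple targets: {sorted(tnames)}")
    keep = [(i, rec) for i, rec in enumerate(alignments)
            if rec.tend - rec.tstart >= params.min_subblock_size]
    keep.sort(key=lambda item: (item[1].tstart, item[1].tend))

    blocks: list[SyntenyBlock] = []
    current: SyntenyBlock | None = None
    prev_rec: PafRecord | None = None
    for i, rec in keep:
        if current is not None and _colinear(prev_rec, rec, params):
            current.tend = rec.tend
            current.qstart = min(current.qstart, rec.qstart)
            current.qend = max(current.qend, rec.qend)
            current.members.append(i)
        else:
            if current is not None:
                blocks.append(current)
            current = SyntenyBlock(
                tstart=rec.tstart, tend=rec.tend, qname=rec.qname,
                qstart=rec.qstart, qend=rec.qend, orientation=rec.strand,
                members=[i])
        prev_rec = rec
    if current is not None:
        blocks.append(current)

    blocks = [b for b in blocks if b.target_span >= params.min_block_size]
    # enforce non-overlap on target
    pruned: list[SyntenyBlock] = []
    for b in blocks:
        if pruned and b.tstart < pruned[-1].tend:
            b.tstart = pruned[-1].tend
            if b.target_span < params.min_block_size:
                continue
        pruned.append(b)
    return pruned


def breakpoints(
    blocks: Sequence[SyntenyBlock],
    chromosome_length: int | None = None,
    exclude_termini: bool = True,
) -> np.ndarray:
    """Sorted, deduplicated block boundary positions on the target.

    Chromosome termini (position 0 and ``chromosome_length``) are alignment
    artifacts rather than rearrangement evidence and are dropped by default
    when ``chromosome_length`` is given.
    """
    pos = sorted({p for b in blocks for p in (b.tstart, b.tend)})
    if exclude_termini and chromosome_length is not None:
        pos = [p for p in pos if p not in (0, chromosome_length)]
    return np.asarray(pos, dtype=np.int64)


def _min_distances(midpoints: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Distance from each midpoint to its nearest break (both sorted-safe)."""
    breaks = np.sort(breaks)
    idx = np.searchsorted(breaks, midpoints)
    left = np.abs(midpoints - breaks[np.clip(idx - 1, 0, breaks.size - 1)])
    right = np.abs(breaks[np.clip(idx, 0, breaks.size - 1)] - midpoints)
    return np.minimum(left, right)


def _lower_median(values: np.ndarray) -> float:
    """Median taking the lower of the middle two for even counts."""
    v = np.sort(values)
    return float(v[(v.size - 1) // 2])


def median_break_distance(
    features: Sequence[tuple[int, int]], breaks: np.ndarray
) -> float:
    """Median over features of the distance from the feature midpoint to the
    nearest synteny break."""
    if len(breaks) == 0:
        raise ValueError("no synteny breaks")
    if len(features) == 0:
        raise ValueError("no features")
    mids = np.array([(s + e) // 2 for s, e in features], dtype=np.int64)
    return _lower_median(_min_distances(mids, np.asarray(breaks)))


@dataclass
class PermutationResult:
    observed_median_bp: float
    null_medians: np.ndarray
    empirical_p: float
    n_perm: int
    block_length_bp: int
    restricted: bool

    def to_dict(self, histogram_bins: int = 50) -> dict:
        hist, edges = np.histogram(self.null_medians, bins=histogram_bins)
        return {
            "observed_median_bp": self.observed_median_bp,
            "empirical_p": self.empirical_p,
            "n_perm": self.n_perm,
            "block_length_bp": self.block_length_bp,
            "restricted": self.restricted,
            "null_median_mean": float(self.null_medians.mean()),
            "null_histogram": {
                "counts": hist.tolist(),
                "edges": edges.tolist(),
            },
        }


def _restricted_sampler(
    restriction: Sequence[tuple[int, int]], block_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """(cumulative allowed-start mass, interval table) for restricted draws."""
    table = []
    for s, e in restriction:
        room = (e - s) - block_length + 1
        if room > 0:
            table.append((s, room))
    if not table:
        raise ValueError("restriction intervals cannot hold a block")
    starts = np.array([s for s, _ in table], dtype=np.int64)
    rooms = np.array([r for _, r in table], dtype=np.int64)
    return starts, rooms


def permutation_test(
    features: Sequence[tuple[int, int]],
    breaks: np.ndarray,
    chromosome_length: int,
    n_perm: int = 5000,
    block_length: int = 11_000,
    restriction: Sequence[tuple[int, int]] | None = None,
    seed: int = 0,
) -> PermutationResult:
    """Permutation null for the median feature-to-break distance.

    Each permutation draws ``len(features)`` blocks of ``block_length``
    uniformly over allowed start positions (with replacement; within
    ``restriction`` intervals when given) and recomputes the median
    midpoint-to-break distance. ``empirical_p = (1 + #{null <= obs}) /
    (n_perm + 1)``.
    """
    if chromosome_length <= block_length:
        raise ValueError("chromosome shorter than a sampled block")
    breaks = np.asarray(breaks, dtype=np.int64)
    observed = median_break_distance(features, breaks)
    nf = len(features)
    rng = np.random.default_rng(seed)
    if restriction is None:
        starts = rng.integers(0, chromosome_length - block_length + 1,
                              size=(n_perm, nf))
    else:
        if sum(e - s for s, e in restriction) < nf * block_length:
            raise ValueError("restriction too small for the feature count")
        iv_starts, rooms = _restricted_sampler(restriction, block_length)
        cum = np.cumsum(rooms)
        draw = rng.integers(0, cum[-1], size=(n_perm, nf))
        which = np.searchsorted(cum, draw, side="right")
        offset = draw - np.concatenate([[0], cum[:-1]])[which]
        starts = iv_starts[which] + offset
    mids = starts + block_length // 2
    dists = _min_distances(mids.ravel(), breaks).reshape(n_perm, nf)
    dists.sort(axis=1)
    null = dists[:, (nf - 1) // 2].astype(float)
    p = (1 + int((null <= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed_median_bp=observed, null_medians=null, empirical_p=p,
        n_perm=n_perm, block_length_bp=block_length,
        restricted=restriction is not None)
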