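"""Read-depth copy-number estimation from exact canonical k-mers.

The estimator mirrors standard k-mer read-depth CN practice: k-merize the
reads (default k=32), count how often each reference k-mer occurs, and
convert depth to copy number by normalizing the gene-window mean against the
mean over single-copy control regions, scaled by ploidy. Matching is exact
on canonical k-mers (lexicographic min of a k-mer and its reverse
complement); a mismatch-tolerance hook exists in the original tooling but is
deliberately not replicated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _seq
from .simulate import LocusHaplotype


def _codes_2d(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed 2-bit k-mer codes along the last axis of a 0..3 array."""
    m = arr.shape[-1] - k + 1
    if m <= 0:
        return np.empty(arr.shape[:-1] + (0,), dtype=np.uint64)
    codes = np.zeros(arr.shape[:-1] + (m,), dtype=np.uint64)
    for j in range(k):
        codes |= arr[..., j:j + m].astype(np.uint64) << np.uint64(
            2 * (k - 1 - j))
    return codes


def canonical_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-min) k-mer codes of a 0..3 encoded sequence."""
    if k < 11 or k > 32:
        raise ValueError("k must be in [11, 32] for 64-bit packing")
    fwd = _codes_2d(arr, k)
    rc = _codes_2d((3 - arr)[..., ::-1], k)[..., ::-1]
    return np.minimum(fwd, rc)


def _read_code_bag(reads: Iterable[str], k: int) -> np.ndarray:
    """All canonical k-mer codes over a read set, batched by read length."""
    by_len: dict[int, list[np.ndarray]] = {}
    for read in reads:
        arr = _seq.encode(read)
        if arr.size >= k:
            by_len.setdefault(arr.size, []).append(arr)
    chunks = []
    for length, arrs in by_len.items():
        stacked = np.stack(arrs)
        chunks.append(canonical_codes(stacked, k).ravel())
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.sort(np.concatenate(chunks))


def kmer_depth(reads: Iterable[str], reference: str, k: int = 32
               ) -> np.ndarray:
    """Per-position read depth of reference k-mers.

    Position ``i`` of the result holds the number of exact occurrences, over
    all reads on either strand, of the reference k-mer starting at ``i``;
    the vector has ``len(reference) - k + 1`` entries.
    """
    ref = _seq.encode(reference)
    if ref.size < k:
        raise ValueError("k exceeds reference length")
    ref_codes = canonical_codes(ref, k)
    bag = _read_code_bag(reads, k)
    lo = np.searchsorted(bag, ref_codes, side="left")
    hi = np.searchsorted(bag, ref_codes, side="right")
    return (hi - lo).astype(np.int64)


@dataclass
class KmerCNModel:
    """Depth model over one reference paralog window.

    ``gene_window`` and ``control_regions`` are 0-based half-open intervals
    on the reference; control regions must be single-copy-per-haplotype
    sequence and disjoint from the gene window. ``mask_factor`` drops
    repeat-degenerate positions whose depth exceeds that multiple of the
    gene window's own median.
    """

    k: int = 32
    reference_name: str = "reference"
    gene_window: tuple[int, int] = (0, 0)
    control_regions: list[tuple[int, int]] = field(default_factory=list)
    depth: np.ndarray | None = None
    control_depth_mean: float | None = None
    mask_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("k must be >= 11")
        gs, ge = self.gene_window
        for cs, ce in self.control_regions:
            if cs < ge and gs < ce:
                raise ValueError("control region overlaps the gene window")

    def fit(self, reads: Iterable[str], reference: str) -> "KmerCNModel":
        self.depth = kmer_depth(reads, reference, self.k)
        ctrl = self._positions(self.control_regions)
        if ctrl.size == 0:
            raise ValueError("no control positions inside the depth vector")
        mean = float(self.depth[ctrl].mean())
        if mean <= 0:
            raise EstimationError("control regions have zero depth")
        self.control_depth_mean = mean
        return self

    def _positions(self, regions: Sequence[tuple[int, int]]) -> np.ndarray:
        assert self.depth is not None
        idx = []
        for s, e in regions:
            e = min(e - self.k + 1, self.depth.size)
            if e > s:
                idx.append(np.arange(s, e))
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)


class EstimationError(RuntimeError):
    pass


@dataclass
class CopyNumberEstimate:
    sample: str
    read_cn: float
    assembly_cn: int
    window: tuple[int, int]


def estimate_cn(model: KmerCNModel, ploidy: int = 2) -> float:
    """Copy number = masked gene-window mean / control mean x ploidy."""
    if model.depth is None or model.control_depth_mean is None:
        raise EstimationError("model not fitted")
    gene = model._positions([model.gene_window])
    if gene.size == 0:
        raise EstimationError("empty gene window")
    d = model.depth[gene].astype(float)
    med = np.median(d)
    if med > 0:
        d = d[d <= model.mask_factor * med]
    return float(d.mean() / model.control_depth_mean * ploidy)


def assembly_cn(
    assemblies: Sequence[LocusHaplotype | str],
    probe: str,
    min_match_bp: int = 6000,
    k: int = 32,
    merge_gap_bp: int = 500,
) -> int:
    """Count probe matches of at least ``min_match_bp`` across assemblies.

    A match is a run of assembly positions whose canonical k-mers occur in
    the probe, merged across gaps up to ``merge_gap_bp`` (SNVs between a
    diverged copy and the probe knock out up to ``k`` consecutive shared
    k-mers, so runs are merged before the length filter). Matches shorter
    than ``min_match_bp`` — e.g. truncated copies — are excluded. A merged
    run spanning several probe lengths (directly adjacent tandem copies)
    counts as ``round(span / len(probe))`` copies.
    """
    if len(probe) < min_match_bp:
        raise ValueError("probe shorter than min_match_bp")
    probe_codes = np.sort(canonical_codes(_seq.encode(probe), k))
    total = 0
    for asm in assemblies:
        seq = asm.sequence if isinstance(asm, LocusHaplotype) else asm
        arr = _seq.encode(seq)
        if arr.size < k:
            continue
        codes = canonical_codes(arr, k)
        idx = np.searchsorted(probe_codes, codes)
        idx = np.clip(idx, 0, probe_codes.size - 1)
        member = probe_codes[idx] == codes
        pos = np.nonzero(member)[0]
        if pos.size == 0:
            continue
        gaps = np.diff(pos)
        breaks = np.nonzero(gaps > merge_gap_bp)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(starts, ends):
            span = pos[e] - pos[s] + k
            if span >= min_match_bp:
                total += max(1, round(span / len(probe)))
    return total


def cn_concordance(estimates: Sequence[CopyNumberEstimate]) -> dict:
    """Pearson r and mean absolute difference of read vs assembly CN."""
    if len(estimates) < 3:
        raise ValueError("need at least 3 samples")
    read = np.array([e.read_cn for e in estimates], dtype=float)
    asm = np.array([e.assembly_cn for e in estimates], dtype=float)
    mad = float(np.mean(np.abs(read - asm)))
    if np.ptp(read) == 0 or np.ptp(asm) == 0:
        return {"pearson_r": None, "mad": mad, "n": len(estimates),
                "note": "correlation undefined for constant vectors"}
    r, _p = stats.pearsonr(read, asm)
    return {"pearson_r": float(r), "mad": mad, "n": len(estimates)}
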