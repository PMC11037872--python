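"""Assembly validation from primary/secondary base depth.

Reads are mapped back onto the assembly they produced; at every position the
depth of the most frequent aligned base (primary) and the second most
frequent (secondary) is recorded. A correct assembly backed by highly
accurate long reads shows secondary fractions at the sequencing error floor
(~0.1%); a collapse of two diverged copies shows ~50% secondary fraction at
their divergent sites plus a primary-depth spike, and a gap shows no read
support at all. The source analysis drew these calls from depth plots by
eye; here the same signals are thresholded explicitly (per-site discordant
secondary counts, zero-coverage runs), with every threshold exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import _seq


@dataclass
class ReadPlacement:
    """An ungapped placement of a read on a target sequence."""

    sequence: str
    target_start: int


@dataclass
class DepthProfile:
    name: str
    primary_depth: np.ndarray
    secondary_depth: np.ndarray

    def __post_init__(self) -> None:
        if self.primary_depth.shape != self.secondary_depth.shape:
            raise ValueError("depth arrays differ in length")
        if np.any(self.secondary_depth > self.primary_depth):
            raise ValueError("secondary depth exceeds primary depth")


@dataclass
class QcFlag:
    start: int
    end: int
    kind: str  # "GAP" | "COLLAPSE"
    mean_primary_depth: float
    mean_secondary_fraction: float
    depth_spike: float = 0.0  # mean primary depth / expected depth


def depth_profile(
    placements: Iterable[ReadPlacement], target_length: int,
    name: str = "target",
) -> DepthProfile:
    """Per-position primary/secondary base depth from ungapped placements."""
    counts = np.zeros((4, target_length), dtype=np.int32)
    for pl in placements:
        arr = _seq.encode(pl.sequence)
        s = pl.target_start
        if s < 0:  # overhanging placement: keep the overlapping part
            arr = arr[-s:]
            s = 0
        e = min(s + arr.size, target_length)
        if s >= target_length or e <= s:
            continue
        seg = arr[: e - s]
        for base in range(4):
            counts[base, s:e] += seg == base
    order = np.sort(counts, axis=0)
    return DepthProfile(name=name,
                        primary_depth=order[3].astype(np.int64),
                        secondary_depth=order[2].astype(np.int64))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True values."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def _bridge(runs: list[tuple[int, int]], max_gap: int
            ) -> list[tuple[int, int]]:
    """Merge runs separated by at most ``max_gap`` indices."""
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def flag_regions(
    profile: DepthProfile,
    expected_depth: float,
    secondary_frac_threshold: float = 0.10,
    depth_spike_factor: float = 1.5,
    min_flag_window: int = 5000,
    window: int = 1000,
    min_discordant_per_window: int = 1,
    min_site_depth: int = 5,
    min_secondary_depth: int = 5,
    bridge_windows: int = 2,
    min_total_discordant: int = 5,
) -> list[QcFlag]:
    """Flag GAP and COLLAPSE intervals from a depth profile.

    The profile is aggregated into non-overlapping windows (default 1 kbp) so
    isolated error pileups cannot trigger a call; runs of flagged windows
    shorter than ``min_flag_window`` are dropped. GAP = no primary depth at
    all. COLLAPSE follows the per-site secondary-base signal: a position is
    *discordant* when its secondary depth reaches
    ``secondary_frac_threshold`` of its primary depth and at least
    ``min_secondary_depth`` reads (at primary depth >= ``min_site_depth``).
    At a collapse of two diverged copies that happens at every divergent
    site (secondary fraction ~0.5), while the ~0.1% sequencing error floor
    and stray multi-mapped reads stay below the absolute count. A window is
    collapse-like when it holds at least ``min_discordant_per_window``
    discordant sites; divergent sites are sparse at allelic SNV density
    (~1.5/kbp), so collapse-like windows separated by up to
    ``bridge_windows`` quiet windows merge into one candidate region, which
    is reported when it spans ``min_flag_window`` and accumulates
    ``min_total_discordant`` discordant sites. The
    primary-depth spike relative to ``expected_depth`` is recorded as
    corroborating evidence, not a gate.
    """
    if expected_depth <= 0:
        raise ValueError("expected_depth must be positive")
    length = profile.primary_depth.size
    n_win = max(1, length // window)
    used = n_win * window
    prim = profile.primary_depth[:used].reshape(n_win, window)
    seco = profile.secondary_depth[:used].reshape(n_win, window)
    prim_sum = prim.sum(axis=1)
    discordant = ((seco >= secondary_frac_threshold * prim)
                  & (seco >= min_secondary_depth)
                  & (prim >= min_site_depth))
    gap_mask = prim_sum == 0
    discordant_per_win = discordant.sum(axis=1)
    col_mask = (~gap_mask) & (discordant_per_win
                              >= min_discordant_per_window)

    min_windows = max(1, min_flag_window // window)
    flags: list[QcFlag] = []
    for kind, mask in (("GAP", gap_mask), ("COLLAPSE", col_mask)):
        runs = _runs(mask)
        if kind == "COLLAPSE":
            runs = _bridge(runs, bridge_windows)
        for ws, we in runs:
            if we - ws < min_windows:
                continue
            if kind == "COLLAPSE" and \
                    discordant_per_win[ws:we].sum() < min_total_discordant:
                continue
            start, end = ws * window, min(we * window, length)
            mp = float(profile.primary_depth[start:end].mean())
            psum = profile.primary_depth[start:end].sum()
            sfrac = float(profile.secondary_depth[start:end].sum() / psum) \
                if psum > 0 else 0.0
            flags.append(QcFlag(
                start=start, end=end, kind=kind,
                mean_primary_depth=mp, mean_secondary_fraction=sfrac,
                depth_spike=mp / expected_depth))
    flags.sort(key=lambda f: (f.start, f.kind))
    return flags


def passes_qc(flags: Sequence[QcFlag]) -> bool:
    return len(flags) == 0


# ---------------------------------------------------------------------------
# minimal seed-and-vote read placement, adequate for substitution-only reads


def map_reads_ungapped(
    reads: Iterable[str], target: str, k: int = 21, stride: int = 12,
    max_occurrences: int = 20,
) -> list[ReadPlacement]:
    """Place reads on ``target`` by majority vote over shared k-mer diagonals.

    Reads from a second near-identical copy absent from the target map onto
    the surviving copy through their conserved k-mers, which is exactly the
    behavior a collapse screen needs. Seeds are dense (every ``stride``
    bases), so a read carrying any site discriminating two near-identical
    copies out-votes the wrong copy; ties are left only to reads identical
    on both placements, which contribute no mismatch signal wherever they
    land, and are broken deterministically. Reads without two concordant
    seed votes are dropped (unmapped). ``max_occurrences`` must exceed the
    copy number of the most repeated segment, or vote starvation misplaces
    reads from the uncredited copies.
    """
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i:i + k], []).append(i)
    placements: list[ReadPlacement] = []
    for read in reads:
        votes: dict[int, int] = {}
        for off in range(0, max(1, len(read) - k + 1), stride):
            for tpos in index.get(read[off:off + k], ())[:max_occurrences]:
                diag = tpos - off
                votes[diag] = votes.get(diag, 0) + 1
        if not votes:
            continue
        diag, nvotes = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
        if nvotes < 2:
            continue
        placements.append(ReadPlacement(sequence=read, target_start=diag))
    return placements
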