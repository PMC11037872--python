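"""Structural equivalence, distinctness and heterozygosity of haplotypes.

Two haplotypes of a duplication locus are *structurally equivalent* when 90%
or more of each sequence maps to the other in a single alignment, allowing
indels of at most 1 kbp inside that alignment (larger indels split it).
From the pairwise equivalence relation follow the cohort statistics: the
fraction of haplotypes with no equivalent partner (structural distinctness)
and the fraction of diploid samples whose two haplotypes are not equivalent
(structural heterozygosity). Equivalence uses the minimum of the two
coverage fractions, which makes the relation symmetric by construction; it
is intentionally not forced to be transitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .paf import PafRecord, ALIGNED_OPS, parse_cigar


@dataclass
class EquivalenceReport:
    name_a: str
    name_b: str
    fraction_a: float
    fraction_b: float
    equivalent: bool


def split_segments(
    ops: Sequence[tuple[int, str]], max_insertion_bp: int = 1000
) -> list[tuple[int, int]]:
    """(query_span, target_span) of each sub-alignment after splitting the
    cigar at every insertion or deletion longer than ``max_insertion_bp``.

    Adjacent operations of the same kind are merged first, so a degenerate
    cigar like ``600I500I`` splits exactly like the canonical ``1100I``."""
    canonical: list[tuple[int, str]] = []
    for n, op in ops:
        if canonical and canonical[-1][1] == op:
            canonical[-1] = (canonical[-1][0] + n, op)
        else:
            canonical.append((n, op))
    segments: list[tuple[int, int]] = []
    q = t = 0
    for n, op in canonical:
        if op in ALIGNED_OPS:
            q += n
            t += n
        elif op == "I":
            if n > max_insertion_bp:
                segments.append((q, t))
                q = t = 0
            else:
                q += n
        elif op in ("D", "N"):
            if n > max_insertion_bp:
                segments.append((q, t))
                q = t = 0
            else:
                t += n
        # S/H/P consume no aligned span
    segments.append((q, t))
    return [(q, t) for q, t in segments if q > 0 or t > 0]


def single_alignment_coverage(
    alignments: Sequence[PafRecord], max_insertion_bp: int = 1000
) -> tuple[float, float]:
    """Best single-alignment coverage (query side, target side) for one pair.

    Every record must be between the same two sequences. Each record's cigar
    is split at indels above ``max_insertion_bp``; the reported fractions
    are the per-side maxima of sub-alignment span over sequence length.
    """
    if not alignments:
        return 0.0, 0.0
    qname, tname = alignments[0].qname, alignments[0].tname
    best_q = best_t = 0
    for rec in alignments:
        if rec.qname != qname or rec.tname != tname:
            raise ValueError("alignments mix different sequence pairs")
        rec.validate()
        ops = rec.cigar
        if ops is None:
            raise ValueError(f"record {qname}->{tname} lacks a cg cigar tag")
        for qspan, tspan in split_segments(ops, max_insertion_bp):
            best_q = max(best_q, qspan)
            best_t = max(best_t, tspan)
    return best_q / alignments[0].qlen, best_t / alignments[0].tlen


def is_equivalent(
    fraction_a: float, fraction_b: float, threshold: float = 0.90
) -> bool:
    """Symmetric 90%-coverage rule: both sides must clear the threshold."""
    return min(fraction_a, fraction_b) >= threshold


def equivalence_matrix(
    names: Sequence[str],
    alignments: Iterable[PafRecord],
    threshold: float = 0.90,
    max_insertion_bp: int = 1000,
) -> pd.DataFrame:
    """All-by-all boolean equivalence over ``names`` from PAF alignments.

    Pairs without any alignment are non-equivalent. The result is asserted
    symmetric; the diagonal is False by convention (a haplotype is not its
    own partner).
    """
    pairs: dict[tuple[str, str], list[PafRecord]] = {}
    for rec in alignments:
        key = (rec.qname, rec.tname)
        pairs.setdefault(key, []).append(rec)
    mat = pd.DataFrame(False, index=list(names), columns=list(names))
    for (qname, tname), recs in pairs.items():
        if qname == tname or qname not in mat.index or tname not in mat.index:
            continue
        fq, ft = single_alignment_coverage(recs, max_insertion_bp)
        if is_equivalent(fq, ft, threshold):
            mat.loc[qname, tname] = True
            mat.loc[tname, qname] = True
    assert (mat.values == mat.values.T).all(), "equivalence must be symmetric"
    return mat


def distinctness_fraction(matrix: pd.DataFrame) -> float:
    """Fraction of haplotypes with no structurally equivalent partner."""
    values = matrix.values.copy()
    np.fill_diagonal(values, False)
    partnerless = (~values.any(axis=1)).sum()
    return float(partnerless / len(matrix))


def structural_heterozygosity(
    sample_haplotypes: Mapping[str, tuple[str, ...]],
    matrix: pd.DataFrame,
) -> float:
    """Fraction of diploid samples whose two haplotypes are not equivalent.

    ``sample_haplotypes`` maps sample id to its haplotype names; samples
    without both haplotypes are excluded with a warning.
    """
    n = het = 0
    for sample, haps in sample_haplotypes.items():
        if len(haps) != 2:
            warnings.warn(f"sample {sample} is not diploid; excluded")
            continue
        h1, h2 = haps
        n += 1
        if not bool(matrix.loc[h1, h2]):
            het += 1
    if n == 0:
        raise ValueError("no diploid samples")
    return het / n


def population_cn_compare(samples: pd.DataFrame) -> dict:
    """Compare diploid copy-number totals between two populations.

    ``samples`` needs columns ``sample``, ``population`` and ``diploid_cn``
    (total copies over both haplotypes and clusters). Returns per-group
    means and a Welch two-sample t-test.
    """
    groups = {pop: df["diploid_cn"].to_numpy(dtype=float)
              for pop, df in samples.groupby("population")}
    if len(groups) != 2:
        raise ValueError("exactly two populations required")
    for pop, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"population {pop} has fewer than 2 samples")
    (pa, va), (pb, vb) = groups.items()
    t, p = stats.ttest_ind(va, vb, equal_var=False)
    return {
        "means": {pa: float(va.mean()), pb: float(vb.mean())},
        "difference": float(va.mean() - vb.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "n": {pa: int(va.size), pb: int(vb.size)},
    }


def diploid_totals(copy_number: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diploid totals (all haplotypes, all clusters) from a
    truth copy-number table with sample/population/n_copies columns."""
    agg = (copy_number.groupby(["sample", "population"], as_index=False)
           ["n_copies"].sum()
           .rename(columns={"n_copies": "diploid_cn"}))
    return agg


def align_pair(
    seq_a: str, seq_b: str, name_a: str = "a", name_b: str = "b"
) -> PafRecord:
    """Global edit-distance alignment of two same-orientation sequences,
    returned as a cigar-bearing PAF record (query = ``seq_a``).

    Suitable for modest sequence sizes; large cohorts should supply
    aligner-produced PAF instead.
    """
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    cg = res["cigar"]
    ops = parse_cigar(cg)
    matches = sum(n for n, op in ops if op == "=")
    rec = PafRecord(
        qname=name_a, qlen=len(seq_a), qstart=0, qend=len(seq_a),
        strand="+", tname=name_b, tlen=len(seq_b), tstart=0,
        tend=len(seq_b), matches=matches,
        block_len=sum(n for n, _op in ops), tags={"cg": cg},
    )
    rec.validate()
    return rec
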