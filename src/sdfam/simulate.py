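"""Synthetic cohorts for a tandemly duplicated gene family.

This module generates every input class the downstream analyses consume —
phased haplotype pairs carrying a variable number of tandem gene cassettes,
rearranged chromosome pairs, shotgun read sets, full-length transcript (FLNC)
reads, and coding sequences with engineered indels — together with
machine-readable truth, so the whole pipeline is testable without external
data.

The sequence model is deliberately simple and exact:

* A duplication cluster is ``flank + k x cassette + flank``, where each
  cassette holds one gene unit (default ~11 kbp) padded to the cassette
  length (default ~40 kbp).
* Paralog groups descend from a shared ancestral cassette, each group
  ancestor mutated at half the paralogous SNV density so that *between*-group
  pairwise distances average ``paralog_snv_rate`` SNVs/10 kbp; individual
  copies mutate from their group ancestor at half the allelic density so that
  *within*-group pairwise distances average ``allelic_snv_rate`` (default
  15.3 SNVs/10 kbp, the published allelic rate in segmental duplications).
* Substitutions only; indels occur solely where explicitly engineered. SNV
  densities therefore translate exactly into pairwise distances.

Per-population copy numbers are drawn from a negative binomial discretized
and clamped to ``[cn_min, cn_max]`` (default 1..14 per cluster per
haplotype, the observed human range). All randomness flows from a single
``numpy`` Generator seeded by ``SimConfig.seed``: identical config + seed
reproduces byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import nbinom

from . import _seq
from .paf import PafRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class PopulationSpec:
    """Copy-number distribution for one population.

    ``cn_mean`` is the mean copy number per cluster per haplotype;
    ``cn_dispersion`` is the negative-binomial shape (larger = closer to
    Poisson). Draws are clamped to ``[cn_min, cn_max]``.
    """

    name: str
    cn_mean: float
    cn_dispersion: float = 15.0
    cn_min: int = 1
    cn_max: int = 14

    def validate(self) -> None:
        if self.cn_mean <= 0 or self.cn_dispersion <= 0:
            raise ConfigurationError(
                f"population {self.name}: mean and dispersion must be positive"
            )
        if not (0 < self.cn_min <= self.cn_max):
            raise ConfigurationError(
                f"population {self.name}: need 0 < cn_min <= cn_max"
            )


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 10  # per population
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("AFR", cn_mean=8.6),
            PopulationSpec("NONAFR", cn_mean=6.35),
        ]
    )
    n_clusters: int = 2
    n_paralog_groups: int = 4
    cassette_length_bp: int = 40_000
    unit_gene_length_bp: int = 11_000
    flank_length_bp: int = 10_000
    allelic_snv_rate: float = 15.3  # SNVs per 10 kbp within a paralog group
    paralog_snv_rate: float = 60.0  # SNVs per 10 kbp between paralog groups
    read_depth: float = 30.0
    read_error_rate: float = 0.001
    #: stratified inverse-CDF copy-number draws (Latin-hypercube style):
    #: the cohort's empirical distribution tracks the nominal one closely
    #: even at small n; set False for plain iid draws
    stratified_cn: bool = True

    def validate(self) -> None:
        if self.n_samples < 1 or not self.populations:
            raise ConfigurationError("need >= 1 sample and >= 1 population")
        for pop in self.populations:
            pop.validate()
        if self.unit_gene_length_bp > self.cassette_length_bp:
            raise ConfigurationError("gene unit longer than cassette")
        for name in ("allelic_snv_rate", "paralog_snv_rate",
                     "read_depth", "read_error_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_clusters < 1 or self.n_paralog_groups < 1:
            raise ConfigurationError("need >= 1 cluster and paralog group")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class ParalogCopy:
    start: int  # gene-unit interval, 0-based half-open on the haplotype
    end: int
    strand: str
    group: str


@dataclass
class LocusHaplotype:
    sample: str
    haplotype: int  # 1 or 2
    population: str
    cluster: int
    sequence: str
    copies: list[ParalogCopy]

    @property
    def name(self) -> str:
        return f"{self.sample}_h{self.haplotype}_c{self.cluster}"

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass
class TruthSet:
    """Machine-readable truth accompanying a simulated dataset.

    Only the tables relevant to the generating operation are populated.
    """

    copies: pd.DataFrame | None = None       # per paralog copy interval
    copy_number: pd.DataFrame | None = None  # per haplotype copy count
    read_groups: pd.DataFrame | None = None  # FLNC read -> source group
    breakpoints: list[int] | None = None
    orf_effect: dict | None = None
    config_json: str | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.copies is not None:
            bed = self.copies[["haplotype_name", "start", "end",
                               "group", "strand"]]
            bed.to_csv(outdir / "truth_copies.bed", sep="\t",
                       header=False, index=False)
            self.copies.to_csv(outdir / "truth_copies.tsv", sep="\t",
                               index=False)
        if self.copy_number is not None:
            self.copy_number.to_csv(outdir / "truth_copy_number.tsv",
                                    sep="\t", index=False)
        if self.read_groups is not None:
            self.read_groups.to_csv(outdir / "truth_read_groups.tsv",
                                    sep="\t", index=False)
        if self.breakpoints is not None:
            with open(outdir / "truth_breakpoints.tsv", "w") as fh:
                for pos in self.breakpoints:
                    fh.write(f"{pos}\n")
        if self.orf_effect is not None:
            (outdir / "truth_orf_effect.json").write_text(
                json.dumps(self.orf_effect, indent=2))
        if self.config_json is not None:
            (outdir / "config.json").write_text(self.config_json)

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthSet":
        outdir = Path(outdir)
        ts = cls()
        if (outdir / "truth_copies.tsv").exists():
            ts.copies = pd.read_csv(outdir / "truth_copies.tsv", sep="\t")
        if (outdir / "truth_copy_number.tsv").exists():
            ts.copy_number = pd.read_csv(
                outdir / "truth_copy_number.tsv", sep="\t")
        if (outdir / "truth_read_groups.tsv").exists():
            ts.read_groups = pd.read_csv(
                outdir / "truth_read_groups.tsv", sep="\t")
        if (outdir / "truth_breakpoints.tsv").exists():
            txt = (outdir / "truth_breakpoints.tsv").read_text().split()
            ts.breakpoints = [int(x) for x in txt]
        if (outdir / "truth_orf_effect.json").exists():
            ts.orf_effect = json.loads(
                (outdir / "truth_orf_effect.json").read_text())
        if (outdir / "config.json").exists():
            ts.config_json = (outdir / "config.json").read_text()
        return ts


def _clamped_nb_mean(raw_mean: float, pop: PopulationSpec) -> float:
    """Expectation of a NB(raw_mean, dispersion) draw clamped to the pop's
    copy-number bounds."""
    theta = pop.cn_dispersion
    p = theta / (theta + raw_mean)
    k = np.arange(0, pop.cn_max + 1)
    pmf = nbinom.pmf(k, theta, p)
    clamped = np.clip(k, pop.cn_min, pop.cn_max)
    tail = 1.0 - pmf.sum()  # mass above cn_max, clamped down to cn_max
    return float((clamped * pmf).sum() + tail * pop.cn_max)


def _raw_nb_mean(pop: PopulationSpec) -> float:
    """Raw NB mean whose clamped expectation equals the configured mean.

    Clamping to [cn_min, cn_max] shifts the mean of the raw distribution;
    the generator honors ``cn_mean`` as the mean of the *delivered* copy
    numbers, solved by bisection.
    """
    if pop.cn_min == pop.cn_max:
        return float(pop.cn_min)  # point mass: clamp decides everything
    lo, hi = 1e-3, 10.0 * pop.cn_max
    eps = 1e-9
    if not (_clamped_nb_mean(lo, pop) - eps <= pop.cn_mean
            <= _clamped_nb_mean(hi, pop) + eps):
        raise ConfigurationError(
            f"population {pop.name}: cn_mean {pop.cn_mean} not achievable "
            f"within [{pop.cn_min}, {pop.cn_max}]")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _clamped_nb_mean(mid, pop) < pop.cn_mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def draw_copy_number(pop: PopulationSpec, rng: np.random.Generator) -> int:
    """One clamped, mean-corrected negative-binomial copy-number draw."""
    theta = pop.cn_dispersion
    m = _raw_nb_mean(pop)
    p = theta / (theta + m)
    value = int(rng.negative_binomial(theta, p))
    return int(min(max(value, pop.cn_min), pop.cn_max))


def stratified_copy_numbers(
    pop: PopulationSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` clamped NB draws by stratified inverse-CDF sampling.

    One uniform is jittered inside each of ``n`` equal quantile strata and
    the set is shuffled, so the empirical distribution (and in particular
    the mean) tracks the nominal clamped distribution far more closely than
    iid draws while individual values keep the full spread.
    """
    theta = pop.cn_dispersion
    m = _raw_nb_mean(pop)
    p = theta / (theta + m)
    u = (np.arange(n) + rng.random(n)) / n
    values = nbinom.ppf(u, theta, p)
    values = np.clip(values, pop.cn_min, pop.cn_max).astype(int)
    return rng.permutation(values)


@dataclass
class _ClusterAncestry:
    """Shared ancestral sequences of one duplication cluster."""

    flank_left: np.ndarray
    flank_right: np.ndarray
    group_cassettes: dict[str, np.ndarray]
    unit_ancestor: np.ndarray  # un-mutated ancestral cassette (gene + spacer)


def _make_ancestry(config: SimConfig, cluster: int,
                   rng: np.random.Generator) -> _ClusterAncestry:
    cassette = _seq.random_seq(rng, config.cassette_length_bp)
    groups = {}
    for g in range(config.n_paralog_groups):
        name = f"c{cluster}_G{g + 1}"
        groups[name] = _seq.mutate(cassette, config.paralog_snv_rate / 2, rng)
    return _ClusterAncestry(
        flank_left=_seq.random_seq(rng, config.flank_length_bp),
        flank_right=_seq.random_seq(rng, config.flank_length_bp),
        group_cassettes=groups,
        unit_ancestor=cassette,
    )


def make_population(
    config: SimConfig,
) -> tuple[list[LocusHaplotype], TruthSet]:
    """Simulate a diploid cohort of duplication-cluster haplotypes.

    Returns two haplotypes per sample per cluster, with copy counts drawn
    from each population's clamped negative binomial, and a TruthSet holding
    the per-copy intervals/groups and per-haplotype copy numbers.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ancestries = {c: _make_ancestry(config, c, rng)
                  for c in range(1, config.n_clusters + 1)}
    group_names = {c: list(a.group_cassettes) for c, a in ancestries.items()}

    haplotypes: list[LocusHaplotype] = []
    copy_rows, cn_rows = [], []
    for pop in config.populations:
        if config.stratified_cn:
            draws = iter(stratified_copy_numbers(
                pop, config.n_samples * 2 * config.n_clusters, rng))
        else:
            draws = None
        for i in range(config.n_samples):
            sample = f"{pop.name}_s{i:03d}"
            for hap in (1, 2):
                for cluster in range(1, config.n_clusters + 1):
                    anc = ancestries[cluster]
                    k = (int(next(draws)) if draws is not None
                         else draw_copy_number(pop, rng))
                    parts = [anc.flank_left]
                    copies = []
                    pos = config.flank_length_bp
                    for _ in range(k):
                        group = group_names[cluster][
                            rng.integers(0, config.n_paralog_groups)]
                        copy = _seq.mutate(anc.group_cassettes[group],
                                           config.allelic_snv_rate / 2, rng)
                        parts.append(copy)
                        copies.append(ParalogCopy(
                            start=pos,
                            end=pos + config.unit_gene_length_bp,
                            strand="+", group=group))
                        pos += config.cassette_length_bp
                    parts.append(anc.flank_right)
                    hap_obj = LocusHaplotype(
                        sample=sample, haplotype=hap, population=pop.name,
                        cluster=cluster,
                        sequence=_seq.decode(np.concatenate(parts)),
                        copies=copies)
                    haplotypes.append(hap_obj)
                    cn_rows.append(dict(
                        sample=sample, haplotype=hap, population=pop.name,
                        cluster=cluster, n_copies=k))
                    for j, cp in enumerate(copies):
                        copy_rows.append(dict(
                            haplotype_name=hap_obj.name, sample=sample,
                            haplotype=hap, population=pop.name,
                            cluster=cluster, copy_index=j, start=cp.start,
                            end=cp.end, strand=cp.strand, group=cp.group))
    truth = TruthSet(
        copies=pd.DataFrame(copy_rows),
        copy_number=pd.DataFrame(cn_rows),
        config_json=config.to_json(),
    )
    return haplotypes, truth


# ---------------------------------------------------------------------------
# truth-derived pairwise alignments and structural equivalence


def cluster_geometry(config: SimConfig) -> tuple[int, int]:
    """(flank_length, cassette_length) — haplotype layout constants."""
    return config.flank_length_bp, config.cassette_length_bp


def truth_pair_alignment(
    a: LocusHaplotype, b: LocusHaplotype, config: SimConfig
) -> PafRecord:
    """The true pairwise alignment between two same-cluster haplotypes.

    Haplotypes share flanks and differ structurally only in cassette count,
    so the true alignment matches the left flank plus the shared cassettes,
    carries one insertion/deletion of the surplus cassettes, and matches the
    right flank. Mismatch-level detail is irrelevant to structural coverage
    and is summarized by M operations.
    """
    if a.cluster != b.cluster:
        raise ValueError("haplotypes belong to different clusters")
    flank, cas = cluster_geometry(config)
    ka, kb = a.n_copies, b.n_copies
    kmin = min(ka, kb)
    la, lb = len(a.sequence), len(b.sequence)
    ops: list[tuple[int, str]] = [(flank + kmin * cas, "M")]
    if ka > kb:
        ops.append(((ka - kb) * cas, "I"))
    elif kb > ka:
        ops.append(((kb - ka) * cas, "D"))
    ops.append((flank, "M"))
    cg = "".join(f"{n}{op}" for n, op in ops)
    aligned = sum(n for n, op in ops if op == "M")
    rec = PafRecord(
        qname=a.name, qlen=la, qstart=0, qend=la, strand="+",
        tname=b.name, tlen=lb, tstart=0, tend=lb,
        matches=aligned, block_len=sum(n for n, _ in ops),
        tags={"cg": cg},
    )
    rec.validate()
    return rec


def truth_coverage(
    a: LocusHaplotype, b: LocusHaplotype, config: SimConfig
) -> tuple[float, float]:
    """Closed-form best single-alignment coverage for a truth pair.

    Independent of cigar parsing: computed directly from the haplotype
    geometry. With equal cassette counts the single alignment is full
    length; otherwise the surplus-cassette indel splits it into
    [flank + shared cassettes] and [flank] pieces, of which the first is
    always the larger.
    """
    flank, cas = cluster_geometry(config)
    if a.n_copies == b.n_copies:
        return 1.0, 1.0
    piece = flank + min(a.n_copies, b.n_copies) * cas
    return piece / len(a.sequence), piece / len(b.sequence)


def truth_equivalent(
    a: LocusHaplotype, b: LocusHaplotype, config: SimConfig,
    threshold: float = 0.90,
) -> bool:
    fa, fb = truth_coverage(a, b, config)
    return min(fa, fb) >= threshold


# ---------------------------------------------------------------------------
# rearranged chromosome pairs


@dataclass
class RearrangementEvent:
    kind: str  # "inversion" | "translocation"
    start: int
    end: int
    mid: int | None = None  # pivot of a translocation (segment swap)

    @property
    def breakpoints(self) -> list[int]:
        if self.kind == "translocation" and self.mid is not None:
            return [self.start, self.mid, self.end]
        return [self.start, self.end]


@dataclass
class RearrangedChromosome:
    ref_seq: str
    alt_seq: str
    events: list[RearrangementEvent]
    breakpoints: list[int]                  # on the reference chromosome
    duplication_intervals: list[tuple[int, int]]
    alignments: list[PafRecord]             # alt (query) -> ref (target)
    truth: TruthSet


def _place_events(
    base_length: int, n_events: int, rng: np.random.Generator,
    event_min: int, event_max: int,
) -> list[tuple[int, int]]:
    """Non-overlapping event intervals, uniform placement by rejection."""
    placed: list[tuple[int, int]] = []
    for _ in range(n_events):
        for _try in range(1000):
            size = int(rng.integers(event_min, event_max + 1))
            if size >= base_length:
                raise GenerationError("event larger than chromosome")
            start = int(rng.integers(0, base_length - size))
            iv = (start, start + size)
            # keep a buffer so distinct events never share a breakpoint
            if all(iv[1] + 1 < s or e + 1 < iv[0] for s, e in placed):
                placed.append(iv)
                break
        else:
            raise GenerationError(
                f"could not place {n_events} non-overlapping events of "
                f"{event_min}-{event_max} bp in {base_length} bp")
    return sorted(placed)


def _fragment(total_q: int, total_t: int, strand: str, q0: int, t0: int,
              qlen: int, tlen: int, tname: str, qname: str,
              piece: int) -> list[PafRecord]:
    """Split one colinear segment into sub-alignment PAF records."""
    assert total_q == total_t
    recs = []
    n_pieces = max(1, -(-total_q // piece))
    bounds = np.linspace(0, total_q, n_pieces + 1).astype(int)
    for off, nxt in zip(bounds[:-1], bounds[1:]):
        off, n = int(off), int(nxt - off)
        if strand == "+":
            qs = q0 + off
        else:
            qs = q0 + (total_q - off - n)
        rec = PafRecord(
            qname=qname, qlen=qlen, qstart=qs, qend=qs + n, strand=strand,
            tname=tname, tlen=tlen, tstart=t0 + off, tend=t0 + off + n,
            matches=n, block_len=n, tags={"cg": f"{n}M"},
        )
        rec.validate()
        recs.append(rec)
    return recs


def make_rearranged_chromosome(
    base_length_bp: int,
    n_events: int,
    anchor_at_copies: bool,
    config: SimConfig,
    event_min_bp: int = 1_000_000,
    event_max_bp: int = 3_000_000,
    n_duplications: int | None = None,
    fragment_bp: int = 400_000,
) -> RearrangedChromosome:
    """Simulate a chromosome pair differing by large-scale rearrangements.

    The alternate chromosome differs from the reference by ``n_events``
    non-overlapping inversions and translocations (adjacent-segment swaps);
    truth breakpoints are the event boundaries on the reference. Duplication
    (gene-cassette) intervals are placed either at each breakpoint
    (``anchor_at_copies``) or uniformly at random, and the true colinear
    alignment set between the two chromosomes is emitted as fragmented PAF
    records ready for synteny chaining.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if n_events > 0 and base_length_bp < n_events * (event_min_bp + 2):
        raise GenerationError("events cannot fit inside the chromosome")
    intervals = _place_events(base_length_bp, n_events, rng,
                              event_min_bp, event_max_bp)
    events = []
    for s, e in intervals:
        if rng.random() < 0.5:
            events.append(RearrangementEvent("inversion", s, e))
        else:
            mid = int((s + e) // 2)
            events.append(RearrangementEvent("translocation", s, e, mid))

    ref = _seq.random_seq(rng, base_length_bp)
    alt = ref.copy()
    for ev in events:
        if ev.kind == "inversion":
            alt[ev.start:ev.end] = (3 - ref[ev.start:ev.end])[::-1]
        else:
            a = ref[ev.start:ev.mid]
            b = ref[ev.mid:ev.end]
            alt[ev.start:ev.start + b.size] = b
            alt[ev.start + b.size:ev.end] = a

    breakpoints = sorted({bp for ev in events for bp in ev.breakpoints})

    # duplication cassettes: one per breakpoint when anchored, else random
    unit = config.unit_gene_length_bp
    dup_intervals: list[tuple[int, int]] = []
    if anchor_at_copies:
        for bp in breakpoints:
            start = min(bp, base_length_bp - unit)
            dup_intervals.append((start, start + unit))
    else:
        n_dup = n_duplications if n_duplications is not None else max(
            len(breakpoints), 1)
        for _ in range(n_dup):
            start = int(rng.integers(0, base_length_bp - unit))
            dup_intervals.append((start, start + unit))
        dup_intervals.sort()

    # truth alignments: colinear runs between/within events
    qlen = tlen = base_length_bp
    recs: list[PafRecord] = []
    cursor = 0
    segments: list[tuple[int, int, int, str]] = []  # (tstart, tend, qstart, strand)
    for ev in events:
        if cursor < ev.start:
            segments.append((cursor, ev.start, cursor, "+"))
        if ev.kind == "inversion":
            segments.append((ev.start, ev.end, ev.start, "-"))
        else:
            la = ev.mid - ev.start
            lb = ev.end - ev.mid
            # ref [start,mid) now sits at alt [start+lb, end)
            segments.append((ev.start, ev.mid, ev.start + lb, "+"))
            segments.append((ev.mid, ev.end, ev.start, "+"))
        cursor = ev.end
    if cursor < base_length_bp:
        segments.append((cursor, base_length_bp, cursor, "+"))
    for ts, te, qs, strand in segments:
        recs.extend(_fragment(te - ts, te - ts, strand, qs, ts,
                              qlen, tlen, "ref", "alt", fragment_bp))

    truth = TruthSet(breakpoints=breakpoints, config_json=config.to_json())
    return RearrangedChromosome(
        ref_seq=_seq.decode(ref), alt_seq=_seq.decode(alt), events=events,
        breakpoints=breakpoints, duplication_intervals=dup_intervals,
        alignments=recs, truth=truth)


# ---------------------------------------------------------------------------
# shotgun reads


@dataclass
class SimulatedRead:
    id: str
    sequence: str
    source: str
    start: int  # truth placement on the source sequence


def simulate_reads(
    sequences: dict[str, str],
    depth: float,
    read_length_bp: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    stratified: bool = False,
) -> list[SimulatedRead]:
    """Uniform-coverage single-end reads with independent substitution errors.

    The read count per source sequence is ``round(len * depth / read_length)``
    with uniform start positions, so expected per-base coverage equals
    ``depth`` away from sequence ends. With ``stratified`` the starts are
    drawn one per equal-width stratum (jittered systematic sampling): the
    marginal distribution stays uniform but regional coverage is nearly
    noise-free, which isolates systematic error when validating depth-based
    estimators.
    """
    if depth <= 0:
        raise GenerationError("depth must be positive")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    for name, seq in sequences.items():
        arr = _seq.encode(seq)
        if read_length_bp > arr.size:
            raise GenerationError(
                f"read length {read_length_bp} exceeds sequence {name!r} "
                f"({arr.size} bp)")
        n_reads = int(round(arr.size * depth / read_length_bp))
        hi = arr.size - read_length_bp + 1
        if stratified:
            u = (np.arange(n_reads) + rng.random(n_reads)) / n_reads
            starts = np.floor(u * hi).astype(np.int64)
        else:
            starts = rng.integers(0, hi, size=n_reads)
        for i, start in enumerate(starts):
            read = arr[start:start + read_length_bp]
            if error_rate > 0:
                read = _seq.mutate(read, error_rate * 10_000.0, rng)
            reads.append(SimulatedRead(
                id=f"{name}_r{i:06d}", sequence=_seq.decode(read),
                source=name, start=int(start)))
    return reads


def write_fastq(reads: list[SimulatedRead], path: str | Path,
                quality: int = 30) -> None:
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n"
                     f"{qchar * len(read.sequence)}\n")


# ---------------------------------------------------------------------------
# FLNC transcript reads


@dataclass
class SimulatedFlnc:
    id: str
    sequence: str
    accuracy: float  # per-read predicted accuracy, FLNC-style
    group: str       # truth source paralog group


def simulate_flnc(
    transcripts_per_group: dict[str, tuple[str, int]],
    accuracy_range: tuple[float, float] = (0.9992, 1.0),
    length_jitter_bp: int = 0,
    frac_short: float = 0.0,
    frac_low_accuracy: float = 0.0,
    short_length_bp: int = 900,
    low_accuracy_range: tuple[float, float] = (0.990, 0.9985),
    seed: int = 0,
) -> tuple[list[SimulatedFlnc], TruthSet]:
    """FLNC reads drawn from per-group transcript templates.

    A configurable fraction of reads is deliberately generated short
    (< 1000 bp) or below the 99.9% accuracy floor so that downstream filters
    have true positives to reject; which reads violate which filter is recorded
    in the truth table.
    """
    if not transcripts_per_group:
        raise GenerationError("empty template map")
    for group, (tpl, _count) in transcripts_per_group.items():
        if len(tpl) < 300:
            raise GenerationError(f"template for {group} shorter than 300 bp")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedFlnc] = []
    rows = []
    idx = 0
    for group in sorted(transcripts_per_group):
        template, count = transcripts_per_group[group]
        arr = _seq.encode(template)
        for _ in range(count):
            short = rng.random() < frac_short
            lowacc = rng.random() < frac_low_accuracy
            lo, hi = low_accuracy_range if lowacc else accuracy_range
            accuracy = float(rng.uniform(lo, hi))
            seq = arr
            if length_jitter_bp > 0:
                trim = int(rng.integers(0, length_jitter_bp + 1))
                seq = seq[:max(300, arr.size - trim)]
            if short:
                seq = seq[:short_length_bp]
            seq = _seq.mutate(seq, (1.0 - accuracy) * 10_000.0, rng)
            rid = f"flnc_{idx:06d}"
            idx += 1
            reads.append(SimulatedFlnc(
                id=rid, sequence=_seq.decode(seq), accuracy=accuracy,
                group=group))
            rows.append(dict(read_id=rid, group=group,
                             violates_length=bool(short or seq.size < 1000),
                             violates_accuracy=bool(accuracy < 0.999)))
    truth = TruthSet(read_groups=pd.DataFrame(rows))
    return reads, truth


# ---------------------------------------------------------------------------
# engineered coding-sequence indels


@dataclass
class OrfEffect:
    """Ground-truth consequence of an engineered CDS deletion."""

    frameshift: bool
    residues_removed: int
    extension_length_aa: int
    deletion_start: int
    deletion_end: int

    def to_dict(self) -> dict:
        return asdict(self)


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def orf_effect_from_translation(
    cds: str, deletion_start: int, deletion_end: int, downstream: str
) -> OrfEffect:
    """Brute-force truth: translate the mutated sequence and compare proteins.

    ``residues_removed`` counts reference residues without a surviving
    counterpart before the original stop; for a frameshift every residue from
    the first affected codon onward is lost. ``extension_length_aa`` counts
    codons translated past the reference stop position (mapped into mutated
    coordinates) until the first in-frame stop.
    """
    indel_len = deletion_end - deletion_start
    stop_start = len(cds) - 3
    p_ref = str(Seq(cds[:stop_start]).translate())
    mutated = cds[:deletion_start] + cds[deletion_end:] + downstream
    mutated = mutated[: len(mutated) - len(mutated) % 3]
    p_mut = str(Seq(mutated).translate(to_stop=True))
    frameshift = (indel_len % 3) != 0
    pre = _common_prefix(p_ref, p_mut)
    if frameshift:
        removed = len(p_ref) - pre
    else:
        rest_ref, rest_mut = p_ref[pre:], p_mut[pre:]
        suf = _common_prefix(rest_ref[::-1], rest_mut[::-1])
        suf = min(suf, len(rest_mut))
        removed = len(p_ref) - pre - suf
    s_prime = stop_start - indel_len  # original stop in mutated coordinates
    extension = max(0, len(p_mut) - math.ceil(s_prime / 3))
    return OrfEffect(
        frameshift=frameshift, residues_removed=removed,
        extension_length_aa=extension,
        deletion_start=deletion_start, deletion_end=deletion_end)


def engineer_cds_indel(
    cds: str,
    indel_length_bp: int,
    offset_from_stop_bp: int,
    downstream: str = "",
) -> tuple[str, OrfEffect]:
    """Delete ``indel_length_bp`` bases ending ``offset_from_stop_bp`` before
    the stop codon and report the true ORF consequence.

    The returned transcript is the mutated CDS with ``downstream`` (3' UTR)
    appended, so frameshift extensions can run past the ancestral stop. Truth
    is computed by brute-force translation, not by arithmetic shortcuts.
    """
    if len(cds) % 3 != 0:
        raise GenerationError("CDS length not divisible by 3")
    if not cds.startswith("ATG"):
        raise GenerationError("CDS must begin with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise GenerationError("CDS must end with a stop codon")
    stop_start = len(cds) - 3
    deletion_end = stop_start - offset_from_stop_bp
    deletion_start = deletion_end - indel_length_bp
    if deletion_start < 3:
        raise GenerationError("deletion spans the start codon")
    if indel_length_bp < 1 or deletion_end > stop_start:
        raise GenerationError("deletion interval outside the coding sequence")
    effect = orf_effect_from_translation(
        cds, deletion_start, deletion_end, downstream)
    transcript = cds[:deletion_start] + cds[deletion_end:] + downstream
    return transcript, effect


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random CDS: ATG + internal non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = _seq.decode(_seq.random_seq(rng, 3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
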