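"""End-to-end pipeline over a synthetic duplication-family cohort.

Stages run in dependency order — simulate, qc, cn, structure, synteny,
group, express/orf — communicating through files in standard formats (FASTA,
PAF, BED, TSV, JSON) so any stage can be replaced by external tool output.
Every stage directory receives a provenance block (package version, config
hash, seed) and the run report collects per-stage status and headline
statistics. Defaults for the analysis thresholds are the published values;
cohort sizes default to desk-scale numbers chosen so a full run stays in the
minutes range on one CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, _seq
from . import depth as depth_mod
from . import phylo, qc, simulate, structure, synteny, transcripts
from .orf import orf_frameshift_report
from .paf import write_paf


@dataclass
class PipelineConfig:
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_qc: bool = True
    run_cn: bool = True
    run_structure: bool = True
    run_synteny: bool = True
    run_group: bool = True
    run_express: bool = True
    # cohort geometry (desk-scale defaults)
    n_samples: int = 5
    populations: list[dict] = field(default_factory=lambda: [
        {"name": "AFR", "cn_mean": 8.6},
        {"name": "NONAFR", "cn_mean": 6.35},
    ])
    n_clusters: int = 2
    n_paralog_groups: int = 3
    cassette_length_bp: int = 40_000
    unit_gene_length_bp: int = 11_000
    flank_length_bp: int = 10_000
    allelic_snv_rate: float = 15.3
    paralog_snv_rate: float = 60.0
    read_depth: float = 30.0
    read_error_rate: float = 0.001
    read_length_bp: int = 150
    #: long-read length for the self-mapping QC stage; HiFi-scale reads span
    #: discriminating SNVs between near-identical copies, so placement is
    #: essentially unambiguous
    qc_read_length_bp: int = 10_000
    inject_collapse: bool = False
    # analysis thresholds (published defaults)
    coverage_threshold: float = 0.90
    max_insertion_bp: int = 1000
    kmer_k: int = 32
    min_match_bp: int = 6000
    max_gap: int = 200_000
    min_block_size: int = 1_000_000
    min_subblock_size: int = 50_000
    n_perm: int = 5000
    perm_block_length_bp: int = 11_000
    grouping_multiplier: float = 1.5
    min_group_size: int = 10
    flnc_min_length: int = 1000
    flnc_min_accuracy: float = 0.999
    score_margin: float = 10.0
    isoform_min_reads: int = 3
    anchor_slop_bp: int = 100
    calibration_mya: float = 6.5
    # synteny simulation geometry
    chrom_length_bp: int = 8_000_000
    n_rearrangements: int = 2

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            seed=self.seed,
            n_samples=self.n_samples,
            populations=[simulate.PopulationSpec(**p)
                         for p in self.populations],
            n_clusters=self.n_clusters,
            n_paralog_groups=self.n_paralog_groups,
            cassette_length_bp=self.cassette_length_bp,
            unit_gene_length_bp=self.unit_gene_length_bp,
            flank_length_bp=self.flank_length_bp,
            allelic_snv_rate=self.allelic_snv_rate,
            paralog_snv_rate=self.paralog_snv_rate,
            read_depth=self.read_depth,
            read_error_rate=self.read_error_rate,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def _provenance(config: PipelineConfig) -> dict:
    return {"version": __version__, "config_hash": config.config_hash(),
            "seed": config.seed}


def _write_stage(outdir: Path, name: str, payload: dict,
                 config: PipelineConfig) -> None:
    stage_dir = outdir / name
    stage_dir.mkdir(parents=True, exist_ok=True)
    payload = dict(payload)
    payload["provenance"] = _provenance(config)
    (stage_dir / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True))


def _copy_unit(hap: simulate.LocusHaplotype, index: int = 0) -> str:
    cp = hap.copies[index]
    return hap.sequence[cp.start:cp.end]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all enabled stages; returns (and writes) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "provenance": _provenance(config)}

    if not config.run_simulate:
        raise PipelineError("pipeline requires the simulate stage as input "
                            "source in this build")

    # ---- simulate -------------------------------------------------------
    sim_cfg = config.sim_config()
    haplotypes, truth = simulate.make_population(sim_cfg)
    truth.write(outdir / "simulate")
    simulate.write_fasta(
        {h.name: h.sequence for h in haplotypes[:4]},
        outdir / "simulate" / "haplotypes_head.fasta")
    report["stages"]["simulate"] = {
        "status": "ok",
        "n_haplotypes": len(haplotypes),
        "n_copies_total": int(truth.copy_number["n_copies"].sum()),
    }
    _write_stage(outdir, "simulate", report["stages"]["simulate"], config)

    excluded: set[str] = set()

    # ---- qc -------------------------------------------------------------
    if config.run_qc:
        qc_stats = {}
        subjects = haplotypes[:2]
        for i, hap in enumerate(subjects):
            assembly = hap.sequence
            sources = {hap.name: hap.sequence}
            if config.inject_collapse and i == 0 and hap.n_copies >= 2:
                # reads come from the true two-copy locus, the assembly
                # lost one copy: classic collapse signal
                cp = hap.copies[-1]
                cas_start = cp.start
                assembly = (hap.sequence[:cas_start]
                            + hap.sequence[cp.start + config.cassette_length_bp:])
            reads = simulate.simulate_reads(
                sources, depth=config.read_depth,
                read_length_bp=config.qc_read_length_bp,
                error_rate=config.read_error_rate,
                seed=config.seed + 1000 + i)
            placements = qc.map_reads_ungapped(
                [r.sequence for r in reads], assembly)
            profile = qc.depth_profile(placements, len(assembly),
                                       name=hap.name)
            flags = qc.flag_regions(profile, expected_depth=config.read_depth)
            if flags:
                excluded.add(hap.name)
            qc_stats[hap.name] = {
                "n_reads": len(reads), "n_placed": len(placements),
                "n_flags": len(flags),
                "flags": [asdict(f) for f in flags],
                "passed": qc.passes_qc(flags),
            }
        report["stages"]["qc"] = {
            "status": "ok", "haplotypes": qc_stats,
            "excluded": sorted(excluded),
        }
        _write_stage(outdir, "qc", report["stages"]["qc"], config)

    kept = [h for h in haplotypes if h.name not in excluded]

    # ---- cn -------------------------------------------------------------
    if config.run_cn:
        estimates = []
        samples = sorted({h.sample for h in kept})[:3]
        for si, sample in enumerate(samples):
            haps = [h for h in kept
                    if h.sample == sample and h.cluster == 1]
            if not haps or not haps[0].copies:
                continue
            probe = _copy_unit(haps[0])
            control = haps[0].sequence[:config.flank_length_bp]
            reference = probe + control
            reads = []
            for h in haps:
                reads += [r.sequence for r in simulate.simulate_reads(
                    {h.name: h.sequence}, depth=config.read_depth / 2,
                    read_length_bp=config.read_length_bp,
                    error_rate=config.read_error_rate,
                    seed=config.seed + 2000 + si * 10 + h.haplotype)]
            model = depth_mod.KmerCNModel(
                k=config.kmer_k, reference_name=f"{sample}_probe",
                gene_window=(0, len(probe)),
                control_regions=[(len(probe), len(reference))])
            model.fit(reads, reference)
            read_cn = depth_mod.estimate_cn(model, ploidy=len(haps))
            asm_cn = depth_mod.assembly_cn(
                haps, probe, min_match_bp=config.min_match_bp,
                k=config.kmer_k)
            estimates.append(depth_mod.CopyNumberEstimate(
                sample=sample, read_cn=read_cn, assembly_cn=asm_cn,
                window=(0, len(probe))))
        stage = {"status": "ok",
                 "estimates": [asdict(e) for e in estimates]}
        if len(estimates) >= 3:
            stage["concordance"] = depth_mod.cn_concordance(estimates)
        pd.DataFrame([asdict(e) for e in estimates]).to_csv(
            outdir / "cn_estimates.tsv", sep="\t", index=False)
        report["stages"]["cn"] = stage
        _write_stage(outdir, "cn", stage, config)

    # ---- structure ------------------------------------------------------
    if config.run_structure:
        stage = {"status": "ok", "clusters": {}}
        for cluster in range(1, config.n_clusters + 1):
            haps = [h for h in kept if h.cluster == cluster]
            names = [h.name for h in haps]
            recs = []
            for i in range(len(haps)):
                for j in range(i + 1, len(haps)):
                    recs.append(simulate.truth_pair_alignment(
                        haps[i], haps[j], sim_cfg))
            write_paf(recs, outdir / f"structure_cluster{cluster}.paf")
            mat = structure.equivalence_matrix(
                names, recs, threshold=config.coverage_threshold,
                max_insertion_bp=config.max_insertion_bp)
            samples = {}
            for h in haps:
                samples.setdefault(h.sample, []).append(h.name)
            het = structure.structural_heterozygosity(
                {s: tuple(v) for s, v in samples.items()
                 if len(v) == 2}, mat)
            stage["clusters"][str(cluster)] = {
                "distinctness_fraction": structure.distinctness_fraction(mat),
                "structural_heterozygosity": het,
                "n_haplotypes": len(names),
            }
        totals = structure.diploid_totals(truth.copy_number)
        stage["population_cn"] = structure.population_cn_compare(totals)
        report["stages"]["structure"] = stage
        _write_stage(outdir, "structure", stage, config)

    # ---- synteny --------------------------------------------------------
    if config.run_synteny:
        rearr = simulate.make_rearranged_chromosome(
            base_length_bp=config.chrom_length_bp,
            n_events=config.n_rearrangements,
            anchor_at_copies=True, config=sim_cfg,
            event_min_bp=config.chrom_length_bp // 10,
            event_max_bp=config.chrom_length_bp // 5)
        params = synteny.SyntenyParams(
            max_gap=config.max_gap,
            min_block_size=config.min_block_size,
            min_subblock_size=config.min_subblock_size)
        blocks = synteny.chain_synteny(rearr.alignments, params)
        breaks = synteny.breakpoints(blocks, config.chrom_length_bp)
        perm = synteny.permutation_test(
            rearr.duplication_intervals, breaks, config.chrom_length_bp,
            n_perm=config.n_perm,
            block_length=config.perm_block_length_bp,
            seed=config.seed + 3000)
        stage = {"status": "ok",
                 "n_blocks": len(blocks),
                 "n_breakpoints": int(breaks.size),
                 "truth_breakpoints": rearr.breakpoints,
                 "permutation": perm.to_dict()}
        report["stages"]["synteny"] = stage
        _write_stage(outdir, "synteny", stage, config)

    # ---- group ----------------------------------------------------------
    if config.run_group:
        cluster1 = [h for h in kept if h.cluster == 1]
        alignment: dict[str, str] = {}
        truth_labels: dict[str, str] = {}
        for h in cluster1:
            for idx, cp in enumerate(h.copies):
                name = f"{h.name}_p{idx}"
                # whole cassette, not just the gene unit: longer sequence
                # tightens the max-pairwise distance statistic
                alignment[name] = h.sequence[
                    cp.start:cp.start + config.cassette_length_bp]
                truth_labels[name] = cp.group
                if len(alignment) >= 60:
                    break
            if len(alignment) >= 60:
                break
        rng = np.random.default_rng(config.seed + 4000)
        first = next(iter(alignment.values()))
        outgroup_seq = _seq.decode(_seq.mutate(
            _seq.encode(first), 150.0, rng))
        alignment["outgroup"] = outgroup_seq
        dm = phylo.distance_matrix(alignment)
        tree = phylo.nj_tree(dm, outgroup="outgroup")
        params = phylo.GroupingParams(
            allelic_rate=config.allelic_snv_rate,
            multiplier=config.grouping_multiplier,
            min_group_size=config.min_group_size)
        groups = phylo.clade_groups(tree, dm, params, outgroup="outgroup")
        partition = phylo.group_partition(groups)
        # strict-clock age of the family expansion, calibrated on the
        # outgroup divergence
        ingroup = [n for n in alignment if n != "outgroup"]
        out_div = float(np.mean([dm[n, "outgroup"] for n in ingroup]))
        in_div = max(
            (g.max_intra_distance for g in groups), default=0.0)
        inter = max(dm.filter(ingroup).data.max(), in_div)
        age = phylo.clock_date(inter, out_div, config.calibration_mya)
        pd.DataFrame(
            [{"leaf": leaf, "group": grp}
             for leaf, grp in sorted(partition.items())]).to_csv(
            outdir / "paralog_groups.tsv", sep="\t", index=False)
        tree.write(str(outdir / "paralogs.nwk"))
        stage = {"status": "ok",
                 "n_leaves": len(ingroup),
                 "n_groups": len(groups),
                 "n_population_level": sum(
                     1 for g in groups if g.is_population_level),
                 "expansion_age_mya": age}
        report["stages"]["group"] = stage
        _write_stage(outdir, "group", stage, config)

    # ---- express / orf --------------------------------------------------
    if config.run_express:
        hap0 = next(h for h in kept if h.cluster == 1 and len(
            {c.group for c in h.copies}) >= 2)
        by_group: dict[str, str] = {}
        for idx, cp in enumerate(hap0.copies):
            by_group.setdefault(cp.group, hap0.sequence[cp.start:cp.start
                                                        + 1500])
        groups = sorted(by_group)[:2]
        counts = {groups[0]: 90, groups[1]: 10}
        flnc, flnc_truth = simulate.simulate_flnc(
            {g: (by_group[g], counts[g]) for g in groups},
            frac_short=0.05, frac_low_accuracy=0.05,
            seed=config.seed + 5000)
        reads = [transcripts.FlncRead(r.id, r.sequence, r.accuracy)
                 for r in flnc]
        kept_reads, dropped = transcripts.filter_flnc(
            reads, config.flnc_min_length, config.flnc_min_accuracy)
        alns = transcripts.align_to_copies(
            kept_reads, {g: by_group[g] for g in groups})
        assignments = transcripts.assign_reads(
            alns, {g: g for g in groups},
            score_margin=config.score_margin,
            read_ids=[r.id for r in kept_reads])
        copy_table = (truth.copies[truth.copies.group.isin(groups)]
                      .groupby(["group", "haplotype_name"]).size()
                      .unstack(fill_value=0))
        summary = transcripts.expression_summary(assignments, copy_table)
        truth_map = dict(zip(flnc_truth.read_groups.read_id,
                             flnc_truth.read_groups.group))
        correct = sum(1 for a in assignments
                      if a.status == transcripts.ASSIGNED
                      and truth_map[a.read_id] == a.group)
        n_assigned = sum(1 for a in assignments
                         if a.status == transcripts.ASSIGNED)

        # ORF stage: engineered frameshift deletion on a synthetic CDS
        rng = np.random.default_rng(config.seed + 6000)
        cds = simulate.random_cds(rng, 200)
        utr = _seq.decode(_seq.random_seq(rng, 300))
        transcript, effect = simulate.engineer_cds_indel(
            cds, indel_length_bp=43, offset_from_stop_bp=9, downstream=utr)
        orf_report = orf_frameshift_report(transcript, cds,
                                           config.anchor_slop_bp)
        stage = {
            "status": "ok",
            "n_reads": len(reads),
            "n_filtered": len(dropped),
            "n_assigned": n_assigned,
            "n_ambiguous": sum(1 for a in assignments
                               if a.status == transcripts.AMBIGUOUS),
            "assignment_accuracy": (correct / n_assigned
                                    if n_assigned else None),
            "expression": summary.to_dict(),
            "orf": {"report": asdict(orf_report),
                    "truth": effect.to_dict(),
                    "agrees": (orf_report.frameshift == effect.frameshift
                               and orf_report.residues_removed
                               == effect.residues_removed
                               and orf_report.extension_length_aa
                               == effect.extension_length_aa)},
        }
        report["stages"]["express"] = stage
        _write_stage(outdir, "express", stage, config)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
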