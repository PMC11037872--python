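"""Generator correctness: truth bookkeeping, rates, determinism."""

import numpy as np
import pytest

from sdfam import _seq, simulate
from sdfam.simulate import (
    ConfigurationError,
    GenerationError,
    PopulationSpec,
    SimConfig,
)


def _point_mass_config(copies: int) -> SimConfig:
    return SimConfig(
        seed=3, n_samples=2,
        populations=[PopulationSpec("P", cn_mean=copies,
                                    cn_min=copies, cn_max=copies)],
        n_clusters=1, n_paralog_groups=2,
        cassette_length_bp=3000, unit_gene_length_bp=1500,
        flank_length_bp=1000)


class TestMakePopulation:
    def test_point_mass_distribution_gives_exact_copy_counts(self):
        haps, truth = simulate.make_population(_point_mass_config(3))
        assert all(h.n_copies == 3 for h in haps)
        assert (truth.copy_number["n_copies"] == 3).all()

    def test_seeded_rerun_is_byte_identical(self, small_config):
        haps1, truth1 = simulate.make_population(small_config)
        haps2, truth2 = simulate.make_population(small_config)
        assert [h.sequence for h in haps1] == [h.sequence for h in haps2]
        assert truth1.copy_number.equals(truth2.copy_number)

    def test_two_haplotypes_per_sample_per_cluster(self, small_cohort):
        haps, truth = small_cohort
        counts = truth.copy_number.groupby(["sample", "cluster"]).size()
        assert (counts == 2).all()

    def test_truth_intervals_lie_within_sequences(self, small_cohort):
        haps, _ = small_cohort
        for h in haps:
            for cp in h.copies:
                assert 0 <= cp.start < cp.end <= len(h.sequence)

    def test_invalid_distribution_rejected(self):
        cfg = SimConfig(populations=[PopulationSpec("P", cn_mean=-1)])
        with pytest.raises(ConfigurationError):
            simulate.make_population(cfg)

    def test_unachievable_mean_rejected(self):
        pop = PopulationSpec("P", cn_mean=14.5, cn_max=14)
        with pytest.raises(ConfigurationError):
            simulate._raw_nb_mean(pop)

    def test_population_mean_difference_recovered(self):
        """Monte-Carlo check of the generator's own truth: diploid group
        means land within +-1.0 copy of the configured 34.4 vs 25.4."""
        cfg = SimConfig(
            seed=17, n_samples=30,
            populations=[PopulationSpec("AFR", 8.6),
                         PopulationSpec("NONAFR", 6.35)],
            n_clusters=2, n_paralog_groups=2,
            cassette_length_bp=2000, unit_gene_length_bp=1000,
            flank_length_bp=800)
        _, truth = simulate.make_population(cfg)
        diploid = truth.copy_number.groupby(
            ["sample", "population"])["n_copies"].sum().reset_index()
        means = diploid.groupby("population")["n_copies"].mean()
        assert abs(means["AFR"] - 34.4) <= 1.0
        assert abs(means["NONAFR"] - 25.4) <= 1.0


class TestSnvRates:
    def test_within_and_between_group_distances(self, rng):
        """Within-group pairwise distance tracks allelic_snv_rate within
        10%; between-group distance clears 1.5 x 15.3 for paralog rates
        >= 30 SNVs/10 kbp."""
        cfg = SimConfig(
            seed=5, n_samples=6,
            populations=[PopulationSpec("P", 4.0)],
            n_clusters=1, n_paralog_groups=2,
            cassette_length_bp=12000, unit_gene_length_bp=10000,
            flank_length_bp=1000, paralog_snv_rate=30.0)
        haps, truth = simulate.make_population(cfg)
        units, groups = [], []
        for h in haps:
            for cp in h.copies:
                units.append(_seq.encode(h.sequence[cp.start:cp.end]))
                groups.append(cp.group)
        within, between = [], []
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                d = _seq.hamming(units[i], units[j]) / len(units[i]) * 1e4
                (within if groups[i] == groups[j] else between).append(d)
        assert abs(np.mean(within) - cfg.allelic_snv_rate) \
            <= 0.1 * cfg.allelic_snv_rate
        assert np.mean(between) > 1.5 * 15.3

    def test_truth_roundtrip(self, small_cohort, tmp_path):
        _, truth = small_cohort
        truth.write(tmp_path)
        back = simulate.TruthSet.read(tmp_path)
        assert back.copy_number.equals(truth.copy_number)
        assert back.copies.equals(truth.copies)


class TestRearrangedChromosome:
    CFG = SimConfig(seed=9, n_samples=1, unit_gene_length_bp=5000)

    def test_zero_events_identical(self):
        r = simulate.make_rearranged_chromosome(
            500_000, 0, False, self.CFG)
        assert r.ref_seq == r.alt_seq
        assert r.breakpoints == []

    def test_single_inversion_two_breakpoints(self):
        r = simulate.make_rearranged_chromosome(
            4_000_000, 1, False, self.CFG,
            event_min_bp=1_000_000, event_max_bp=1_200_000)
        if r.events[0].kind == "inversion":
            assert len(r.breakpoints) == 2
        else:
            assert len(r.breakpoints) == 3
        ev = r.events[0]
        seg = r.alt_seq[ev.start:ev.end]
        assert r.alt_seq != r.ref_seq
        if ev.kind == "inversion":
            assert seg == _seq.revcomp(r.ref_seq[ev.start:ev.end])

    def test_anchored_duplications_touch_breakpoints(self):
        r = simulate.make_rearranged_chromosome(
            6_000_000, 2, True, self.CFG,
            event_min_bp=800_000, event_max_bp=1_200_000)
        for bp in r.breakpoints:
            dist = min(min(abs(bp - s), abs(bp - e))
                       for s, e in r.duplication_intervals)
            assert dist == 0

    def test_oversized_events_rejected(self):
        with pytest.raises(GenerationError):
            simulate.make_rearranged_chromosome(
                1_000_000, 3, False, self.CFG,
                event_min_bp=400_000, event_max_bp=500_000)


class TestSimulateReads:
    def test_mean_coverage_near_depth(self):
        seqs = {"chr": _seq.decode(_seq.random_seq(
            np.random.default_rng(1), 1_000_000))}
        reads = simulate.simulate_reads(seqs, depth=30, read_length_bp=500,
                                        error_rate=0.0, seed=4)
        cov = np.zeros(1_000_000)
        for r in reads:
            cov[r.start:r.start + 500] += 1
        assert abs(cov.mean() - 30) <= 1.5
        assert all(r.sequence == seqs["chr"][r.start:r.start + 500]
                   for r in reads[:50])

    def test_zero_depth_rejected(self):
        with pytest.raises(GenerationError):
            simulate.simulate_reads({"x": "ACGT" * 100}, depth=0.0)

    def test_read_longer_than_sequence_rejected(self):
        with pytest.raises(GenerationError):
            simulate.simulate_reads({"x": "ACGT" * 10}, depth=1,
                                    read_length_bp=100)

    def test_seeded_rerun_identical(self):
        seqs = {"x": "ACGTTGCA" * 200}
        a = simulate.simulate_reads(seqs, 5, 50, 0.01, seed=8)
        b = simulate.simulate_reads(seqs, 5, 50, 0.01, seed=8)
        assert [r.sequence for r in a] == [r.sequence for r in b]


class TestSimulateFlnc:
    TEMPLATES = {
        "A": ("ACGT" * 400, 90),
        "B": ("TTGACA" * 300, 10),
    }

    def test_truth_counts_match_request(self):
        reads, truth = simulate.simulate_flnc(self.TEMPLATES, seed=2)
        counts = truth.read_groups.group.value_counts()
        assert counts["A"] == 90 and counts["B"] == 10

    def test_engineered_fraction_fails_length_filter(self):
        reads, truth = simulate.simulate_flnc(
            self.TEMPLATES, frac_short=0.10, seed=2)
        short_ids = set(
            truth.read_groups[truth.read_groups.violates_length].read_id)
        by_id = {r.id: r for r in reads}
        assert short_ids
        for rid, read in by_id.items():
            assert (len(read.sequence) < 1000) == (rid in short_ids)

    def test_empty_template_map_rejected(self):
        with pytest.raises(GenerationError):
            simulate.simulate_flnc({}, seed=0)

    def test_short_template_rejected(self):
        with pytest.raises(GenerationError):
            simulate.simulate_flnc({"A": ("ACGT" * 10, 5)}, seed=0)


class TestEngineerCdsIndel:
    def test_in_frame_42bp_removes_14_residues(self, rng):
        cds = simulate.random_cds(rng, 150)
        _, effect = simulate.engineer_cds_indel(cds, 42, 0)
        assert not effect.frameshift
        assert effect.residues_removed == 14
        assert effect.extension_length_aa == 0

    def test_43bp_deletion_causes_frameshift(self, rng):
        cds = simulate.random_cds(rng, 150)
        utr = _seq.decode(_seq.random_seq(rng, 300))
        _, effect = simulate.engineer_cds_indel(cds, 43, 9, utr)
        assert effect.frameshift

    def test_deletion_spanning_start_codon_rejected(self, rng):
        cds = simulate.random_cds(rng, 50)
        with pytest.raises(GenerationError):
            simulate.engineer_cds_indel(cds, len(cds) - 5, 0)

    def test_bad_cds_rejected(self):
        with pytest.raises(GenerationError):
            simulate.engineer_cds_indel("ATGAAATA", 3, 0)  # not mult of 3
        with pytest.raises(GenerationError):
            simulate.engineer_cds_indel("AAAATGTAA", 3, 0)  # no leading ATG
        with pytest.raises(GenerationError):
            simulate.engineer_cds_indel("ATGAAAAAA", 3, 0)  # no stop
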