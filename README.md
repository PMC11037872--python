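# sdfam

Analyses for tandemly duplicated ("segmental duplication") gene families in
haplotype-resolved genome assemblies. The package re-implements, as a
reusable and tested pipeline, the computational stages used to characterize
a human core-duplicon gene family such as *TBC1D3*: assembly validation
from read depth, copy-number estimation from k-mer depth, structural
diversity statistics over haplotypes, a permutation test for the proximity
of gene copies to synteny breakpoints, phylogeny-based paralog grouping
with molecular-clock dating, assignment of long-read cDNA (FLNC) reads to
paralog groups, and ORF frameshift/extension analysis. A first-class
synthetic-data module generates every input with machine-readable truth, so
the whole pipeline runs and is validated without any external download.

## The statistics at the core

* **Read-depth copy number.** For a gene window *g* and single-copy control
  region *c* on a reference, with per-position canonical 32-mer read depth
  *d*, the diploid copy number is estimated as
  `CN = mean(d[g]) / mean(d[c]) × ploidy`.
* **Structural equivalence (90% rule).** Two haplotypes are structurally
  equivalent if at least 90% of *each* sequence maps to the other in a
  single alignment, where alignments are split at indels > 1 kbp.
  *Distinctness* is the fraction of haplotypes with no equivalent partner;
  *structural heterozygosity* is the fraction of diploid samples whose two
  haplotypes are not equivalent.
* **Synteny-break permutation test.** Pairwise chromosome alignments are
  chained into colinear blocks (max_gap 200 kbp, min_block_size 1 Mbp,
  min_subblock_size 50 kbp); the observed median distance from gene-copy
  midpoints to block boundaries is compared against 5000 permutations that
  redraw the same number of ~11 kbp blocks uniformly (optionally restricted
  to given intervals), with `p = (r+1)/(n+1)`.
* **Paralog grouping.** On a neighbor-joining tree of all copies (rooted on
  an outgroup), clades are collapsed top-down while their maximum pairwise
  SNV density stays within 1.5 × the allelic rate of 15.3 SNVs/10 kbp;
  groups with ≥ 10 members are population-level paralogs. Expansions are
  dated with a strict clock against the human–chimpanzee (6.5 Mya) or
  human–macaque (25 Mya) calibration.
* **FLNC assignment.** Reads ≥ 1000 bp with predicted accuracy ≥ 99.9% are
  assigned to the paralog group whose best alignment score beats every
  other group's best by ≥ 10; expression is normalized by the group's
  median per-haplotype copy number.

## Worked example

```python
from sdfam import simulate, structure, synteny

cfg = simulate.SimConfig(
    seed=42, n_samples=20,
    populations=[simulate.PopulationSpec("AFR", cn_mean=8.6),
                 simulate.PopulationSpec("NONAFR", cn_mean=6.35)],
    n_clusters=2, n_paralog_groups=3,
    cassette_length_bp=4000, unit_gene_length_bp=2000, flank_length_bp=1500)
haplotypes, truth = simulate.make_population(cfg)

totals = structure.diploid_totals(truth.copy_number)
res = structure.population_cn_compare(totals)
print(f"diploid copy-number means: "
      f"AFR {res['means']['AFR']:.1f}, NONAFR {res['means']['NONAFR']:.1f} "
      f"(Welch p = {res['p_value']:.1e})")

cluster1 = [h for h in haplotypes if h.cluster == 1]
names = [h.name for h in cluster1]
recs = [simulate.truth_pair_alignment(cluster1[i], cluster1[j], cfg)
        for i in range(len(cluster1)) for j in range(i + 1, len(cluster1))]
mat = structure.equivalence_matrix(names, recs)
samples = {}
for h in cluster1:
    samples.setdefault(h.sample, []).append(h.name)
het = structure.structural_heterozygosity(
    {s: tuple(v) for s, v in samples.items()}, mat)
print(f"cluster 1: {structure.distinctness_fraction(mat):.0%} of haplotypes "
      f"structurally distinct, heterozygosity {het:.0%}")

rearr = simulate.make_rearranged_chromosome(
    20_000_000, 3, anchor_at_copies=True, config=cfg,
    event_min_bp=1_500_000, event_max_bp=3_000_000)
blocks = synteny.chain_synteny(rearr.alignments)
breaks = synteny.breakpoints(blocks, 20_000_000)
perm = synteny.permutation_test(rearr.duplication_intervals, breaks,
                                20_000_000, n_perm=5000, seed=42)
print(f"synteny: {len(blocks)} blocks, observed median break distance "
      f"{perm.observed_median_bp/1e3:.1f} kbp, empirical p = {perm.empirical_p:.1e}")
```

prints

```
diploid copy-number means: AFR 34.5, NONAFR 25.3 (Welch p = 2.2e-05)
cluster 1: 1% of haplotypes structurally distinct, heterozygosity 85%
synteny: 6 blocks, observed median break distance 1.0 kbp, empirical p = 2.0e-04
```

The two populations were generated at diploid means 34.4 and 25.4 copies
and the cohort recovers them; with tiny 4 kbp cassettes most haplotypes
share a copy-number class (hence low distinctness) while the two haplotypes
of a sample usually differ (high heterozygosity); and because the
duplication cassettes were planted at the rearrangement breakpoints, the
observed median distance to synteny breaks (1 kbp) is far below every
permutation draw, giving the minimum attainable p of 1/(5000+1).

The same stages are available from the shell:

```bash
sdfam run --out out/ --seed 1        # full synthetic pipeline
sdfam simulate --out sim/ --seed 1   # cohort + truth files only
sdfam synteny-perm --paf aln.paf --features genes.bed \
      --chrom-length 83000000 --n-perm 5000 --seed 1 --out perm.json
sdfam group --alignment copies.fasta --outgroup chimp --out groups.tsv
```

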