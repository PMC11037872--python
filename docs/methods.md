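# Methods

This note documents the models, parameter choices and numerical decisions
behind `sdfam`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Synthetic cohort model

A duplication-cluster haplotype is `flank + k × cassette + flank`. Each
cassette (default 40 kbp) carries one gene unit (default 11 kbp) padded
with spacer sequence. Paralog groups descend from one ancestral cassette:
each group ancestor is mutated at half the paralogous SNV density (default
60 SNVs/10 kbp pairwise between groups) and each copy instance at half the
allelic density (default 15.3 SNVs/10 kbp pairwise within a group, the
published allelic SNV rate inside segmental duplications). Substitutions
are independent per site and always change the base, so SNV densities
convert exactly into expected pairwise distances; indels exist only where
engineered. All randomness flows from one `numpy` generator seeded by the
config, so identical config + seed reproduces byte-identical output.

**Copy-number distribution.** Per population the copy number of a cluster
on one haplotype is a negative binomial (dispersion shape default 15,
giving a realistic 1–14 spread around means near 8), discretized and
clamped to `[1, 14]`. Two refinements matter for small cohorts:

1. *Mean correction.* Clamping shifts the raw NB mean; the generator
   solves (by bisection on the analytic clamped expectation) for the raw
   mean whose clamped expectation equals the configured `cn_mean`, so the
   delivered distribution honors its nominal mean exactly.
2. *Stratified draws.* Copy numbers are drawn by jittered inverse-CDF
   sampling over equal quantile strata (Latin-hypercube style) and
   shuffled. The marginal distribution is unchanged and individual samples
   keep the full spread, but a cohort of n = 30 represents its nominal
   distribution closely — group means land within a few tenths of a copy
   rather than the ±1+ copies of iid sampling. A config flag
   (`stratified_cn=False`) restores iid draws.

The same idea is available for shotgun reads (`simulate_reads(...,
stratified=True)`): read starts are drawn one per equal-width stratum, so
regional coverage is nearly noise-free while the marginal start
distribution stays uniform. The default remains iid-uniform.

**What the generator does not emulate.** Indel sequencing errors, HiFi
error profiles and quality strings (reads carry a constant Q score);
duplication mechanism (NAHR) and gene conversion; transcript splicing;
GC-coverage bias. Passing tests therefore validate the *estimators and
decision rules*, not robustness to those real-data artifacts.

## Assembly QC (gap / collapse flagging)

Reads are placed back on the assembly by a seed-and-vote mapper (21-mer
seeds every 12 bp, diagonal majority vote; the occurrence cap per seed must
exceed the tandem copy number, default 20). Per position the depth of the
most frequent (primary) and second most frequent (secondary) base is
profiled. The source method made these calls from depth plots by eye; the
thresholds here are explicit stand-ins chosen from first principles:

* **GAP** — zero primary depth over ≥ `min_flag_window` (5 kbp).
* **COLLAPSE** — a site is *discordant* when its secondary depth is ≥ 10%
  of primary and ≥ 5 reads at ≥ 5× depth; collapse of two diverged copies
  makes every divergent site discordant (secondary fraction ≈ 0.5), while
  the ≈ 0.1% HiFi error floor essentially never reaches 5 concordant wrong
  bases. Divergent sites are sparse at allelic density (~1.5/kbp), so
  collapse-like 1 kbp windows separated by ≤ 2 quiet windows merge, and a
  region is reported when it spans ≥ 5 kbp with ≥ 5 discordant sites.

A windowed *mean* secondary fraction cannot work here: at 1% copy
divergence the window mean is ~0.005 while the per-site signal is ~0.5,
which is why the per-site form is used. QC reads default to 10 kbp
(HiFi-scale): long reads almost always span a site discriminating two
near-identical copies, so placement is essentially unambiguous; with short
reads, stretches identical between two copies shadow each other and
produce artifactual zero-coverage runs (the problem ONT k-mer anchor
validation addresses in the original workflow, which is out of scope
here).

## k-mer read-depth copy number

Reference 32-mers are matched exactly in canonical (strand-min) form
against the read k-mer bag; copy number is the gene-window mean depth over
the control-region mean, times ploidy. Positions whose depth exceeds 10 ×
the gene window's own median are masked as repeat-degenerate before
averaging — the mask is relative to the window median, not to the control,
so genuinely high copy numbers (diploid CN > 20) are not masked away.
Exact matching differs from mismatch-tolerant k-mer CN tools: copies
diverged from the reference by density *d* lose ≈ `1 − (1−d)^32` of their
k-mers, biasing CN low by ~5% at allelic and ~20% at paralogous density.
The accuracy experiment (diploid truths 1–28 within ±0.5 at 30× total
coverage) therefore uses identical copies and stratified read starts: it
validates the counting and normalization machinery, with divergence
dropout documented as a known limitation of exact matching. Control
regions in that experiment are 20 kbp so the normalization constant is
estimated to ≪ 1%.

Assembly-side copy number counts runs of assembly positions whose k-mers
occur in the probe, merged across gaps ≤ 500 bp (an SNV knocks out up to
32 consecutive shared k-mers); runs shorter than 6 kbp — truncated copies
— are excluded, and a run spanning several probe lengths (directly
adjacent tandem copies) counts as `round(span / probe_length)` copies.

## Structural diversity

Coverage is computed per alignment record by splitting the cigar at any
single indel operation > 1 kbp (adjacent same-type operations are merged
first) and taking, per side, the maximum sub-alignment span over sequence
length. Equivalence takes the *minimum* of the two coverages against the
0.90 threshold — the symmetric reading; using one side only would make
"equivalent pair" asymmetric. Equivalence is deliberately not forced to be
transitive, and distinctness counts partnerless haplotypes rather than
connected components. Cohort alignments may come from any external aligner
as PAF with `cg` tags; the generator also emits exact truth alignments
from its own cassette bookkeeping, and an edlib-based internal aligner
covers small ad-hoc pairs (its unit gap costs can absorb parts of large
random insertions as mismatches, so it is not used where exact segment
sizes matter).

## Synteny blocks and the permutation test

Chaining merges target-sorted alignments while query name, orientation and
colinearity hold and both gaps stay ≤ `max_gap`; members below
`min_subblock_size` are dropped before, chains below `min_block_size`
after. Breakpoints are deduplicated block boundaries, excluding chromosome
termini by default (they are alignment artifacts, not rearrangement
evidence). Feature-to-break distance is measured from the feature midpoint
(edge distance is a config alternative), and the median takes the lower of
the middle two for even counts. The null redraws blocks of fixed 11 kbp
with replacement — "randomly selected" with no exclusion stated — and the
empirical p-value uses `(r+1)/(n+1)`, so p is never zero and is uniform
under the null (verified by KS calibration at 200 replicates × 500
permutations; the headline test uses 5000 permutations).

## Paralog grouping and dating

Neighbor joining (scikit-bio) stands in for ML tree inference; grouping
depends only on clade structure, which NJ recovers for groups separated
well beyond the threshold, and externally built newick trees are accepted.
"Intra-variation" is implemented as the *maximum* pairwise SNV density
within a clade (conservative; the mean is a config alternative), with
pre-order early acceptance so accepted clades are maximal and partition
the leaves. Clades below 10 members stay as named minor groups rather
than being merged upward, mirroring how low-frequency paralogs are
reported separately. One practical consequence of the max statistic: on
sequence of length L the pairwise density has sampling standard deviation
`sqrt(15.3 / (L/10kbp))` SNVs/10 kbp, so short fragments (≈ 10 kbp) can
push a clade's maximum past the 1.5× threshold by chance and fragment true
groups; grouping should run on the full gene/cassette sequence (the
recovery experiments use 60 kbp), as the original analysis did on whole
gene copies. Expansion ages use a strict linear clock scaled by a
calibration divergence (6.5 Mya human–chimpanzee or 25 Mya human–macaque).

## FLNC transcripts and ORFs

Filters are inclusive at their boundaries (≥ 1000 bp, ≥ 99.9% accuracy).
The assignment margin operates in raw aligner score units; with SAM/PAF
input the `AS` tag is used unchanged, and the internal scorer reports the
negated global edit distance, which lives on the same scale. Reads
aligning to copies of a single group are assigned with infinite margin (a
config flag can require a competing mapping). Isoform collapsing is
consumed, not implemented; a trivial exact-model grouper covers synthetic
data. Expression normalization divides raw assigned counts by the median
per-haplotype copy number of the group (enforced ≥ 1).

The ORF analyzer fits the full reference CDS inside the transcript with
affine-gap alignment (match 2, mismatch −6, open −12, extend −0.1,
transcript end gaps free). The stiff mismatch/extension ratio guarantees a
contiguous engineered indel is never traded for runs of chance mismatches,
which makes the net coding indel — and hence the frameshift call —
recoverable even when the only right-hand anchor is the stop codon itself.
Residue counts come from translating the transcript's own reading frame:
`residues_removed` is the count of reference residues without a surviving
counterpart before the ancestral stop (for a frameshift, everything from
the first affected codon), and `extension_length_aa` counts codons
translated past the ancestral stop position, mapped into transcript
coordinates, until the first in-frame stop. Truth for engineered fixtures
is computed by brute-force translation from the known deletion, entirely
independent of the alignment path; the two agree on 1000 random fixtures
per run. Deletions not aligned to codon boundaries may count one hybrid
codon as removed.

## Problem sizes and runtimes

The validation experiments run at desk scale by choice: cohorts of
30 + 30 samples for population statistics (2 kbp cassettes — copy-number
statistics are independent of cassette size); 24 haplotypes for structural
statistics; 20 Mbp chromosomes with 3 rearrangements for the permutation
test; 20 families × 36 copies × 60 kbp for grouping recovery; diploid
truths 1–28 at 30× for copy number; 160-read FLNC libraries; 1000 ORF
fixtures. The full test suite runs in well under a minute and
`scripts/acceptance.py` in about half a minute on one CPU.

## Known limitations

Exact k-mer matching under-counts diverged copies (above); the internal
aligners are adequate for synthetic data but not substitutes for minimap2
on real assemblies; the collapse screen assumes substitution-dominated
divergence between collapsed copies; the strict clock ignores rate
variation and gene conversion, both of which shape real duplication
histories; and the permutation null treats the chromosome as uniformly
sampleable, which real assembly gaps would violate.
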