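# Methods

## The generative model

`linkedsim` simulates a linked-read library in three layers, mirroring the
stLFR workflow: long-fragment generation, combinatorial barcoding, and
short-read sampling with errors.

**Diploid input.** The genome is a phased diploid assembly: two independent
contig sets (names, counts and lengths may differ between haplotypes).
Coordinates are 0-based half-open throughout; sequences are restricted to
A/C/G/T/N and uppercased on load. Fragments never span contig boundaries.

**Fragments.** Physical coverage C_F (fold) is split equally: haplotype h is
targeted at (C_F/2) × L_h summed fragment bases over its own length L_h,
which keeps per-haplotype depth equal even when the assemblies differ in
length. Starts are uniform with contigs weighted by length; lengths are
Exponential(μ_FL) rounded to integers, rejected and redrawn below `min_fl`
(default 1000 bp — shorter molecules could not carry a read pair). Rejection
rather than clamping keeps the length law a clean truncated exponential;
note its population mean is therefore `min_fl + μ_FL` (≈ 51 kb at the 50 kb
default), not μ_FL. Fragments overrunning their contig are truncated at the
end (the truncated length still counts toward volume; truncated fragments
below `min_fl` are discarded); with μ_FL ≪ contig length this touches a
vanishing fraction of molecules. Fragments with more than 50% N are rejected
so assembly gaps neither enter reads wholesale nor punch coverage holes
(N bases inside accepted fragments are emitted verbatim and never mutated by
the error model). Generation stops as soon as the per-haplotype volume
target is reached, making achieved physical coverage exact up to the last
fragment — this "volume targeting" was chosen over generating a fixed
N_bc = C_F × G / μ_FL fragment count because downstream read budgeting
consumes volume, and N_bc remains available as the documented expectation.

**Barcodes.** The whitelist holds 1536 distinct 10-mers; triples are ordered
and drawn with replacement, giving a combination space of 1536³ =
3,623,878,656 (both with- and without-replacement interpretations round to
3.62 × 10⁹; with-replacement matches three independent ligation rounds).
The real whitelist is a fixed platform constant that is not publicly
printed, so the default list is a deterministic synthetic stand-in
(rejection-sampled to minimum pairwise Hamming distance 2, seed fixed and
independent of the run seed); `load_whitelist` accepts the genuine list.
Partitions (one fragment each at NFL = 1; k fragments at NFL = k, last
partition possibly smaller) receive triples sampled uniformly without
replacement, implemented by drawing integer codes in [0, 1536³) and
rejecting repeats — demand is always far below the space, so rejections are
negligible.

**Reads.** The read budget counts individual reads: n_f = round(C_R ×
length_f / RL) per fragment, halved (rounded, minimum one) for pairs. This
interpretation makes emitted base coverage over the DNA volume equal C_R in
both PE and SE modes, which is what the symbol denotes. Pair placement is
i.i.d. uniform on [0, length_f − insert]; inserts are Normal(μ_IS, σ_IS)
rounded and clamped to [2 RL, length_f] (clamping, not rejection, so short
fragments still contribute), orientation fixed FR. σ_IS defaults to
0.1 μ_IS (60 bp at the 600 bp default). Single-end reads are uniform with a
fair strand coin. Per-run determinism comes from fixed child RNG streams:
`[seed, hap]` for each haplotype's fragments, `[seed, 17]` for barcode
assignment, `[seed, 3, fragment_id]` for each fragment's reads — so one
haplotype's or fragment's draws never shift when another changes. FASTQ is
gzip with zeroed mtime, making byte-identical reruns testable.

**Qualities and errors.** The default quality model is positional: mean Q
declines linearly 38 → 30 across cycles with Gaussian jitter sd 3, rounded
and clamped to [2, 41]; `QualityModel.from_table` loads empirical per-cycle
profiles (TSV: cycle, mean, sd). Errors are substitutions only, at per-base
probability p_i = c · 10^(−Q_i/10). The scale c is calibrated once per run
against the *exact* discretized quality distribution (normal CDF differences
over the integer grid, tails lumped into the clamps), so E[mean p_i] equals
the configured error rate regardless of profile shape — the 1% setting is
honored in expectation, not approximately. Substituted bases are uniform
over the three alternatives; a per-base cap of 0.75 keeps p a probability
under extreme user profiles. No indels, adapters, duplicates or GC bias are
modelled.

## Presets and hybrids

The twelve presets cross C_F–C_R pairs (350, 0.1), (140, 0.25), (70, 0.5),
(47, 0.75) with μ_FL = 50/75/100 kb by group of four; insert 600 bp, error
1%, NFL = 1 throughout; 70× doubles C_F and keeps C_R. The (47, 0.75) pair
multiplies to 35.25×; it is stored as conventionally quoted and the config
reports the achieved product rather than "correcting" either number. Hybrid
libraries are merged at FASTQ level (alignment-level merging is downstream
of this package): read names gain an A/B source prefix for global
uniqueness, barcode tags stay untouched within each source but are
namespaced by the prefix since the two libraries were barcoded
independently. Same-arity inputs merge elementwise; a PE + SE mix keeps the
pair files and adds an `_se` file, with one manifest covering every read.

## Synthetic fixtures

The fixture generator emulates only what the simulator consumes: a base
reference of i.i.d. bases at configurable GC (default 0.41, human-like),
phased SNPs (default 10⁻³/bp), small indels (10⁻⁴/bp, geometric lengths,
mean 3 bp) and optional SV-sized insertions/deletions, each genotyped
0|1 / 1|0 / 1|1 with probability ⅓ and recorded in a phased VCFv4.2 truth
file. Variants never overlap (1 bp buffer); candidate positions that collide
with an already-placed variant are dropped, so the VCF records exactly what
was applied. These genomes have no repeat structure, no segmental
duplications and no realistic variant clustering: passing tests demonstrate
correct simulator bookkeeping (coordinates, phasing, coverage accounting,
error calibration), not performance of downstream tools on real human
genomes.

## QC

QC recomputes everything from the run's own artefacts (fragment manifest,
truth sidecar, FASTQ): achieved C_F/2 per haplotype, emitted bases over the
DNA volume (achieved C_R), fragment-length and insert statistics, barcode
cardinalities and the realized substitution rate. The error rate is measured
by direct comparison of each read with its truth substring — deliberately
aligner-free, so mapping artefacts cannot leak into the verification
surface. A sentinel test confirms QC detects a single corrupted base in an
otherwise error-free library.

## Problem sizes and numerical choices

Statistical checks run on sizes where the tested law dominates the noise,
chosen once as part of the test design:

- Volume targeting, insert law, error calibration: one PE100_stLFR library
  at C_F = 35, C_R = 0.5, μ_FL = 50 kb on a ~1 Mb-per-haplotype (acceptance
  script) or ~200 kb (test suite) synthetic diploid — ≥ 10⁴ pairs and
  ≥ 10⁶ bases, so 1%-level tolerances sit several σ above sampling noise.
- Fragment-length law: 10 Mb-per-haplotype N-free reference, so contig-end
  truncation touches < 1% of fragments; 100 seeds for the two-sample
  comparison against an independently coded truncated-exponential oracle
  (KS, α = 0.01), ≥ 20,000 pooled fragments for the mean.
- Heterozygous allele balance: SNP-only fixture (haplotype coordinates equal
  reference coordinates), zero-error reads, thousands of site-overlapping
  reads pooled across ~130 heterozygous SNPs.

Tie-breaks and edges: all rounding is banker's (`numpy.rint`); ceil for the
N_bc expectation as an "at least one partition" count; fragments shorter
than 2 RL (PE) or RL (SE) yield no reads and are counted as skipped;
C_F = 0 or C_R = 0 produce empty but valid outputs; a plan whose `min_fl`
exceeds every contig raises an explicit unsatisfiable-plan error.

## Known limitations

Substitution-only errors with an idealized positional quality model; no
chimeric fragments, GC bias, PCR/optical duplicates or barcode sequencing
errors (whitelist correction is therefore out of scope); fragments are
confined to single contigs; hybrid merging is FASTQ-level only. The
synthetic fixtures are statistically simple stand-ins — conclusions about
variant-calling performance on real genomes require real assemblies as
input, which the two-FASTA interface accepts directly.
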