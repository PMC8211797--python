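# Methods

`bescan` reimplements, as a tested library and CLI, the computational
analyses surrounding adenine-base-editor (ABE) therapy design for a
nonsense point mutation: strand-aware guide design and batch
variant-targetability scanning, mismatch-tolerant genomic off-target
enumeration, per-position editing quantification from amplicon reads or
Sanger traces, and transcriptome-wide A-to-I off-target variant
filtering. A seeded synthetic-data module supplies every input with
machine-readable ground truth, so all stages run without downloads.

## Coordinate and strand conventions

Genomic positions are 1-based inclusive (VCF convention); internal
string offsets are 0-based half-open, with conversions confined to
`seqcore`. Protospacer positions are numbered 1 (PAM-distal, 5' end)
through 20 (PAM-proximal), so the editing window 4–8 and statements
like "the target adenine at position 4" follow the field's standard
numbering. For a minus-strand protospacer, "genomic start" is the
forward-axis coordinate of the protospacer's 5' base (the highest
coordinate of its footprint).

Sequences are upper-cased at ingestion and restricted to the IUPAC DNA
alphabet. An ambiguous genome base (N or a degenerate code) never
satisfies a concrete PAM-pattern position: ambiguous reference regions
are not reported as PAMs or off-target sites.

## Guide design and targetability

An ABE corrects a mutation when the disease allele reads as adenine on
one strand: alt=A is scanned on the plus strand, alt=T on the minus
strand, and any other allele yields no designs. Candidate placements
are every 20-mer containing the disease adenine, evaluated on the
*mutant* sequence (the editor acts on patient DNA; the unsubstituted
reference is consulted only to decide whether an edit restores the
reference allele). A placement becomes a design when an
editor-repertoire PAM (IUPAC pattern, matched at its own length) lies
immediately 3' of the protospacer. A design is "in window" when the
target adenine falls in the editing window, 4–8 by default.

Built-in editor profiles: `NGG` (classical SpCas9 repertoire), `NG`
(relaxed, pattern NGN), and `NGA` — an NG-repertoire editor whose NGA
preference is carried as an annotation on designs whose observed PAM
matches NGA, because such editors recognise NG broadly while favouring
NGA. Targetability under the NGA profile therefore equals NG
targetability; the per-design `pam_preferred` flag exposes the subtype.

Bystanders are adenines other than the target inside the window
(counted against a design) or inside a wider reporting window (1–12 by
default, listed but flagged, so positions such as an A at 11 are
visible without being called in-window). Window cytosines are tracked
separately because ABEs exhibit cytosine-to-thymine off-target
activity at on-target loci.

`best_design` picks, among in-window designs: fewest in-window
bystanders, then target position closest to the window centre (ties
resolved toward the window's low end), then plus strand. No published
rule exists; this ordering optimises precision first.

Codon consequences are evaluated per edited position, each as if
edited alone, against a minimal frame model (strand + one codon first
base): `restores_reference` when the edited base equals the reference
allele, otherwise `synonymous` / `missense` / `creates_stop` /
`removes_stop` by standard-table translation, or `not_coding` outside
the declared frame region.

The batch scanner reports, per editor, counts and fractions of
G:C→A:T transitions (ref G→alt A or ref C→alt T — the only classes an
ABE can revert) and of targetable variants, together with the window
and PAM repertoire used, so any external count can be reconciled
against explicit criteria.

## Off-target search

Sites are Hamming near-matches to the guide on either strand with a
pattern-matching 3' PAM; PAM mismatches are never counted, and bulges
are out of scope (mismatch-only model). The seed is the PAM-proximal
12 bp (positions 9–20 of a 20-mer) — the region where mismatches most
strongly disrupt targeting; a site is seed-identical when no mismatch
falls there. A single mismatch at position 12 therefore breaks seed
identity.

The implementation is a vectorised sliding-window comparison per
contig and strand, deduplicated by (chrom, start, strand) and sorted
deterministically. Its normative reference is an all-positions
brute-force Hamming oracle, implemented twice independently: a plain
Python loop (small genomes) and a shift-and-accumulate scan (100 kb
scale); the test suite asserts exact agreement on planted random
genomes. The default scanning PAM is NGN, mirroring the NG editor;
genome-scale runs against a real assembly (e.g. mm10 for the published
histogram of 1/2/55 sites at 1/2/3 mismatches) use the same API with a
genome FASTA via `bescan offtarget` and are practical but not part of
the test suite, which runs on synthetic genomes only.

## Amplicon quantification

ABE products are substitutions, so each read is placed against the
amplicon by its best gapless offset: an exact flank-anchor lookup
first, then a minimal-Hamming scan over all containment offsets. Reads
with no acceptable placement (≥ `min_overlap`, mismatch fraction ≤
0.2) imply an indel or an unrelated fragment and are excluded from
substitution tallies — counted, never silently dropped. Defaults:
mean Phred ≥ 20 per read, per-base masking below Q10 (masked bases
leave the depth denominator); no published thresholds exist for the
original trace/deep-sequencing analyses, so these are the package's
own conservative choices.

Per protospacer position the edit frequency is edited-base count /
post-masking depth (A→G at adenines, C→T at cytosines, on the
protospacer strand). Allele classes partition the used reads:
`unedited`, `precise` (target only), `bystander_containing` (any
non-target A→G), `cytosine_edit_containing` (window-cytosine C→T
without adenine bystanders), `other` (unexpected substitutions, e.g.
sequencing error); a conservation assertion enforces the partition on
every run.

Trace mode consumes a per-position four-channel peak-intensity table
aligned 1:1 with the amplicon and computes the edited-base share
normalised over the two relevant channels only (reference + edited),
because four-channel baselines are instrument-specific. Positions
outside the protospacer whose dominant peak disagrees with the
reference are flagged as alignment warnings. This is a deliberately
simplified surrogate for chromatogram-deconvolution tools, not a clone
of them; AB1 binary parsing is out of scope.

## RNA A-to-I off-target filtering

Called RNA variants (VCF with INFO FS/QD/DP and FORMAT AD, SNVs on
canonical chromosomes) pass through, in order:

1. **Confidence filters** — remove FS > 30.0 (strand bias), QD < 2.0,
   DP < 30, and every member of any SNV cluster (≥ 5 SNVs whose
   positions span ≤ 35 bases on one chromosome, any-window membership;
   distinct alleles at one position count once toward cluster size).
   Comparisons are strict, so boundary records (FS = 30.0, QD = 2.0,
   DP = 30) are kept. Each removed record is attributed to exactly one
   rule (annotation, FS, QD, DP, cluster, in that order) so kept +
   removals always equals the input count. Cluster membership is
   evaluated on the full input call set: a cluster is a property of
   the calls, not of what survives the threshold rules.
2. **Control subtraction** — drop any record whose full
   (chrom, pos, ref, alt) key appears among the control sample's
   confident calls; confident variants are allele-specific. An
   optional site blacklist emulates upstream known-SNP masking.
3. **A-to-I classification** — A→G plus T→C calls (the same edit read
   from the opposite cDNA strand). Non-A-to-I records are retained
   with the flag false; reports carry both the all-events and the
   A-to-I counts because published per-sample event counts do not
   state which definition they use.
4. **Editing rate** = alt reads / DP (DP is not assumed to equal the
   AD sum; callers differ). Zero depth yields an undefined, flagged
   rate. Cross-replicate sharing intersects (chrom, pos, ref, alt)
   keys, reporting a shared-by-exactly-k histogram and the
   shared-by-all set.

Upstream alignment, duplicate marking, recalibration and calling
(STAR/Picard/GATK) are consumed as a finished VCF and are out of
scope.

## Synthetic data

Every generator is deterministic under a fixed seed, emits a
GroundTruth JSON sufficient to recompute expected outputs, and
re-verifies its own planting with an independent brute-force check
before returning.

* `gen_genome` — i.i.d. bases at a requested GC fraction (default
  0.42, mammalian-like).
* `plant_offtargets` — overwrites non-overlapping loci with sites at
  exact Hamming distances plus an instantiated PAM; optional flags
  force or forbid seed-region mismatches. Generation is rejected and
  reseeded if it accidentally creates extra near-matches within the
  maximum requested distance (vanishingly rare for a 20-mer at ≤ 3–4
  mismatches in 100 kb), so the planted set is exactly the near-match
  set. The default planting template {1:1, 2:2, 3:55} mirrors the
  structure of a genome-wide prediction for the studied guide.
* `gen_variant_table` — plants variants every 80 bp in fully
  controlled local contexts: targetable entries (ref G → alt A with a
  window-reachable PAM at a chosen position, other in-window PAM slots
  scrubbed) and three guaranteed-untargetable categories (`no_pam`:
  every window-reachable PAM G-position made non-G; `out_of_window`: a
  PAM reachable only from a position outside the window;
  `non_a_allele`: disease allele C or G). Exactly round(n·fraction)
  variants are targetable by construction, and a brute-force placement
  enumeration re-verifies every context.
* `simulate_amplicon_reads` — full-amplicon reads with independent
  per-read Bernoulli edits at programmed protospacer positions on the
  protospacer strand, uniform substitution error elsewhere (default
  1e-3), constant Q37 quality. Ground truth records the exact drawn
  edit count per position, so error-free runs are recoverable exactly
  and noisy runs to binomial precision. Default rate templates (0.326;
  0.58/0.089/0.004 at positions 6/8/11) use published wet-lab editing
  percentages as realistic settings — the percentages themselves are
  biological measurements and are not desk-reproducible.
* `simulate_rna_vcfs` — treated/control VCF sets with shared true
  A-to-I events (default 22 across 3 samples, mirroring the published
  sharing structure), per-sample private events, a control-shared SNP
  background, and decoys each violating exactly one filter rule,
  including a 5-SNV/≤35 bp cluster and, optionally, one boundary-value
  event that the strict thresholds must keep.

What the generators do **not** emulate: real sequence composition
(repeats, homopolymers, Alu editing hotspots), correlated or
position-dependent sequencing error, paired-end structure, indels,
coverage variation along transcripts, and linkage between nearby true
edits. Passing recovery tests therefore demonstrates correctness of
the estimators and filters under their stated models, not robustness
to every artefact of real libraries.

## Problem sizes and numerics

Test and reproduction runs use: 100 kb synthetic genomes (100
replicates for oracle equivalence), 20,000 reads × 100 seeded runs per
rate template for quantification recovery (acceptance band: within 3
binomial standard errors in ≥ 99% of runs), and 3-sample VCF sets with
22 shared events for filter recovery. These sizes keep the whole suite
in a few minutes on one CPU while leaving the binomial bands narrow
enough to detect estimator bias. Frequencies at zero depth are NaN and
flagged rather than zeroed. All randomness flows from
`numpy.random.default_rng` seeds recorded in GroundTruth.

## Known limitations

* No guide-activity or cutting-frequency scoring (CFD/MIT); design
  ranking is by bystander burden and window geometry only.
* Off-target model is mismatch-only (no bulges), matching the
  mismatch-count presentation it reimplements.
* The amplicon quantifier is a simplified stand-in for full
  indel-aware amplicon genotyping: reads implying indels are excluded
  rather than genotyped.
* Genome-build semantics for human variant tables are metadata only;
  no liftover.
* External reconciliations that require large downloads (a real mm10
  search; a full supplementary variant table) are supported by the
  same APIs but deliberately not exercised by the test suite.
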