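# Methods

This note records the models, conventions and numerical choices behind
`delbin`, and what the synthetic-data generators do and do not emulate.

## Deletion-bin inference

**Geometry.** A deletion line with breakpoint FL *f* retains the proximal
interval [0, *f*] of its arm (centromere = 0, telomere = 1). Marker
absence therefore pushes the marker distal to *f*; presence pulls it to a
position ≤ *f*. The inferred bin is the half-open interval
(max FL over absent lines, min FL over present lines], with the upper
bound **inclusive** because a retaining line with breakpoint *f* is
compatible with the marker sitting exactly at *f*. When no deletion line
on the arm retains the marker, the telomere closes the bin at 1.0 —
justified only if the arm's ditelosomic amplifies; otherwise inference
raises.

**Chromosome and arm.** A chromosome is assigned only when the marker is
absent in every nullisomic of that chromosome and present in all other NT
lines; absence in nullisomics of two chromosomes is flagged as
multi-locus/contradictory with no assignment. An arm is assigned as the
complement of the arm retained by the non-amplifying ditelosomic, and only
when the sister ditelosomic amplifies.

**Contradictions.** If the largest absent breakpoint meets or exceeds the
smallest present one, the default (strict) mode raises a
`ContradictionError` naming the conflicting line pairs. The tolerant mode
drops calls greedily — the call involved in the most conflicts first, ties
broken by line name — and reports the dropped lines on the resulting bin.
Tolerance exists for noisy real-world panels; the packaged panel is
consistent.

**Oracle.** `brute_force_bin` enumerates a grid of candidate positions
(default step 0.001) and keeps those consistent with every call, treating
an amplifying ditelosomic as a present line at FL 1.0. The hull of
survivors equals the analytic bin up to one grid step; the test suite
asserts this equivalence on the packaged panel and on random panels, and
asserts that error-free simulated panels always yield bins containing the
true position.

**Merged primer sets.** Two primer sets assaying the same gene can be
merged into one evidence row; per line, non-missing calls must agree, and
a disagreement is demoted to missing with a warning rather than picking a
side.

## Gene models and coordinates

Coordinates are ATG-anchored with no position 0: the A of the initiation
ATG is +1 and 5′-UTR positions are negative, so the span of (−20, 468) is
488 bp. Amplicons merge by the longest exact suffix/prefix overlap of at
least `min_overlap` bp (default 15 — comfortably below the 19-bp junction
of the two packaged upstream/downstream fragments and above random
expectation); no mismatch tolerance is applied, and when region
coordinates are present a discordant overlap is reported with the first
mismatching offset.

ORF selection (when the 5′-UTR length is not given) takes the 5′-most ATG
that reaches an in-frame stop and passes a lenient Kozak check — purine at
−3 **or** G at +4 — falling back to the 5′-most ORF with a warning if no
ATG passes; both context bases are reported. Translation uses the
standard genetic code (terminal stop required and excluded, internal stops
rejected), so a clean ORF of L bp encodes L/3 − 1 residues. GC content is
reported to 0.1%; molecular weight is the sum of average residue masses
plus one water, in kDa, with the empty peptide defined as water plus a
warning rather than an error.

## Variant calling

Allele pairs are aligned globally with affine gap scoring: match +2,
mismatch −3, gap open −7, gap extend −2 (a gap of length L scores
−7 − 2(L−1)). The conservative gap penalties keep a single 6-bp InDel
intact rather than splitting it. Among co-optimal alignments the engine's
first traceback is used, which is deterministic for fixed inputs; the test
suite checks optimality against an independent exhaustive enumeration on
short sequences.

Each mismatch column yields one SNP (adjacent substituted columns are
counted separately); each maximal gap run yields one InDel whose bases are
left-aligned within repeat context. Positions are ATG-anchored on the
reference allele; an insertion's position names the reference base after
which the new bases sit (an insertion shifted to before the first base is
reported at the first base's coordinate — a degenerate case the
generators never produce). Identity is match columns over all alignment
columns, gaps included — stated explicitly because published identity
percentages cannot arbitrate the denominator. Applying a called variant
set back to the reference reconstructs the alternate allele exactly
(patch round-trip, asserted over seeds).

Protein consequences: per-SNP codon arithmetic on the reference ORF
classifies synonymous/missense/nonsense changes, and a protein-level
alignment supplies the overall substitution count and inserted/deleted
residues; any InDel whose length is not a multiple of three flags the
comparison as a frameshift and leaves the counts undefined.

## In-silico PCR and genotyping

A primer binds a site only if its 3′-terminal 3 bases match exactly and
total mismatches are ≤ 2 (both configurable) — a kinetic abstraction of
*Taq*'s intolerance of 3′ mispairing, which is what makes the
allele-specific assays dominant. Both strands are scanned; every
convergent forward/reverse site pair within 5000 bp yields a product whose
size is the distance between the two 5′ ends. No melting-temperature or
thermodynamic model is attempted; annealing temperatures are carried as
metadata.

Genotypes come from the complementary dominant assay pair (540-bp assay
diagnostic for the high-activity allele, 640-bp for the low-activity
allele): exactly one expected-size product (±10 bp, a gel-resolution
analogy) identifies its allele; both is ambiguous
(heterozygosity/contamination); neither is null. Off-size products are
ignored with a warning.

## Replicate QC and association

Replicate enzyme activities (U min⁻¹ g⁻¹) are assayed in duplicate; the
coefficient of variation is 100 × sample SD / mean. A duplicate with
CV ≤ 10% passes with its mean; a failing duplicate with a third
measurement is resolved to the mean of the two closest values —
discarding the aberrant measurement that triggered the retest — and a
failing duplicate without one is excluded. The resolution rule is
invariant under replicate order.

Association is a single-locus fixed-effects one-way ANOVA on per-variety
means (environments flattened before testing), run per region and
combined, with ambiguous/null genotypes excluded and counted. Fisher's
LSD at α = 0.05 and 0.01 uses
t(1 − α/2, df_within) · sqrt(MSW · (1/nᵢ + 1/nⱼ)), with letters assigned
by descending-mean grouping. Degenerate inputs are defined explicitly:
zero within-group variance gives F = 0 (equal means) or F = ∞ with p = 0
(unequal means). Population structure, kinship and multiple-marker
correction are out of scope. The implementation computes the sums of
squares directly (the LSD needs MSW); `scipy.stats.f_oneway` and the
pooled-variance t-test (F = t²) serve as independent cross-checks in the
tests.

## Synthetic data: what it emulates

All generators draw from a single `numpy` generator seeded explicitly;
identical seed and configuration give byte-identical outputs, and every
generator returns its ground truth.

* **Panels/matrices** reproduce the real panel's composition by default
  (21 NT lines, Dt pairs, and the 38 group-7 deletion breakpoints) and
  derive error-free calls from the deletion geometry, with optional
  independent false-absent/false-present flips.
* **Allele pairs** default to the study's dimensions: 20-bp 5′ UTR,
  1074-bp ORF (357 residues), 27-bp 3′ UTR, GC 0.695 (the GC-richness
  typical of cereal POD coding sequence), 21 exonic substitutions and one
  6-bp "GCTGTG" insertion after ORF base 42 (adding Ala-Val after residue
  14). SNPs are placed uniformly with ≥ 2-bp spacing, sparing the start
  and stop codons and an 8-bp flank around the insertion so the planted
  indel keeps a unique context — without that flank an optimal alignment
  can legitimately trade a SNP against two split gaps, and recovery is
  then a property of the alignment, not an error of the caller. No
  substitution may create a premature stop.
* **Templates** share one reverse-primer site (the two real assays'
  reverse primers are one a suffix of the other) and carry both forward
  sites at offsets implied by the 540/640-bp product sizes; the
  off-target assay's forward site gets a 3′-terminal mismatch. Planted
  sites sit in random backbone, so accidental secondary sites are
  vanishingly unlikely but not impossible in principle.
* **Variety panels** default to the published dimensions: 224 varieties
  in groups 83/64 (one winter-wheat region) and 32/45 (the other), with
  the per-(region, allele) mean activities on the 650–760 U min⁻¹ g⁻¹
  scale, between-variety SD 80, replicate CV 5%, and a third replicate
  drawn whenever a duplicate breaches the 10% CV rule. Phenotype noise is
  normal; real activity distributions may be skewed or heavier-tailed,
  and the generator does not model genotype × environment interaction
  beyond the per-region means.

Passing tests on these generators therefore demonstrate correctness of
the inference machinery under the stated noise models — not robustness to
every artefact of real gels, sequencing chemistry or field trials.

## Problem sizes and calibration checks

The statistical acceptance checks use Monte-Carlo sizes chosen to keep the
whole suite fast while leaving binomial error well below the effects being
detected: 100 random panels for the bin oracle equivalence, 50 generator
seeds for exact variant recovery, 200 null panels for type-I calibration
(±3·binomial SE band), and 100 effect panels compared against the
closed-form power of the corresponding two-sample test (with a 5-point
allowance for the replicate-noise inflation of the per-variety SD).

## Known limitations

* Bin inference assumes a single-copy marker per genome; multi-locus
  amplification only surfaces through the NT contradiction flag.
* The merge step handles clean Sanger-style amplicons (exact overlaps);
  it is not a general assembler and tolerates no sequencing error.
* The PCR model has no thermodynamics: a primer with a tolerated internal
  mismatch binds as well as a perfect one.
* Identity percentages depend on the alignment and denominator
  convention; they are property-tested (monotone in planted mutation
  load) rather than anchored to published values, which were produced by
  different software.
* The association module deliberately omits population structure and
  kinship corrections; it reproduces a single-locus test, not a modern
  GWAS.
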