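# Methods

`compartmeth` re-implements an integrative chromatin-architecture /
DNA-methylation analysis as a reusable pipeline: A/B compartment and TAD
inference from binned Hi-C matrices, whole-genome bisulfite methylome
segmentation and differentially-methylated-region (DMR) calling with
fixed numeric thresholds, and the statistics that tie methylation
features to compartments. Because the original sequencing datasets are
far beyond desk scale, every claim the package makes is exercised on a
synthetic multi-stage cohort with complete planted ground truth; this
note records the models, the defaults and the design choices, and what
the synthetic results do and do not show about real data.

## Hi-C side

**Matrix model.** Input is a symmetric per-chromosome matrix of contact
counts on fixed 40-kb bins. Analysis is strictly intra-chromosomal.

**ICE balancing.** Iterative proportional fitting per chromosome until
every unmasked row sum is within a relative tolerance (default 1e-5,
maximum 200 iterations) of the mean row sum. Bins whose raw coverage
falls below the 2% quantile of nonzero row sums, and zero-coverage bins,
are masked first. The quantile is an automated stand-in for per-dataset
manual coverage thresholds, which are inherently dataset-specific; it is
exposed in the configuration. A naive alternating row/column
normalization serves as an independent oracle in the tests.

**Expected profile and O/E.** The expected contact at bin distance d is
the mean balanced contact over unmasked pairs at that distance.
Observed/expected ratios at distance 0 are defined but the main diagonal
is excluded from the correlation computation, since self-contacts
dominate the variance.

**Compartments.** Per chromosome, the Pearson correlation matrix of O/E
rows is eigendecomposed; the leading component (scaled by the square
root of its eigenvalue) is the compartment eigenvector, with A for
PC1 > 0 and B for PC1 < 0. Exactly zero is left unassigned — the sign
convention does not define it. Two choices deserve note:

* *Component selection.* Occasionally a lower component carries the
  compartment pattern for part of a chromosome. Rather than curating
  such cases by hand, the caller examines the first three components and
  keeps the one with the largest |Pearson correlation| with a per-bin
  activity track (gene density, expression, or any active-chromatin
  proxy); the choice is recorded in the run log. The component is then
  oriented so that this correlation is non-negative, which pins A to
  active chromatin. Orientation evidence below |r| = 0.1 is flagged.
* *Standardization.* The differential rule below uses an absolute
  threshold (ΔPC1 ≥ 1), which presupposes a scale. PC1 tracks are
  variance-standardized per chromosome before differential calling
  (configurable off), making the threshold meaningful on any input.

**Differential compartments.** A bin qualifies when the two samples'
PC1 signs differ and |PC1_a − PC1_b| ≥ δ with δ = 1; a region is a
maximal run of at least two consecutive qualifying bins of uniform
direction (runs split where the direction changes). A brute-force
per-bin scan re-derives the rule independently in the tests.

**Common compartments** are bins with the same sign in every sample of
a cohort; a bin unassigned anywhere is unassigned, everything else is
dynamic.

**TAD insulation.** For window depth w and bin i, the diamond mean is
the mean balanced contact over [i−w, i) × [i, i+w). Depths run from
300 kb to 3 Mb in 300-kb steps; each depth is converted to a whole
number of bins by rounding (300 kb is 7.5 bins of 40 kb; the rounded
set is deduplicated and logged). Per scale and chromosome the track is
z-transformed over defined bins, and the final score is the mean over
scales; bins whose diamond does not fit at a scale are masked at that
scale rather than padded. Boundaries are local minima with prominence
≥ 0.5 z-units (a deliberately simple criterion; the analysis this package
re-implements fixes only the depths and the minimum distance), selected
greedily from the deepest minimum upward under a 400-kb minimum pairwise
distance.

## Methylome side

**Calls.** Per-cytosine records (chrom, 0-based position, strand,
context CpG/CHH, methylated count, total count). The two strands of a
CpG are summed onto the forward-strand position before any analysis;
counts are conserved exactly.

**Segmentation.** The partition into UMR / LMR / FMR / PMD fixes only
two constraints a priori: PMDs shorter than 100 kb are excluded (they
mostly reflect partially demethylated gene bodies of highly expressed
genes), and FMRs must average at least 85% CpG methylation. The
concrete algorithm around those constraints is this package's declared
default, consistent with CpG-methylation-guided segmentation
methodology:

1. *PMDs.* A two-state hidden Markov model (ordered vs disordered) over
   per-CpG levels discretized to low (< 0.3) / mid (0.3–0.7) /
   high (> 0.7); emissions favor high in the ordered state and mid in
   the disordered state, stay probability 0.997. Maximal disordered runs
   are PMD candidates; candidates under 100 kb are discarded (kept in a
   sidecar for inspection) and their CpGs re-enter step 2. Decoding uses
   Viterbi with fixed, not fitted, parameters.
2. *UMR/LMR.* Outside PMDs, levels are smoothed with a 3-CpG running
   mean; maximal runs below 0.5 with ≥ 4 CpGs are hypomethylated
   segments — UMRs when ≥ 30 CpGs (long, CpG-rich, promoter-like), LMRs
   otherwise (short, distal-regulatory-like). The 0.5 cutoff, 3-CpG
   window and 30-CpG split are configurable defaults.
3. *FMR.* Remaining stretches with mean level ≥ 0.85 and ≥ 5 CpGs
   (the 5-CpG floor avoids single-CpG FMRs); anything left is
   unclassified.

CpGs below a coverage floor (default 4, mirroring the DMR rule) are
excluded throughout.

**DMR calling.** Purely threshold-based, no test statistic: eligible
CpGs are present in both samples with coverage ≥ 4 in both and per-CpG
|Δ| ≥ 10%; a window of 5 consecutive eligible CpGs with uniform Δ sign
and adjacent gaps ≤ 1 kb qualifies when its mean |Δ| ≥ 40%; overlapping
qualifying windows of one sign merge into a region from the first to
the last CpG (end-exclusive at last position + 1). Two readings were
open: "over five CpGs" is implemented as a sliding window with merging
(a fixed partition would drop boundary-straddling regions), and sign
uniformity within a region is enforced, since hyper- and hypomethylated
regions are reported as distinct classes. The gap rule measures genomic
distance between adjacent *eligible* CpGs; ineligible CpGs in between do
not reset it. A window-enumeration oracle with no shared code
cross-checks the scanning implementation on randomized inputs.

**CHH.** Non-CpG calls are pooled into 1-kb bins (summed counts; the
bin level is the ratio of sums, not the mean of ratios) to raise the
effective coverage. Bins without CHH records are masked.

## Integration statistics

Features are assigned to A or B by majority base overlap (> 50%); exact
ties stay unassigned (no canonical assignment rule exists; majority
overlap is the declared choice). Signal enrichment
is the mean signal in a selected bin set (A-compartment bins, or bins
inside context intervals such as FMRs) over the genome-wide mean.
Significance uses seeded circular-shift permutation tests — the feature
set or signal track is rotated around each chromosome by a random
offset and the statistic recomputed (default 1,000 shifts); the
p-value is (1 + #{permutations ≥ observed}) / (n + 1). Circular shifts
respect genomic autocorrelation and need no distributional assumptions,
which is why they replace a parametric group test here; the tests
verify the p-values are calibrated on label-free nulls. Sample PCA
mean-centers jointly defined columns and reports the top-2 embedding,
with each axis oriented so the first sample's coordinate is
non-negative.

## The synthetic cohort

The generator emulates a six-sample differentiation cohort — ES,
progenitor, fetal, newborn, adult, and an adult knockout lacking the de
novo DNA methyltransferases — on a 2 × 20 Mb genome at 40-kb bins.

**Contacts.** Expected intensity is multiplicative: distance decay
(1+d)^(−α) with α = 1, a compartment plaid (same-label × (1+ε),
cross-label × (1−ε), ε = 0.4), and a within-TAD boost × (1+τ), τ = 1.
Counts are multinomial with 10^6 read pairs per chromosome, so totals
are conserved exactly. Compartment blocks span 12–24 bins; a few blocks
switch label at the progenitor or fetal stage; the knockout shares the
adult compartment truth exactly (ablating DNA methylation does not
reorganize compartments in this model). TAD boundaries comprise every
compartment block edge plus internal splits, always ≥ 480 kb apart.

**Methylomes.** CpG positions are laid down once (geometric spacing,
mean 100 bp) and shared by all stages and genotypes, so per-CpG deltas
need no matching logic. True levels follow the planted region class:
FMR ~ Beta(27, 3) (mean 0.90), LMR ~ Beta(3, 12), UMR ~ Beta(1, 24),
PMD per-CpG Uniform(0.3, 0.7) ("disordered"). Counts are binomial at
Poisson coverage with mean 30 — deep-coverage WGBS of the kind used for
threshold-based DMR calling. The coverage default is a power
consideration: at 30× the standard error of a per-CpG level estimate at
intermediate methylation is ≈ 0.09, placing the 40%-mean window
threshold far above the sampling-noise floor; at shallow coverage the
printed rule would pick up spurious windows inside PMDs. Counts are
emitted per strand (the combined total split hypergeometrically) so
strand combining is genuinely exercised.

**Feature dynamics.** Methylation features follow compartment switches
with a one-stage lag (configurable; the real lag is not quantified, so
it is a parameter, not a constant): LMRs and UMRs live in (lagged) A
blocks at every stage, PMDs appear in B blocks from the fetal stage
onward — which produces B-hypermethylation relative to A in the
ES/progenitor stages and the reverse after PMDs form — and adult-only
features are planted DMRs (hypomethylated in the knockout by ≥ 0.5,
with counts band-truncated so that every planted CpG satisfies the
caller's eligibility with margin) and CHH-positive regions inside
A-compartment FMRs. CHH sites exist genome-wide at low background
methylation (1%), rise to 20% inside CHH-positive adult regions, and
carry exactly zero methylated counts in the knockout. Planted DMRs are
flanked by > 1-kb CpG-free gaps so their extent is unambiguous under
read noise.

**What the synthetic results do not show.** The generator has no
restriction-fragment structure, no read-level errors, no copy-number or
mappability artifacts, no CpG-island clustering beyond the planted
UMRs, and its plaid is exactly two-state — so passing tests demonstrate
the pipeline's correctness and calibration under the stated model, not
performance on the idiosyncrasies of real libraries.

## Problem sizes and numerics

The default cohort (1,000 bins, ~4 × 10^5 CpGs, 10^6 contacts per
chromosome per sample) runs end-to-end in well under a minute per
sample on one core; these sizes were chosen so that the complete test
suite and the reproduction script stay desk-scale. Degenerate inputs
are handled explicitly: chromosomes with fewer than three usable bins
yield unassigned compartments; all-zero matrices are an error; empty
call sets segment to nothing; zero-signal tracks report "no signal"
rather than an infinite fold. Determinism is end-to-end: one global
seed derives per-module sub-seeds through `SeedSequence` with hashed
module keys, so identical configuration and seed reproduce every output
byte-for-byte, and adding a module never perturbs another module's
stream.
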