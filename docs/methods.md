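# Methods

This note documents the models, defaults and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The scientific setting

In *Arabidopsis*, DDM1 maintains DNA methylation of heterochromatic
transposable elements (TEs); in *ddm1* mutants these TEs lose methylation
and a subset acquires the Polycomb mark H3K27me3 (deposited by PRC2, whose
catalytic subunit here is CLF). Removing CLF on top of *ddm1* lets DNA
methyltransferases partially remethylate TEs — but only on the short
stretches of linker DNA between nucleosome core particles, producing ~20-bp
hypermethylated segments spaced one nucleosome repeat length (NRL, ~150 bp)
apart and phased to well-positioned nucleosomes. The pipeline quantifies
each piece of that story: spike-in-normalized H3K27me3 changes, short-DMR
discovery, methylation periodicity, TE mobilization, and the set statistics
that tie them together.

## Synthetic epigenome generator (`epiphase.simulate`)

**Genome layout.** Random uniform background sequence; TEs and genes placed
uniformly without overlap (greedy rejection sampling; an error is raised if
packing is infeasible). A central span of 40% of each chromosome is
declared pericentromeric and a central 2% is masked as centromeric repeats.
Defaults: 2-Mb single chromosome, 120 TEs of 2–8 kb drawn from six family
consensus sequences, 150 genes of 1–3 kb. `GenomeSpec.scaled(length)`
preserves feature density at other genome sizes.

**TE consensus sequences** are first-order Markov chains with P(G | C) =
0.5. Rationale: plant TE bodies are CpG-dense, and CG-context DMR calling
in 20-bp windows needs CG dinucleotides to test — under a uniform
composition ~29% of 20-bp windows contain none and are untestable at the
two-cytosine floor. Each planted TE copy carries its consensus with 2%
random substitutions, so consensus-based evidence collection is exercised
against diverged copies.

**Nucleosomes and linker patches.** Centers are phased every NRL (default
150 bp) across each TE body; the core particle footprint is 130 bp. A
hypermethylation patch of 20 bp is recorded mid-linker between consecutive
centers — with the default geometry the patch exactly fills the linker and
never intersects a core. The `snap_patches_to_grid=20` option rounds patch
starts to the 20-bp window grid for geometry measurements; because 150 is
not a multiple of 20, snapping shifts alternate patches by ±5 bp (so
snapped patches may clip core edges by up to 5 bp, and consecutive snapped
patch centers alternate 140/160 bp apart — the reported median spacing of
recovered DMRs is therefore 160, the grid's nearest representation of the
150-bp repeat).

**Methylomes.** For every reference cytosine (contexts CG/CHG/CHH called
on both strands), coverage is Poisson (mean 30 by default) and the
methylated count Binomial(coverage, p) with p given by the genotype's
baseline for the cytosine's context and region class (pericentromeric TE,
arm TE, gene, intergenic), plus a linker gain inside patch intervals.
Baselines (CG/CHG/CHH in pericentromeric TEs): WT and *clf* 0.85/0.60/0.15;
*ddm1* and *ddm1 clf* 0.20/0.10/0.05. The *ddm1 clf* linker gain is
0.55/0.30/0.10, i.e. patches remethylate toward wild-type heterochromatic
levels. The gain deliberately clears the caller's 40-point CG cutoff with
margin: a gain exactly equal to the cutoff is recovered for only ~half the
patches at any coverage (the measured difference is centred on the
threshold), which would misrepresent the phenomenon being emulated — in the
real data the discovered short DMRs necessarily exceeded the cutoff and
their ~150-bp spacing implies consecutive patches were detected. A unit
test documents this knife-edge property at a planted +40 gain.

**ChIP counts.** Immunoprecipitated material per feature is
multiplier × length; a constant exogenous spike-in mass (default 5% of the
unit-multiplier target mass) competes for the library's reads. Feature
counts are gamma-Poisson (negative binomial, dispersion 0.1 — the standard
count model for ChIP-seq replicates); the spike-in IP tally `Nd_IP`
is Binomial over the library size. Because the spike mass is constant, the
ratio of Rx-normalized totals between two libraries estimates their true
global signal ratio irrespective of sequencing depth.

**Insertion read sets.** A haplotype is built per library by inserting the
donor TE's genomic copy at uniformly drawn sites, rejecting (and logging)
sites inside the donor span, the centromere mask, or any annotated TE span
(a split-read caller cannot anchor junctions inside repeats — planting them
there would make truth unreachable by construction, not by defect).
Error-free paired-end reads (100 bp, inserts 300 ± 30 bp) are drawn to 30×
and retained only if a mate overlaps a capture probe window (200 bp at each
end of every donor-family TE copy, planted copies included). Truth tables
give reference-coordinate junctions.

**What the generator does not emulate:** real sequence composition and
repeat structure, sequencing errors and mapping ambiguity beyond exact
repeats, bisulfite conversion failure, batch effects, fragment-size biases,
and chromatin-state heterogeneity along TEs. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under clean,
truth-known conditions, not robustness to real-data artifacts.

## Spike-in ChIP (`epiphase.chip`)

`Rx = r / Nd_IP` exactly, with `r` a percentage in (0, 100]; zero or
negative inputs raise "unusable spike-in". Marked-feature calling replaces
a peak caller with a per-feature test — the analysis unit throughout is the
annotated TE/gene — using a one-sided Poisson tail with the depth-scaled
input count plus a 0.5 pseudocount as rate, BH-controlled at 0.01
(conservative; no peak-caller parameters were given to mirror).

Differential marking replaces DESeq2 with a negative-binomial Wald test:
log2FC = log2((mean_B + 1)/(mean_A + 1)); the common dispersion is the
pooled method-of-moments estimate Σ(var − μ)/Σμ² across features within
conditions that carry replicates (a per-feature or median estimator is
badly biased at two replicates), with a Poisson fallback when the estimate
is ≤ 0. The variance of the log-fold-change is evaluated at the pooled null
mean (score-test style) and the statistic is referred to a Student t with
the classical two-sample degrees of freedom, which keeps the null rejection
rate at p < 0.1 below 10% at two replicates per condition (a plain normal
reference is anti-conservative there) while leaving 8-fold effects at full
power. Acceptance is by parameter recovery, not numeric equality with
DESeq2. Whether DESeq2 size factors should be disabled when applying Rx is
undocumented in the source protocol; this implementation applies Rx only.

Metaprofiles rescale each feature body into n bins plus fixed-width flank
bins; heat-map rows sort by descending mean with ties broken by feature id
so outputs are deterministic.

## DMR calling (`epiphase.dmr`)

Windows tile each chromosome from coordinate 0 (the original grid origin is
unstated). A cytosine counts toward a window only when covered by ≥6 reads
(CG, CHG) or ≥10 (CHH) in *every* library; a window is tested only when ≥6
cytosines qualify (100-bp mode) or ≥2 (20-bp mode — six is geometrically
impossible for most 20-bp windows; the floor is configurable and documented
as an inference). Replicates are pooled per condition and each window gets
a two-sided Fisher exact test on the pooled 2×2 table (implemented
vectorised over the hypergeometric support; property-tested against exact
integer enumeration and scipy), BH within context and run. A window is
differential when q < 0.05 and the coverage-weighted difference
(100·Σm/Σt, condition B minus A) clears the context cutoff — 40 points CG,
20 CHG/CHH, read as percentage points. Same-direction windows within one
window size merge; merged differences are recomputed from pooled counts and
q is the member minimum (merging is idempotent and order-independent).
Short-DMR discovery composes these with a TE intersection rule: a DMR is
TE-specific when ≥50% of its length lies in a TE.

## Periodicity (`epiphase.periodicity`)

Anchored profiles take per-position methylation fractions (pooled across
strands) at ±flank (default 1000 bp) around anchors; anchors nearer than
the flank to a chromosome end are excluded and uncovered positions are
missing, ignored by column means. Two anchor modes exist — DMR centers or
nucleosome centers — because the procedure is two-stage: DMRs select the
loci; centers of well-positioned nucleosomes within 100 bp of a DMR anchor
the headline profile.

The periodogram linearly interpolates missing values (error above 20%
missing), removes the mean and a linear trend, applies a 10% split-cosine
taper (the classical default; the recovery property holds with the taper on
or off), and reports power |X_k|²/n at frequencies k/n, k = 1..n/2. The sum
of power × 2/n equals the variance of the preprocessed profile to 1%
(Parseval; tested). The dominant period is 1/argmax restricted to periods
in a band (default 50–500 bp, the plotted neighbourhood; exact range
unstated in the source), ties broken toward the lower period. At the
default ±1 kb flank (n = 2001) the grid has no exact 150-bp frequency; a
planted 150-bp repeat peaks at k = 13 (153.9 bp), which rounds to 150.
Periodograms are computed on the averaged profile, not averaged over
per-anchor periodograms. Linker phasing splits positions at the occupancy
median and reports group means plus the Pearson correlation of the
methylation and occupancy profiles.

## Insertion calling (`epiphase.insertions`)

Reads are mapped by exact 20-mer seeding with maximal exact extension,
both orientations; among equal-score placements exactly one is kept
(lowest reference in index order, then coordinate, then forward strand), so
calling is deterministic and invariant to read order. Soft clips ≥15 bp on
reads anchored outside annotated TEs are remapped by exact substring search
into annotated TE sequences and the consensus library (clips may be shorter
than the seed, hence substring search rather than seeding); a clip landing
in a TE gives split evidence whose side follows the clip orientation.
Pairs with mates >1 kb apart (or on different references), one mate in TE
sequence and one anchored in unique genome, give discordant evidence at the
anchor. Evidence clusters per family within 200 bp (≈ the probe span).
Calls require ≥1 split and/or discordant read on each side; the call
interval is bounded by junction estimates with split positions preferred
(base-exact on clean data; maximal exact extension can absorb 1–2 bp of
chance microhomology, so ≤5 bp positional error is the guarantee).
Exclusions: overlap with the same family's donor span (`donor_span`), the
centromere mask (`centromeric`), or a matching call (same family and
chromosome, centers within 100 bp) in another library (`multi_library`).
min_clip = 15, max_cluster = 200 bp and the 100-bp matching radius are
package defaults (unstated in the source tool), all configurable. Target
site duplications are not modelled.

## Set statistics (`epiphase.setstats`)

Overlap enrichment: expected = |A|·|B|/N, fold = observed/expected, exact
upper-tail hypergeometric p. The universe N is always an explicit input —
annotation totals are never hard-coded, because published fold values
depend on an unprinted universe choice. Motif enrichment scans IUPAC
patterns on both strands (defaults: Telobox TTTAGGG, CTCC×2, (GA)×4,
(AC)×5 — the published motif catalogue prints no explicit patterns, so
these are overridable defaults) and tests each 2×2 table with Fisher exact
at α = 0.05 (the figure legend's "t test, Pval < 0.5" is presumed a typo; a
proportion-z alternative and the threshold are config options). Family
composition uses a chi-square goodness-of-fit of set counts against
background proportions with categories pooled below an expected count of 5.
Allele fractions are 100·G/(G+T) at the EVD/ATR-discriminating SNP.
Fold-change summaries report medians and quartiles per group with Welch
t-tests against a reference group, skipped with a warning below two
observations.

## Problem sizes and determinism

The acceptance study uses a 2-Mb genome with 30× methylomes (≈1 M cytosine
records per genotype; ~2,700 planted patches), and the test suite shares a
300-kb genome across modules; both finish in minutes on one CPU while
leaving hundreds-to-thousands of planted events per measurement. One master
seed drives everything through named `SeedSequence` substreams, so any
stage can be reproduced in isolation; identical runs produce byte-identical
output files (stable sorts, deterministic tie-breaks).

## Known limitations

- The exact-match mapper is for error-free reads; real libraries need a
  real aligner, whose output the insertion module accepts as a DataFrame.
- Poisson feature marking is anti-conservative under biological
  overdispersion between IP and input; it targets the simulated technical
  regime and the published thresholds, not DESeq2 equivalence.
- The 20-bp window grid cannot express a 150-bp phase exactly; all
  geometry read off that grid is quantized to ±10 bp.
- Fisher-based DMR testing pools replicates and therefore ignores
  between-replicate variance (as does the Fisher mode of the tool it
  mirrors); stochastic single-replicate artifacts are controlled only by
  the difference cutoff.
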