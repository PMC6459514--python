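# Methods

## The assay model

Each target variant is assayed by a probe triple: two allele-specific 5'
probes whose 3' terminus sits on the variant base (or, for deletions,
reads across the deletion junction), and one common 3' probe annealing
immediately downstream. A thermostable ligase joins a 5' probe to the 3'
probe only when the 3'-terminal base matches the template, and a second
(labelling) ligation attaches the dye oligo selected by the 5' tag
sequence. The observable per allele is therefore one fluorescent fragment
with a characteristic dye channel and electrophoretic size; four dye
channels (B, G, Y, R) and stuffer-length shifts on the 3' probe give the
panel designer a two-dimensional address space.

`ligatyper` models the assay at the product level: a panel is a set of
variants, each mapping its alleles to (dye, expected size) addresses. One
panel locus may be tri-allelic (one site, two pathogenic substitutions),
in which case it owns three products; the built-in 32-variant
hearing-loss panel has one such locus and hence 65 products.

## Layout design

`design.assign_layout` places products on a discrete grid of size slots.
The slot pitch is the smallest stuffer-step multiple that covers the
minimum same-dye separation (defaults: step 2 nt, separation 3 nt, hence
pitch 4 nt over the 80–260 nt window). Greedy first-fit assigns each
locus the first slot with enough free dyes; all alleles of one locus
share a slot on distinct dyes (the convention that same-size products are
separated by dye), with ties broken by variant order then dye order
B < G < Y < R, so the assignment is deterministic. A fallback lets a
locus straddle two adjacent slots when no single slot has enough free
dyes. For designed probe sets the slot must be at least the natural
(stuffer-free) product length, so stuffers are never negative.
`panel.validate_layout` is the decodability oracle: it reports every
same-dye product pair closer than twice the sizing tolerance
(default 1.5 nt), i.e. every pair a measured peak could not resolve.

The minimum same-dye separation of 3 nt and the 80–260 nt window are
conventional fragment-analysis choices; one-basepair resolution is
routine on capillary instruments, so a 1.5 nt matching tolerance is
conservative for the products modelled here.

## Probe design

Anneal regions are grown from the flanks (18–35 nt) until their duplex
melting temperature falls within the target window (62 ± 3 °C). Tm uses
nearest-neighbor thermodynamics with the unified dinucleotide parameter
set, terminal A/T and G/C initiation penalties, the self-complementarity
entropy correction, and the entropic monovalent-salt correction
ΔS += 0.368 (N−1) ln[Na+], at 50 mM Na+ and 250 nM per-strand oligo
concentration:

    Tm = 1000 ΔH / (ΔS + R ln(C/2)) − 273.15   (non-self-complementary)

SNV alleles are discriminated by the single 3'-terminal base; deletion
alleles by a junction probe ending in the first 1–3 downstream bases
(up to the deleted length). The implementation is cross-checked in the
tests against Biopython's independent nearest-neighbor implementation
with the same parameter table.

## Amplicon grouping

Multiplex-PCR coverage is modelled as single-linkage grouping of targets
by per-contig offset: consecutive sorted targets closer than the maximum
amplicon length share a fragment. A greedy sweep is optimal for this
interval structure. The built-in panel carries plausible relative
placements derived from the cDNA numbering and intron structure (the
source material gives no coordinates), which group its 32 targets into
exactly 18 amplicons.

## Peak simulation

The simulator emits peak-level data only (no raw traces). For each locus
the genotype fixes allele weights: 1 for a homozygote; for heterozygotes
the alt share is 0.5 plus Normal(0, 0.05) jitter, clipped to [0.3, 0.7];
mitochondrial loci weight ref/alt by the homoplasmy fraction. Locus
signal is lognormal (median 1000 RFU, log-SD 0.25) and is split between
alleles by weight. Peak size is the product's expected size plus
Normal(0, 0.15 nt) jitter — about 3.3σ inside the ±0.5 nt band and far
inside the 1.5 nt matching tolerance, which is what makes near-perfect
decoding the expected behaviour rather than an accident. Spurious
baseline peaks arrive as Poisson(2) per sample with uniform size and dye
and bounded uniform heights (20–80 RFU), deliberately below the 100 RFU
detection threshold: real analysis software applies exactly such an
amplitude threshold before genotyping. Per-sample seeds are spawned
deterministically from the cohort seed.

The instrument's raw migration coordinate follows a reciprocal-mobility
curve m = m0 + c/(L0 − L), the relationship the local Southern sizing
method models; the ladder (13 fragments, 60–300 nt every 20 nt) is
rendered through the same curve, so size calling must genuinely invert
the instrument response.

What the simulator does **not** emulate: stutter and pull-up artifacts,
baseline drift, saturation, inter-run mobility shifts, and degraded-DNA
dropout (dropout probability defaults to 0). Passing round-trip tests
therefore demonstrate that the decoding logic is correct and robust to
sizing/height noise of the stated magnitude — not that the assay would
survive every instrument pathology.

## Size calling

Peaks are sized by the local Southern method: within ladder segment
[L_i, L_(i+1)] the reciprocal curve L = L0 + c/(m − m0) is fitted through
ladder points (i−1, i, i+1) — a closed-form 2×2 linear solve after
differencing — and evaluated at the peak's migration. The first segment
and degenerate (collinear) fits fall back to linear interpolation. Using
one fixed point triple per segment makes the map continuous (adjacent
fits share the segment endpoints) and strictly monotone, since three
increasing points force the fitted pole outside the segment. Peaks
outside the ladder span are linearly extrapolated and flagged
``off_size``.

## Genotype calling

Matched peaks below the 100 RFU detection threshold are treated as
absent. A locus with no signal is a no-call (``low_signal``). Nuclear
loci: single-allele signal calls the homozygote; dual signal calls het
for allele ratio in [0.25, 0.75], the majority homozygote for ratio
< 0.1 or > 0.9, and a no-call (``ambiguous``) in the dead zones between —
bands that follow common fragment-analysis practice and are exposed on
`CallThresholds`. Mitochondrial loci report the alt share as the
homoplasmy fraction: ≥ 0.95 homoplasmic alt, ≤ 0.05 reference, otherwise
heteroplasmic with the fraction attached. At a tri-allelic locus the
tallest alternate allele carries the call.

Concordance is counted per (sample, locus): sensitivity over
truth-positive pairs requires the exact zygosity (a het/hom mix-up is
discordant), specificity over truth-reference pairs requires a reference
call.

## Cohort fixtures

The fixture generators expand printed per-variant counts into per-sample
truth sets and are pure functions of (panel, seed) — the seed only
shuffles sample order.

* **Validation set (49 cases).** The printed per-variant counts are taken
  as one-primary-finding-per-patient (29 het + 20 hom = 49, which is the
  printed total); the listed compound findings are layered as second
  variants onto samples already carrying the listed first variant.
  Cross-gene pairs (e.g. a *GJB2* het plus the mitochondrial 1555A>G) are
  dual-gene findings, not compound heterozygotes. Mitochondrial carriers
  are homoplasmic (fraction 1.0).
* **Controls (50).** Five distinct single-het carriers, 45 variant-free.
* **Patient cohort (171).** `cohort_from_counts` realises compound pairs
  first (both members het in one sample, drawn from the per-variant het
  supplies), then the remaining het and hom counts as single-finding
  samples, so the per-variant marginals equal the inputs exactly. The
  printed marginals and pair list are mutually inconsistent for one pair
  (its demand exceeds the remaining het supply of one member); strict
  mode raises, and the default reconciliation mode caps the pair count at
  the available supply with a warning — pairs are capped in listed order,
  so the oversubscribed pair receives what is left after earlier pairs.
  Marginal counts, and hence every per-variant frequency and rate, are
  preserved either way.

## Cohort summary semantics

Summary counting uses variant-carrier *entries* — one per (sample,
variant) with a non-reference call. Only this semantics reproduces the
per-variant frequencies, the per-gene counts, the overall detection rate
and the het/hom split simultaneously on the built-in cohort (57 entries
in 171 patients: 35 het + 22 hom; 30 of them in *GJB2*, of which 16 are
c.235delC); a deduplicated patient-level carrier count is reported
alongside (`n_carrier_samples`). Diagnostic yield counts only samples
whose genotype alone is explanatory under the gene's inheritance mode —
recessive homozygotes and homoplasmic mitochondrial carriers; same-gene
double hets are reported as *possible compound het, phase unknown* and
excluded from the yield, since phase cannot be established without
parental data. Classification precedence is: recessive homozygote >
homoplasmic mitochondrial > same-gene double het > dominant positive >
X-linked positive > carrier (single recessive het or heteroplasmic
mitochondrial) > negative. *GJB3* is treated as recessive, matching the
interpretation applied to the built-in cohort; the inheritance table is
data, not code, and can be overridden per panel.

## Numerical and degenerate-input choices

* Layout and fixture generation are fully deterministic given their
  seeds; the layout solver uses no randomness at all.
* The collision checker sorts within dye and sweeps, returning every
  offending pair (verified against brute-force all-pairs enumeration).
* Ladders must have ≥ 4 strictly increasing points; collinear ladder
  triples fall back to linear interpolation; peaks outside the span are
  flagged rather than dropped.
* Duplicate variant names, products outside the size window, and layouts
  with same-dye collisions are rejected at panel load time.
* In the built-in panel the printed allele column of one *GJB2* variant
  contradicts its name (T/C vs T>G); the name is authoritative and the
  discrepancy is recorded in the panel's notes. One printed cohort
  frequency (64.33% where the counts give 6.43%) is a typo and is not
  asserted anywhere.

## Problem sizes

The test suite and the acceptance script run the complete cohorts the
fixtures define (49 + 50 + 171 samples, 32 loci, 65 products) and the
property checks use 100 random panels and 1000 simulated samples; the
whole suite completes in a few seconds on one CPU.
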