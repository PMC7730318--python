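# Methods

## Coordinate and counting conventions

All genomic intervals are 0-based half-open (BED). A gene is anchored by
one TSS coordinate and a strand; TSS-relative offsets are
`center − tss` on the + strand and `tss − center` on the − strand, so
the promoter window of offsets [−300, +200) covers bases
[tss−300, tss+200) on the + strand and [tss−199, tss+301) on the −
strand. The window is half-open over integer offsets, i.e. exactly 500
positions — consistent with the Bonferroni denominator m = 500 used in
the scan.

A nucleosome positioning site contributes one count at the single offset
of its integer centre `floor((start+end)/2)` (the rounding direction is a
convention; interval coverage is deliberately not used, since the
analysis is about positioned nucleosome centres). Nucleosome maps are
strandless; extra BED columns are ignored.

## Classification

* RPKM classes: Silent = exactly 0; Modest = [1, 25]; High = (25, ∞).
  Values in (0, 1) fall in a gap of these bounds; the default bins them
  as Modest (keeping "Silent" = exactly zero), configurable to
  Unclassified (`gap_policy`).
* BoE: the count of tissues whose RPKM **strictly** exceeds the
  threshold (default 3). Classes: ≤ 6 tissue-specific, 7–24 modest,
  > 24 constitutive. The published bound "6 > BoE ≤ 24" is read as
  6 < BoE ≤ 24, the only reading that makes the classes a partition.
* Chromatin class: Active requires the *entire* promoter window covered
  by Active-group domains; NonActive allows any mixture of inactive
  states (an intermediate-state domain abutting another inactive domain
  is still NonActive). Gaps in coverage, mixed groups, missing
  chromosomes, or windows reaching negative coordinates yield
  Unclassified (recorded, not fatal). Two built-in mappings:
  4-state (Aquamarine vs Lazurite/Malachite/Ruby) and 5-state
  (Yellow/Red vs Green/Blue/Black).

## Profiles and peaks

Average profiles are per-offset column means over a gene set, smoothed
with a centred moving mean (default window 3 nt). At the vector edges
the window shrinks to the available positions so the profile keeps its
500-nt length (truncation would silently shorten it).

`find_peaks` ranks strict local maxima of the smoothed profile by
height; exact ties break toward the offset nearer zero, then negative
first. Maxima within `min_distance` (default 50 nt) of an already
accepted higher peak are suppressed: on a noisy profile the flank of one
broad peak carries spurious shoulder maxima, and 50 nt is well below the
canonical ~150–175 nt nucleosome repeat, so distinct nucleosomes are
never merged.

## Position-wise Kendall scan

At each offset the per-gene counts are correlated with the covariate
using tau-b (tie-corrected in the *statistic*):
τ = (C − D)/√((P − Tx)(P − Ty)). Significance uses the classical normal
approximation with mean 0 and variance D = 2(2N+5)/(9N(N−1)), two-sided,
Bonferroni-masked at α/m with m defaulting to the number of scanned
offsets (500). Offsets whose count column is entirely tied (e.g. all
zero) have undefined τ and are reported as missing, never as zero, and
are never significant.

The classical variance ignores ties. Monte-Carlo checks during
development showed it is well calibrated for deep count columns
(approximately Poisson with mean ≳ 10: uncorrected p < 0.05 rate ≈ 5%,
Bonferroni-tail rate ≈ nominal 1e−4 per offset) but anti-conservative
for sparse 0/1-dominated columns (per-offset Bonferroni false-positive
rate up to ~1e−3, i.e. a few tenths of an expected false hit per
500-offset scan). Consequences adopted here:

* the default reproduces the classical formula exactly; a
  `tie_corrected=True` switch substitutes the exact tie-adjusted
  variance of the concordance statistic (via the asymptotic tau-b
  p-value) for users with sparse maps;
* "significance" of a *region* is judged by runs of ≥ 3 consecutive
  Bonferroni-significant offsets of one sign
  (`CorrelationProfile.significant_runs`). Isolated single-offset flags
  occur at the rate expected from the tie anti-conservatism and are not
  treated as signal; planted effects produce runs of tens of offsets.

Stratified scans (`scan_by_class`) produce one profile per chromatin
class × covariate stratum × sensitivity, refusing the degenerate design
where the covariate is stratified along its own axis; strata with fewer
than 2 genes are skipped with a warning.

## Synthetic data generator

The generator emulates the four inputs with planted, recoverable
structure. Defaults (the study conditions used by all planted-recovery
tests): 5000 genes on five arms, TSS spacing ≥ 1000 nt, strands
Bernoulli(0.5), `active_fraction = 0.5`, 29 tissues.

**Expression.** A per-gene latent u ~ N(0,1) drives a zero-mass +
log-normal mixture: RPKM = 0 if u is below the class's silent quantile
(Active 0.185, NonActive 0.62), else exp(μ + 2.5u) with μ = 1.5 (Active)
or 0 (NonActive). Each tissue redraws the latent with correlation
ρ = 0.95 and the same gating, so BoE rises with S2 RPKM (and is
independent of it at ρ = 0). These values were chosen so the classified
bundle reproduces the intended regime: ~80–82% of Active genes with
RPKM > 0 or BoE > 6, ~40–44% of NonActive genes likewise (i.e. ~58–60%
silent/tissue-specific).

**Nucleosomes.** Active genes carry planted nucleosomes — sensitive
Nuc−2/Nuc−1 at −185/−35, resistant Nuc+1 at +135 with downstream repeats
at 175-nt spacing — each emitted as Poisson-many *independent* site
calls whose centres are jittered N(0, 15 nt). Call multiplicities are
tens per nucleosome per gene: the maps emulate deep pooled site calls,
which is what makes nt-level peak localisation possible at all — a
window-3-smoothed 1-nt histogram needs ≳ 30k pooled draws before the
mode of a σ = 15 peak is stable to ±3 nt, and deep counts are also the
regime where the classical variance formula is calibrated. Sites are
147-nt intervals (canonical footprint; only centres matter downstream).

Expression→occupancy coupling acts on *emission probability*, never on
position, through a saturating activity a = min(1, log1p(RPKM)/log1p(3))
and linear multipliers per offset band: resistant sites in the NDR band
[−120, +80] decrease with a (planted negative correlation), resistant
sites in [+70, +200] and the Nuc+1 calls increase with a (positive),
sensitive upstream [−220, −140] mildly positive, sensitive proximal
[−15, +55] mildly negative; the upstream flank [−300, −121] is
uncoupled. The activity scale of 3 RPKM places the coupling's dynamic
range inside the tissue-specific stratum (RPKM ∈ [0, ~2]), where the
planted correlations must be recoverable after stratification; genes
above ~3 RPKM saturate at a = 1, so constitutive/high-RPKM strata show
no residual correlation — mirroring the empirical pattern that
correlation signal concentrates in tissue-specific/modest classes.
Non-Active genes receive uniform (delocalised) placement over the window
at fixed rates with no coupling, plus a small genome-wide background for
both classes.

Everything is deterministic given (config, seed); bundles include a
manifest with the config echo and SHA-256 per file.

**What the generator does not emulate** — hence what passing tests do
not show about real data: no DNA sequence (no dinucleotide periodicity
or sequence-encoded positioning), no read-level MNase biases or
digestion-depth artefacts, independent counts across offsets (real
147-nt footprints impose spatial anticorrelation), a single TSS per gene
with idealised domain boundaries, and site-call multiplicities chosen
for statistical resolution rather than matched to any particular
sequencing depth.

## Numerical and design choices

* Degenerate inputs: empty gene lists produce empty tables; genes on
  chromosomes absent from the maps get zero count rows / Unclassified;
  all-tied scan columns are missing, not zero.
* The Monte-Carlo null calibration fixture uses deep counts
  (Poisson mean 20) — the regime the generator produces and the variance
  formula serves; sparse-count calibration is documented above instead.
* Problem sizes in the test suite (5000-gene default bundle, 100
  replicates × 300 genes × 500 offsets for the calibration) keep each
  planted-recovery check to seconds-to-a-minute while leaving comfortable
  statistical margins; they are the package's chosen study conditions.
* Peak reporting searches (0, +200) for Nuc+1 (k = 1) and (−300, 0) for
  Nuc−1/Nuc−2 (k = 2).

## Known limitations

* The classical-variance scan should not be trusted for isolated
  significant offsets on sparse maps; use runs, or `tie_corrected=True`.
* Chromatin classification requires *entire*-window coverage by one
  state group; real maps with fragmented domains will leave many genes
  Unclassified rather than guessing.
* No FDR control beyond Bonferroni; no spatial clustering test of
  significant runs (runs are reported descriptively).
* No nucleosome calling from raw reads, no occupancy normalisation
  across samples, no GFF/BAM parsing: the pipeline consumes already
  called site maps.
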