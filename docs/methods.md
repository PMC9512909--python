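# Methods

## Fragmentation model

The core assumption is stochastic fragmentation: breakpoints fall
uniformly at random, so fragments of one length represent all genomic
positions equally. For a single fragment length *f* the intact proportion
of an *r*-bp region is (f − r + 1)/f — of the *f* possible phases of the
fragmentation grid relative to the region, f − r + 1 leave it inside one
fragment. For f < r the proportion is defined as 0 (an intact region
cannot be longer than its fragment; the per-length sum below starts at
f = r, which encodes the same convention).

At the sample level each length class is weighted by its **mass**
concentration C_f (pg/µl), not its molar count: a picogram of DNA covers
the same genomic footprint regardless of how it is cut, so mass weighting
makes the numerator and denominator genome-equivalent. The package follows
this convention exactly, both in the closed forms (`fragmodel`) and in the
Monte Carlo length sampling (`simulator.mixture_fragmentation`).

Known deviations from the model, by sample type:

* **cfDNA** is nucleosome-protected, not stochastic — hence the
  `protection` module rather than the calculator.
* **FFPE DNA** amplifies worse than its size profile predicts
  (single-strand breaks, residual crosslinks); the calculator documents
  but does not correct for this.
* Sequence-dependent scission bias in sonication is ignored (a minor
  effect at desk scale).

## Genome-mass constant

Genome copies are derived from mass via
genome_length × 650 g/mol/bp × 10¹² pg/g / N_A with a haploid length of
3,234,830,000 bp, giving 3.4916 pg per genome. The constant is always
computed from its factors; the frequently quoted "3.5 pg" is its 2 s.f.
rounding, and using 3.5 directly would shift copy numbers by ~0.24 %.
Rounding to 3 significant figures is a display option (`round_sig`),
never applied internally.

## Fragment-size distributions

Distributions are integer-bp binned, strictly increasing, with
non-negative pg/µl masses. Region-table exports may be coarse, unsorted,
and may repeat a rounded length; reading rounds lengths to the nearest bp
and mass-sums duplicates. `resample_to_unit_bins` linearly interpolates
mass density over [m, n] and rescales so total mass is conserved to
< 1e-9 relative; all read/merge/resample paths conserve mass to the same
tolerance.

`average_fragment_length` defaults to the number-weighted mean
Σ C_f / Σ (C_f/f) (each molecule counted once, molecule count at length f
∝ C_f/f); a mass-weighted mean Σ f·C_f / Σ C_f is available because
instrument conventions for reported averages vary and are often
undocumented. Number-average ≤ mass-average always (Cauchy–Schwarz), with
equality only for a single-length sample. The calculator treats reference
average lengths as given, whatever convention produced them.

## Fragment Calculator

Reference profiles (distribution + average length) are sorted by average
length; their [175]/[125] anchor ratios must then increase strictly — a
violation means the panel is internally inconsistent and is rejected at
load. A measured ratio is located between two adjacent anchors and the
response (per-anchor [125]/[r] ratio, or average length) is linearly
interpolated; the 125 bp concentration divided by the interpolated ratio
gives the r-bp estimate. r = 1 gives total genome copies (every fragment
contains its 1-bp regions intact, so the [125]/[1] ratio is the 125 bp
intact proportion itself).

Numerical choices:

* Exact anchor hits short-circuit to the profile's own values, making all
  three estimators exact (≤ 1e-9 relative) when the queried sample *is* a
  reference.
* Out-of-range ratios error by default; `clamp` extrapolates on the
  terminal bracket with a warning. Ratios > 1 are rejected outright with a
  hint at copy-number aberration or measurement error, since the model
  bounds [long]/[short] by 1.
* `printed_rounding` rounds the slope, and the intercept derived from the
  rounded slope, to 3 decimals before evaluating — the convention of a
  hand calculation that carries 3-decimal intermediates. It exists to
  reproduce such chains verbatim and is off by default.
* The same interpolation rule is applied for r > 175 (beyond the long
  amplicon); those estimates are extrapolations in model space and should
  be treated with extra caution.

Reference panels ship as data the user supplies (a TSV manifest naming
per-profile distribution CSVs); the published reference profiles are not
redistributable with the package, and the test suite builds synthetic
panels instead.

## Monte Carlo oracle

`equal_length_fragmentation` draws a uniformly random grid phase per
replicate, locates the first cut strictly after the region start, and
scores the region intact when that cut falls at or beyond the region end;
`mixture_fragmentation` first draws a fragment length with probability
∝ C_f. Estimates carry binomial standard errors. The circular-genome
default makes the closed form exact (translation invariance, no edge
effects); the linear flag changes fragment lengths only at the genome
ends, not the intactness of an interior region. All randomness flows
through numpy's PCG64 generator with a mandatory seed; estimates are
bit-reproducible for a fixed seed and numpy version.

## Synthetic data

The generators define the test conditions for every module:

* `synth_distribution("unimodal", mode_bp, sigma=0.35)` — a log-normal
  mass density truncated to [35, 10000] bp, emulating sonicated-DNA
  profiles; sigma 0.35 reproduces the broad unimodal smears typical of
  ultrasonicated gDNA.
* `synth_distribution("nucleosome_ladder", n_peaks)` — Gaussians at
  166·k bp with halving weights and 15 bp spread, the mono-/di-/tri-
  nucleosome ladder characteristic of cfDNA.
* `synth_fragment_set` — fragments of length N(166, 10); each picks a
  planted nucleosome position and is centred there (±10 bp jitter) with
  probability equal to that position's protection strength, else placed
  uniformly.

What these emulate — and do not: real electropherograms carry baseline
noise, marker artefacts and instrument-specific binning; real cfDNA has
sequence-biased cut sites, tissue-specific mixtures of nucleosome
spacings, and mappability gaps. Passing tests therefore demonstrate the
*computational* correctness of the pipeline under the stated generative
assumptions, not robustness to instrument artefacts.

## Windowed Protection Score

For each position p, the window is W = [p − 60, p + 60) (even windows are
anchored so the scored position begins the right half). Among fragments
with length in [120, 180]: +1 if the fragment spans W entirely, −1 if
either of its half-open boundary coordinates lies strictly inside W
(counted once even if both do), 0 otherwise. The three classes are
mutually exclusive per fragment and position, keeping contributions in
{−1, 0, +1}; the published description admits other endpoint readings
(e.g. −1 per endpoint), which is why the convention is spelled out here
and checked against a brute-force recount in the tests.

Peak calling subtracts a running median (default 1000 bp) to remove
coverage trend, smooths with a 21 bp moving mean, and keeps maximal
positive runs of length 25–150 bp; the apex is the maximum of the *raw*
WPS within the run (leftmost on ties). The 25 bp floor follows from the
geometry of the score: a perfectly conserved nucleosome with ~166 bp
fragments elevates a run of only ~166 − 120 = 46 bp, shrinking further
under positional jitter, so a nucleosome-sized floor would reject the
sharpest true peaks while the floor's purpose is only to drop one- and
few-base noise runs. All four parameters are exposed on the API and CLI.

## Region filters

Coverage is an exact per-base overlap count, run-length encoded with
explicit zero runs between covered spans (a base with no CNA calls counts
as 0 and is *kept* by the threshold — probe coverage, below, is what
removes unassayable space). The low-CNA threshold keeps runs with at most
`hard_max` affected samples (the operative published rule, ≤ 34 of
10,610) and merges adjacent survivors; alternatively the cut is derived
as the length-weighted per-base percentile of counts, since a percentile
"of regions" is otherwise ambiguous between run- and base-weighting. The
probe-gap filter drops a candidate when any probe-free gap touching it —
internal gaps between consecutive probes and each edge's distance to its
nearest probe — exceeds 10 kb. Peak-flank windows are [apex − 65,
apex + 66), unioned before intersection so outputs stay disjoint.
Cytosine-free scanning is a plain window scan in which 'N' disqualifies;
reverse-strand screening is the caller's job via `revcomp`, keeping
strand semantics explicit.

## Quantitation helpers

All values are proportions internally; percent formatting is display
only. The factor-2 bisulfite correction applies to qPCR only (one
amplifiable strand per converted duplex ≈ one cycle-threshold shift);
ddPCR counts amplifiable molecules absolutely and must not be corrected.
`ratio_to_mean` normalises each assay by its locus mean, so the returned
ratios average to exactly 1.

## Problem sizes in the test suite

The suite runs on synthetic fixtures generated at test time: Monte Carlo
grids of ~53 cells at 100,000 replicates, 500-fragment WPS instances over
2,000-position tracks, region-filter fixtures on ≤ 100 kb spans, and
4,000-fragment planted-nucleosome recoveries — sizes at which the brute-
force oracles remain exact and the whole suite completes in seconds.

## Known limitations

* No correction for FFPE non-amplifiability or single-strand damage.
* No modelling of sequence-biased scission or enzymatic end-repair.
* No primer thermodynamics, multiplex dimer screening, alignment or
  uniqueness filtering — assay design steps outside the fragmentation
  model are expected to be done with dedicated tools.
* The calculator's accuracy degrades when the sample's distribution shape
  differs from the reference family bracketing it; tight anchors matter
  more than many anchors.
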