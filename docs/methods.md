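# Methods

## The measurement

A surface-tethered pre-mRNA molecule, labeled with a far-red dye, is
imaged by TIRF microscopy together with fluorescent-protein fusions of
splicing factors (e.g. mCherry-U2AF35, mEGFP-U2AF65, mEGFP-U2B″ as a
U2 snRNP marker). Channels are excited one at a time, each until its
fluorophores have bleached completely (far-red RNA dye first, then the
561 nm channel, then 488 nm). For every RNA spot with a colocalized
protein spot, the protein-channel intensity trace is decomposed into
discrete photobleaching steps; each downward step is the bleaching of
one fluorescent-protein molecule, so the step count is the number of
labeled factor molecules bound to that single RNA.

Counting molecules this way requires two corrections, both measured
independently and supplied as a calibration table per protein:

* **Labeled fraction f.** Only a fraction `f_labeled` of the RNA-bound
  pool of a factor carries a mature fluorophore (the rest is
  endogenous unlabeled protein or immature fluorophore). Measured by
  affinity purification on biotinylated RNA; defaults follow the
  measured 75:25 (U2AF35), 69:31 (U2AF65) and 49:51 (U2B″) ratios.
* **Dimer fraction.** Free labeled protein, with no RNA present,
  sometimes bleaches in two steps because it dimerizes. The counts of
  free spots bleaching in 1 vs 2 steps (e.g. 189:33 for mCherry-U2AF35
  without ATP) define the *single-site* step distribution directly:
  one occupied site produces 1 step with probability n1/(n1+n2) and
  2 steps with probability n2/(n1+n2). The same proportion of dimers
  is assumed for molecules bound on RNA.

## Expected step distributions and occupancy tests

For `k` fully occupied sites, each site independently contributes
0 visible steps with probability `1 − f_labeled`, otherwise a draw
from the single-site distribution. The k-fold convolution is
conditioned on a total of at least one visible step, because a complex
with no visible fluorophore is never scored — it is simply an RNA spot
without colocalized protein. Before conditioning, the invisible mass
is exactly `(1 − f_labeled)^k`; this identity is exercised in tests,
and the convolution is cross-checked against brute-force enumeration
of all per-site outcomes for k ≤ 4 (agreement to 1e-12).

Observed step histograms are compared with an expectation by Pearson
chi-square. Classes are pooled from the highest step count downward
until every class has an expected count ≥ 5 (with a final upward merge
if the bottom class is still short); not-determinable traces are
excluded. Degrees of freedom are `classes − 1`, since the expectation
comes from an independent free-protein calibration and no parameter is
fitted to the observed counts. The worked single-occupancy case
(observed 143/21 one-/two-step complexes against the 189:33
calibration scaled to 164) gives χ² = 0.550, df = 1, P = 0.458.

### Occupancy mixture

The proportions π₀, π₁, π₂ of RNA occupied at no/one/two sites are
estimated by direct search: the simplex is scanned at 0.01 resolution
together with the total number of spots N considered accessible in
principle, minimizing the chi-square between observed class counts and
`N ×` the mixture of *unconditioned* per-k distributions. π₀ and the
dark fraction of occupied molecules contribute to the invisible class,
which enters the statistic whenever N exceeds the observed visible
total. Ties break toward smaller π₂, then smaller N. Grid search
rather than a gradient method: the 2-simplex at 0.01 resolution times
a few hundred N candidates is ~10⁶ cells, evaluated vectorized in
well under a second.

**Identifiability caveat.** The visible classes constrain only
`N·π₁` and `N·π₂`; the invisible-class term's numerator is independent
of N while its denominator grows with N, so (π₀, N) form a nearly flat
chi-square ridge. On real data N should therefore be bracketed by what
is known — at most the number of RNA spots examined — and π₀ read with
that caveat. The closed-loop recovery study fixes the candidate range
around the known spot total; with that constraint 20 draws of 400
molecules at π = (0.2, 0.5, 0.3) are recovered with mean absolute
error ≤ 0.05 per component, and noise-free expected counts recover the
generating grid point exactly.

Error bars on histogram frequencies are binomial standard errors
√(p̂(1−p̂)/n).

## Step detection

A trace is modeled as piecewise-constant with independent Gaussian
noise. For every candidate number of change points m up to a cap
(default 6), the globally optimal placement — minimal residual sum of
squares with all segments at least `min_dwell` frames (default 3) — is
found by dynamic programming over segment boundaries (O(m·n²), exact).
The retained m minimizes a Schwarz-type score,

    n·log(RSS/n) + penalty·(2m + 2)·log(n),

counting one location and one level per change point plus an overall
level and noise SD. All candidate scores are kept in the result so the
selection is auditable. Exact rather than greedy segmentation was
chosen so that model selection provably coincides with exhaustive
enumeration of placements; the test suite checks this equivalence
against an independent brute-force oracle on 500 short traces.

`penalty = 2.0` (twice plain BIC) is the default, calibrated by
simulation on the two regimes that matter: flat noisy traces must stay
at 0 steps (≥ 99% at penalty 2.0; plain BIC yields ~5% spurious
steps because the best of ~n candidate split points is selected), and
3:1 step:noise staircases with dwells ≥ 10 frames must be counted
exactly (≥ 99% per 1–4 steps at penalty 2.0). Noise SD is estimated
robustly as MAD of first differences divided by √2 (differencing
removes the signal except at the few change points; the MAD ignores
those).

A fit becomes a verdict only if it looks like bleaching: every
retained step is a decrease, the terminal level is within 3 estimated
noise SDs of background, per-step amplitudes lie within
[0.4, 2.5] × the median step, and (optionally, off by default) no
competing step count scores within a configurable margin of the
winner. Anything else is "n.d." (not determinable) — reported, but
excluded from all statistics, mirroring how ambiguous complexes are
set aside rather than guessed.

## Spot detection, traces and registration

Detection runs on the mean of the first 5 frames of a channel's
acquisition block (maximal signal before bleaching). Local maxima more
than 5 robust noise SDs above the image median are fit with a
symmetric 2D Gaussian plus constant offset in a 9×9 window; a
candidate is accepted only if the fit converges, its width lies in
0.7–2.5 px (diffraction-limited range at this pixel scale) and the
residual variance is below 3× the image noise variance — i.e. the
intensity profile is actually Gaussian. Detections within one window
radius merge to the brighter fit. Analysis is restricted to a central
square crop (default 250×250 of a 512×512 field). Coordinates are
0-based, pixel-center.

Traces are per-frame sums over a circular ROI (default radius 3 px)
minus the median of a 5–8 px annulus times the ROI pixel count; traces
whose annulus leaves the image are flagged edge-clipped and dropped.

Chromatic aberration between channels is corrected by a planar affine
transform (full 6-parameter form by default; the distortion of a
well-aligned two-color TIRF path is ~1 px of offset plus sub-percent
scale). It is estimated by least squares from corresponding point
pairs — in the pipeline, bootstrapped from a coarse mutual-nearest-
neighbor match at 4 px, which suffices because the distortion is small
compared to typical spot spacing. Colocalization then pairs
transformed protein spots with RNA spots by mutual nearest neighbors
within 2 px (≈ one PSF sigma above registration error), conflicts
resolved by ascending distance; the pairing is deterministic and
symmetric under swapping the two channels.

## The synthetic microscope

`simkit` generates the closed-loop test bed: RNA positions uniform at
low surface density with a minimum separation (default 8 px), each RNA
assigned an occupancy from configurable probabilities over {0, 1, 2}
sites, visible fluorophores drawn per site from the labeled/dimer
model above. Spots render as symmetric 2D Gaussians (σ = 1.3 px)
scaled by the surviving-fluorophore intensity, plus additive Gaussian
camera noise on a constant offset (optional Poisson shot-noise term).
Bleaching is geometric per frame — the discrete analogue of
exponential photobleaching — with mean lifetime 60 frames in a
200-frame acquisition block. Each channel's stack covers only its own
acquisition block, so a channel's fluorophores start bleaching at its
frame 0: this is exactly the sequential channel-by-channel acquisition
of the experiment. The protein channel's positions are the RNA
positions pushed through the configured chromatic affine.

Default photophysics (300 photons/fluorophore/frame, camera noise
SD 3, offset 100) describe a bright-dye TIRF regime in which extracted
traces have step:noise ≈ 8:1. Two defaults interact with detection in
a way worth stating: a fluorophore that bleaches on the very first
frame (probability ≈ 1/lifetime) is physically invisible to a
detection image averaged over early frames, and a fluorophore that
outlives the block (probability (1−1/lifetime)^n_frames ≈ 3.5%)
yields a non-bleaching trace that is correctly rejected as "n.d.".
With the defaults these losses total a few percent, which is why spot
recall on synthetic fields is ≥ 95% rather than 100%. By default RNA
is placed only inside the analysis crop — spots outside it are never
analyzed, so simulating them would only burn compute; full-field
placement is available (`place_in_crop=False`).

What the generator does *not* emulate: stage drift, focus drift,
EMCCD gain noise statistics, fluorophore blinking and dark-state
kinetics (maturation darkness is folded into the static labeled
fraction, matching how the calibration is used), spectral bleed-
through, and RNA multimers. Tests passing on this generator therefore
validate the analysis logic and its statistics, not robustness to
those instrumental artifacts.

## Problem sizes

The test suite and the acceptance script use: 500 traces for the
exhaustive change-point oracle comparison; 1000 traces per case for
step-count recovery and the flat-trace false-positive rate; 20
replicate draws of 400 molecules for mixture recovery; 3 random fields
of 600 RNA / 800 protein spots for chance colocalization; and one full
synthetic field of 400 RNA at single occupancy for the end-to-end
closed loop — the scale of one experimental histogram (200–800
molecules).

## Known limitations

* The change-point score is a Schwarz-type approximation to a full
  Bayesian marginal likelihood; parity with any particular proprietary
  step-detection implementation is not claimed, only internal
  consistency with the stated score (which the brute-force oracle
  verifies).
* π₀ from the occupancy mixture is only as meaningful as the N
  bracket, per the ridge discussed above.
* The chi-square class-pooling rule (expected ≥ 5) makes the test
  conservative when dimer fractions are small and almost all mass sits
  in the 1-step class; with fewer than two poolable classes the test
  is reported as undefined rather than forced.
* Spot detection assumes isolated diffraction-limited spots; it does
  not deconvolve overlapping molecules closer than ~4 px.
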