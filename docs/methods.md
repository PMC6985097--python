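# Methods

This note documents the models behind `astroquant`, the defaults that matter,
the numerical choices, and what validation on synthetic data does and does
not establish.

## Synthetic micrographs

The generator emulates widefield immunofluorescence fields of differentiating
astrocyte cultures: by default 1388 × 1040 px at 0.32 µm/px (a typical ×20
camera geometry; the mm² conversion always comes from the configured pixel
size, never from a hard-coded constant), ~150 cells per field, and one or two
marker channels over a Hoechst-style nuclei channel.

**Cell rendering.**  Each cell is a 2-D Gaussian-profile disc cut at the
radius giving its sampled area (gamma-distributed; default mean 1500 px²,
SD 400 px²), with the remaining profile rescaled so the rim sits at 0.5 of
the cell's peak brightness (peak jittered in [0.85, 1]).  The blob therefore
has soft internal edges but a crisp support, and the intensity histogram has
an empty gap between background and the dimmest rim pixel.  Any threshold in
that gap reproduces the true support exactly, which is what makes noiseless
pipeline recovery *exact* rather than approximate — a deliberate property:
failures of the analysis then indicate bugs, not rendering ambiguity.
Nuclei are smaller discs (15% of the cell area, minimum 60 px) at the same
centres.  Centres are rejection-sampled with a minimum separation of 0.8 ×
the summed cell radii: cell bodies may lightly overlap (merged marker
components are handled by the nucleus-anchored counting rule), nuclei never
touch.

**Marker labels.**  Each marker lights exactly `round(fraction × n_cells)`
cells.  With two markers the joint count follows a latent bivariate
Bernoulli whose correlation is the co-expression target, clipped to the
Fréchet bounds; the realized label correlation is reported in the ground
truth rather than guaranteed, because pixel-level PCC is not analytically
controllable (background and blob overlap shift it — see
`examples/colocalization.py`).

**Corruption.**  A multiplicative illumination ramp
`1 + amplitude·((x/W − ½) + (y/H − ½))` acts on the signal plus a uniform
ambient level (default 0.1), then per-pixel additive Gaussian noise (default
SD 0.02) is applied and the image clipped at zero.  Photon-accurate Poisson
noise, bleaching, 3-D structure and realistic astrocyte morphology are out
of scope; consequently, passing recovery tests demonstrates correctness of
the measurement chain under controlled corruption, not robustness to every
real-microscopy artifact (debris, focal drift, saturation).

## Synthetic Ca²⁺ traces

Recordings default to 300 s at 1 Hz (no acquisition rate is implied by the
protocol being emulated; 1 s sampling resolves transients that evolve over
tens of seconds), baseline F₀ = 100 AU, stimulus at 20 s, 5–10 ROIs per
coverslip.  A responder trace is

    F(t) = F0 · (1 + A·s(t) + ε),   ε ~ N(0, noise_sd²)

with `s = 0` before stimulus + latency (default 23 s), a linear rise to 1
over `rise_duration_s` (default 6 s, so the true 10–90% rise time is
4.8 s), then `(1 − p)·exp(−Δt/τ) + p` with decay τ default 60 s and plateau
ratio `p` (0 = monophasic; p ≥ 0.5 keeps the decayed signal above half-peak,
the defining biphasic geometry).  `round(nonresponder_fraction · n_roi)`
traces carry no transient (default 10%), and antagonist treatment is
modelled purely as amplitude attenuation (default 0.2 for a treated group) —
no receptor pharmacology is simulated.  Noise is additive on the F/F₀ scale
(default SD 0.02).

## Imaging analysis choices

- **Otsu implementation**: 256-bin histogram over the observed intensity
  range; between-class variance computed by cumulative sums; ties broken
  toward the lower threshold; foreground is strictly above the threshold.
  A constant image raises rather than returning an arbitrary cut.
- **Threshold QC**: the QC score is the Pearson correlation of the raw
  intensities with the 0/1 mask itself (the mask treated as an image);
  ≥ 0.8 passes.  The fallback is deterministic: subtract a large-scale
  Gaussian background estimate (σ = 50 px, clipped at zero) and re-apply
  Otsu; if QC still fails, sweep candidate thresholds over the intensity
  quantiles of the background-subtracted image and keep the mask maximizing
  the QC score — the fallback directly optimizes the criterion it is judged
  by.  Gaussian background estimation was chosen over ball-rolling
  morphology for speed and determinism at full frame sizes; its scale
  parameter is configurable.
- **Artifact exclusion** is a user-supplied mask honored everywhere
  (masking, QC, area denominators); no automatic debris detection.
- **Nuclei counting**: QC'd threshold → components < 30 px removed → holes
  filled → one round of distance-transform watershed with peaks ≥ 5 px
  apart.  Residual merges deliberately count as one nucleus; the rule is
  simple and deterministic rather than maximally sensitive.
- **Marker-positive rule**: nucleus centroid inside a marker component of
  ≥ 30 px.  This anchors counting to nuclei (the denominator of "% positive
  cells") and is insensitive to marker components merging across adjacent
  cells.  The identity `% area per average cell × n_positive = % area` holds
  by construction.
- **Co-localization pixel policy**: default is the whole unexcluded frame;
  a union-of-masks policy is available.  Whole-frame PCC is biased upward by
  shared background, union-of-masks downward by single-positive pixels; both
  preserve rank order across conditions, so comparisons must fix the policy.

## Kinetics analysis choices

- **Feature measurement is done on the unfiltered normalized trace.**  The
  zero-phase low-pass (2nd-order Butterworth, default cutoff 0.2 Hz,
  forward–backward) is exposed as `lowpass` and used for the
  monophasic/biphasic shape decision, where smoothing genuinely helps.  It
  is *not* interposed before latency/RT/τ/AUC measurement: measured on this
  generator's waveforms, the filter's corner rounding inflates the noiseless
  10–90% rise time by ~3% and its acausal pre-ring crosses a noiseless
  3·SD onset threshold ~20 s early.  Interpolated threshold crossings and
  the least-squares decay fit are already noise-tolerant at the noise levels
  this pipeline targets.
- **Onset criterion**: baseline mean + 3·SD sustained for 3 consecutive
  samples (k and m configurable).  The reported onset is the linear
  interpolation of the threshold crossing into the first excursion sample,
  which removes the systematic one-sample positive bias of reporting the
  first supra-threshold sample itself.
- **Decay model**: `a·exp(−t′/τ) + c` with `a, c ≥ 0` on the
  baseline-subtracted tail.  The offset `c` (reported as `decay_offset`)
  is ~0 for transients that return to baseline and absorbs the sustained
  plateau of biphasic responses; without it a mono-exponential fit to a
  plateaued decay returns a τ with no relation to the true clearance rate.
  Fit error is RMSE divided by peak amplitude; while it is ≥ 10% the window
  shrinks from the end (10% of samples per step, minimum 5 points) and the
  final window is reported.  τ beyond 10⁴ s or a vanishing `a` raises the
  failure flag with τ absent.
- **Baseline level** for amplitude, AUC and crossings is F/F₀ = 1 by
  construction, not a refitted constant.  The peak is the first global
  maximum after onset.
- **Biphasic rule**: after the (filtered) trace first falls to half of peak
  amplitude, ≥ 20 s sustained at/above half-amplitude ⇒ biphasic; a trace
  that never reaches half-amplitude before the end of the fit window is
  sustained throughout and counts as biphasic.  The 20 s sustain duration is
  configurable and logged; a very slow monophasic decay (τ ≳ 0.7 × the
  post-peak window) is indistinguishable from a plateau under any such rule.
- **Batch behaviour**: per-trace failures (NaNs, degenerate baselines) are
  captured in the feature record's `error` field; a batch never aborts.
- Non-uniform sampling is linearly resampled to the median interval before
  filtering; latency is onset − stimulus time (any solution-exchange dead
  time in real recordings would be included in it, which the simulator does
  not model).

## Statistics choices

- SEM = sample SD/√n, absent for n = 1.
- ANOVA pairwise comparisons use pooled-MSE t statistics (df = N − k) with
  Bonferroni multiplication capped at 1, matching common post-hoc software;
  on two groups the omnibus F equals t².
- Mann-Whitney uses the exact null for both n ≤ 8 without ties, the
  tie-corrected normal approximation otherwise; an all-tied comparison
  returns p = 1 with a flag.
- When a comparison must be chosen automatically, ANOVA requires ≥ 3 groups
  with n ≥ 5 each and a Shapiro-Wilk pass at α = 0.05 per group; otherwise
  pairwise Mann-Whitney with Bonferroni.  The choice is recorded in the
  result's flags.
- The study drivers aggregate at whichever level the input tables carry
  (image-level rows by default); replicate columns are preserved so
  coverslip-level re-aggregation is a groupby away.

## Validation scale

The test suite and validation scripts run at desk scale: 320 × 320 px fields
with ~25 cells for recovery tests (the geometry, not the frame size, drives
segmentation behaviour), 50 traces per condition on the kinetics recovery
grid (latency {3, 10, 23} s × τ {60, 80} s × plateau {0, 0.6} at noise SD
0.02), and 1000 repetitions for the ANOVA type-I calibration.  All random
draws are seeded; reruns are bit-identical.

## Known limitations

- Exact noiseless image recovery relies on the generator's empty intensity
  gap; real micrographs have no such gap, so real-data accuracy is bounded
  by staining contrast, not by these tests.
- The marker-positive rule undercounts when a nucleus centroid falls just
  outside a thin marker process, and cannot separate co-mingled cells whose
  nuclei are merged by segmentation.
- The decay offset makes τ identifiable for plateaued responses but assumes
  the plateau is flat over the fit window; a slowly draining plateau biases
  τ upward.
- Treatment effects are amplitude-only in the simulator; the pipeline will
  measure, but the generator cannot validate, kinetic changes under
  antagonists.
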