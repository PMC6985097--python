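# astroquant

Quantification pipelines for astrocyte differentiation read-outs, with
ground-truthed synthetic data generators for validation.

When astrocytes are derived from stem cells, two measurements dominate the
characterization work: **how many cells express each astrocytic marker**
(GFAP, ALDH1L1, S100β, GLAST, purinoceptors — counted on immunofluorescence
micrographs against a Hoechst nuclei stain) and **how the cells handle
calcium when stimulated with ATP** (fluorescence transients recorded from
cell-body ROIs).  `astroquant` implements both analyses as a tested,
reproducible Python library, plus the group statistics used to compare
culture timepoints and pharmacological treatments, and a synthetic-data
module that generates micrographs and recordings with known ground truth so
every stage can be validated by parameter recovery.

## The methods

**Marker quantification.**  Each channel is thresholded by the Otsu method
(the histogram split maximizing between-class variance).  The binary mask is
quality-controlled by correlating it with the raw channel; the mask passes
when the Pearson correlation coefficient is ≥ 0.8, otherwise a deterministic
re-threshold fallback runs (background subtraction, then a direct sweep
maximizing the QC score).  Nuclei are counted on the DNA channel (connected
components with one round of distance-transform watershed splitting), and a
cell is marker-positive when its nucleus centroid falls inside a marker-mask
component.  Reported per image: marker⁺ cells per mm², % marker⁺ cells
(nuclei denominator), % area covered, and % area per average positive cell.
Co-localization of two stains R and G is

    r = Σᵢ (Rᵢ − R̄)(Gᵢ − Ḡ) / √( Σᵢ (Rᵢ − R̄)² · Σᵢ (Gᵢ − Ḡ)² )

over a configurable pixel set (whole frame or union of masks).

**Ca²⁺ transient decomposition.**  Each ROI trace is normalized to F/F₀
(mean of the 0–20 s pre-stimulus window).  A trace responds when the
post-stimulus signal exceeds baseline mean + 3·SD for 3 consecutive samples;
latency is the interpolated threshold crossing minus the stimulus time.
Responders are decomposed into the 10–90% rise time (RT), peak amplitude
(F/F₀ − 1), area under the baseline-subtracted curve (AUC), and a decay time
constant from a least-squares fit of `f(t) = a·exp(−t/τ) + c` from the peak
to the end of the experiment (300 s, shrunk while the normalized RMSE of the
fit is ≥ 10%).  Waveforms are classed monophasic or biphasic by whether the
decay sustains at or above half of peak amplitude for ≥ 20 s.

**Statistics.**  Mean ± SEM per group; one-way ANOVA with
Bonferroni-adjusted pairwise comparisons, or the exact Mann-Whitney rank-sum
test for small/non-normal samples; stars at p < 0.05 / 0.01 / 0.001.

## A worked example

`examples/quantify_markers.py` simulates a clean 320×320 px field with
25 cells, half of them GFAP⁺, and runs the full imaging pipeline:

```
threshold QC: PCC = 0.977 (passed: True, fallback: False)
nuclei counted:        25  (simulated: 25)
GFAP+ cells:           12  (simulated: 12)
% GFAP+ cells:         48.00
% area covered:        7.651  (true: 7.651)
% area per avg cell:   0.6376
GFAP+ cells per mm^2:  1144.4
```

The mask–image correlation (0.977) clears the 0.8 QC bar on the first pass;
on a noiseless field the recovered counts and area equal the simulator's
ground truth exactly (12/25 = 48%, and round(0.5 × 25) = 12 because the
generator forces the positive count by rounding).  The other examples cover
co-localization (`colocalization.py`), transient decomposition and
antagonist comparison (`calcium_transients.py`), and timepoint statistics
(`group_statistics.py`).

A thin CLI drives file-based runs end to end:

```sh
astroquant all --seed 1 --outdir study_out        # simulate -> quantify -> report
astroquant quantify field1.tif field2.tif --outdir out
```

Every stage writes a JSON provenance record (config hash, seed, counts), and
identical config + seed reproduces every output byte for byte.

## Layout

- `src/astroquant/simulate.py` — ground-truthed micrograph and trace generators
- `src/astroquant/imaging.py` — Otsu, PCC, threshold QC, nuclei counting, marker quantification, co-localization
- `src/astroquant/kinetics.py` — F/F₀, filtering, responder detection, RT/AUC/decay-τ/phase
- `src/astroquant/stats.py`, `report.py` — mean ± SEM, ANOVA + Bonferroni, Mann-Whitney, tidy CSV/JSON reports
- `src/astroquant/study.py`, `cli.py`, `config.py`, `io.py` — end-to-end drivers, CLI, TIFF/CSV I/O
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical choices, limitations
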