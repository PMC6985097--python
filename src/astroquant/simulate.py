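"""Ground-truthed synthetic micrographs and Ca2+ ROI traces.

These generators stand in for the raw acquisitions the analysis pipeline was
designed for: x20 widefield fields (1388 x 1040 px) of nuclei plus one or two
astrocytic marker channels, and 300 s ROI fluorescence recordings of
ATP-evoked transients sampled from 5-10 somata per coverslip.  Every draw is
reproducible from the spec seed, and each output carries a ground-truth
record (true marker labels, true kinetic parameters) so downstream
quantification can be validated by recovery rather than by eye.

Cells are rendered as 2-D Gaussian-profile discs cut at the level giving the
requested area, rescaled so the rim sits at a fixed fraction of peak
brightness: the blob has soft edges yet a crisp support, so a histogram
threshold anywhere in the empty intensity gap between background and rim
recovers the true mask exactly in the noiseless case.  Corruption (uneven
multiplicative illumination, then additive Gaussian noise) is applied last;
ground truth records the labels and masks before corruption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .imaging import Micrograph, pearson_cc
from .kinetics import CalciumTrace

__all__ = [
    "ImageSimSpec",
    "TraceSimSpec",
    "ImageGroundTruth",
    "TraceGroundTruth",
    "generate_micrograph",
    "generate_trace_set",
]


# ---------------------------------------------------------------------------
# micrograph simulation
# ---------------------------------------------------------------------------


def _default_fractions() -> dict[str, float]:
    # realistic study conditions: ~53% GFAP+, ~40% ALDH1L1+ cultures
    return {"GFAP": 0.53, "ALDH1L1": 0.40}


@dataclass(frozen=True)
class ImageSimSpec:
    """Parameters of one simulated multichannel field.

    Intensities are on a [0, ~1.3] arbitrary scale.  ``noise_sd`` is the SD of
    the additive per-pixel Gaussian noise on that scale;
    ``illumination_gradient_amplitude`` scales a multiplicative corner-to-corner
    ramp; ``ambient_level`` is a uniform background fluorescence added before
    the gradient so that uneven illumination shows in the background too.
    """

    width_px: int = 1388
    height_px: int = 1040
    pixel_size_um: float = 0.32
    n_cells: int = 150
    marker_positive_fractions: Mapping[str, float] = field(
        default_factory=_default_fractions
    )
    coexpression_pcc_target: float = 0.3
    mean_cell_area_px: float = 1500.0
    cell_area_dispersion: float = 400.0
    illumination_gradient_amplitude: float = 0.2
    ambient_level: float = 0.1
    noise_sd: float = 0.02
    seed: int = 0
    nucleus_area_fraction: float = 0.15
    rim_level: float = 0.5  # rendered intensity at the blob rim (peak = 1)
    overlap_factor: float = 0.8  # min centre separation / summed cell radii

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise InvalidSpecError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise InvalidSpecError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise InvalidSpecError("n_cells must be >= 0")
        if not 1 <= len(self.marker_positive_fractions) <= 2:
            raise InvalidSpecError("supports 1 or 2 marker channels")
        for name, f in self.marker_positive_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise InvalidSpecError(f"fraction for {name!r} outside [0, 1]")
            if self.n_cells == 0 and f > 0:
                raise InvalidSpecError(
                    f"n_cells = 0 with positive fraction for {name!r}"
                )
        if not -1.0 <= self.coexpression_pcc_target <= 1.0:
            raise InvalidSpecError("coexpression_pcc_target outside [-1, 1]")
        if self.mean_cell_area_px <= 0 or self.cell_area_dispersion <= 0:
            raise InvalidSpecError("cell area mean and dispersion must be > 0")
        if self.illumination_gradient_amplitude < 0 or self.noise_sd < 0:
            raise InvalidSpecError("gradient amplitude and noise_sd must be >= 0")
        if not 0.0 < self.nucleus_area_fraction < 1.0:
            raise InvalidSpecError("nucleus_area_fraction must be in (0, 1)")
        if not 0.0 < self.rim_level < 1.0:
            raise InvalidSpecError("rim_level must be in (0, 1)")


@dataclass
class ImageGroundTruth:
    """True labels of one simulated field, recorded before corruption."""

    cells: pd.DataFrame  # cell_id, row, col, cell_area_px, nucleus_area_px, <marker> flags
    marker_summary: dict  # marker -> n_positive / fraction_realized / true area
    realized_label_pcc: Optional[float]
    true_masks: dict  # role -> boolean support mask before corruption
    spec: ImageSimSpec


def _place_centres(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    radii: np.ndarray,
    overlap_factor: float,
) -> np.ndarray:
    """Rejection-sample cell centres with bounded overlap and full-frame margins."""
    centres = np.empty((n, 2))
    for i in range(n):
        r_i = radii[i]
        margin = min(r_i + 1, min(height, width) / 2 - 1)
        placed = False
        for _ in range(4000):
            row = rng.uniform(margin, height - margin)
            col = rng.uniform(margin, width - margin)
            if i == 0:
                placed = True
            else:
                d = np.hypot(centres[:i, 0] - row, centres[:i, 1] - col)
                placed = bool(np.all(d >= overlap_factor * (radii[:i] + r_i)))
            if placed:
                centres[i] = (row, col)
                break
        if not placed:
            raise InvalidSpecError(
                "could not place cells: field too dense for the requested areas"
            )
    return centres


def _render_blob(
    canvas: np.ndarray,
    support: np.ndarray,
    row: float,
    col: float,
    area_px: float,
    peak: float,
    rim_level: float,
) -> int:
    """Draw one Gaussian-profile disc; returns the pixel count of its support."""
    height, width = canvas.shape
    r_cut = math.sqrt(area_px / math.pi)
    sigma = r_cut / 1.5
    half = int(math.ceil(r_cut)) + 1
    r0, r1 = max(0, int(row) - half), min(height, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(width, int(col) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rho2 = (rr - row) ** 2 + (cc - col) ** 2
    inside = rho2 <= r_cut**2
    g = np.exp(-rho2 / (2.0 * sigma**2))
    cut = math.exp(-(r_cut**2) / (2.0 * sigma**2))
    vals = rim_level + (1.0 - rim_level) * (g - cut) / (1.0 - cut)
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, np.where(inside, peak * vals, 0.0), out=patch)
    support[r0:r1, c0:c1] |= inside
    return int(inside.sum())


def _assign_markers(
    rng: np.random.Generator,
    n_cells: int,
    fractions: Mapping[str, float],
    rho: float,
) -> dict[str, np.ndarray]:
    """Exact-count marker membership; pairwise co-expression targets ``rho``.

    Each marker lights exactly round(fraction * n_cells) cells.  With two
    markers the joint count follows a latent bivariate Bernoulli with
    correlation ``rho``, clipped to the Frechet bounds, so the realized
    label correlation approaches (but is not guaranteed to equal) the target.
    """
    names = list(fractions)
    counts = {m: int(round(fractions[m] * n_cells)) for m in names}
    labels = {m: np.zeros(n_cells, dtype=bool) for m in names}
    if n_cells == 0:
        return labels
    if len(names) == 1:
        m = names[0]
        idx = rng.choice(n_cells, size=counts[m], replace=False)
        labels[m][idx] = True
        return labels
    m1, m2 = names
    n1, n2 = counts[m1], counts[m2]
    p1, p2 = n1 / n_cells, n2 / n_cells
    q1, q2 = 1 - p1, 1 - p2
    p11 = p1 * p2 + rho * math.sqrt(max(p1 * q1 * p2 * q2, 0.0))
    n11 = int(round(p11 * n_cells))
    n11 = max(max(0, n1 + n2 - n_cells), min(n11, min(n1, n2)))
    perm = rng.permutation(n_cells)
    both = perm[:n11]
    only1 = perm[n11 : n11 + (n1 - n11)]
    only2 = perm[n11 + (n1 - n11) : n11 + (n1 - n11) + (n2 - n11)]
    labels[m1][both] = True
    labels[m1][only1] = True
    labels[m2][both] = True
    labels[m2][only2] = True
    return labels


def generate_micrograph(spec: ImageSimSpec) -> tuple[Micrograph, ImageGroundTruth]:
    """Simulate one multichannel field and its ground truth.

    The nuclei channel holds one blob per cell; each marker channel lights the
    cell bodies of exactly round(fraction * n_cells) cells.  The multiplicative
    illumination ramp and additive Gaussian noise are applied last; ground
    truth (labels, per-cell areas, support masks, realized co-expression)
    reflects the uncorrupted scene.
    """
    rng = np.random.default_rng(spec.seed)
    height, width = spec.height_px, spec.width_px
    n = spec.n_cells
    markers = list(spec.marker_positive_fractions)

    # per-cell geometry: gamma-distributed areas (mean, SD from the spec)
    if n > 0:
        shape = (spec.mean_cell_area_px / spec.cell_area_dispersion) ** 2
        scale = spec.cell_area_dispersion**2 / spec.mean_cell_area_px
        areas = np.maximum(rng.gamma(shape, scale, size=n), 50.0)
    else:
        areas = np.empty(0)
    radii = np.sqrt(areas / math.pi)
    centres = _place_centres(rng, n, height, width, radii, spec.overlap_factor)
    nucleus_areas = np.maximum(spec.nucleus_area_fraction * areas, 60.0)
    labels = _assign_markers(
        rng, n, spec.marker_positive_fractions, spec.coexpression_pcc_target
    )
    brightness = {
        role: rng.uniform(0.85, 1.0, size=n) for role in ["nuclei", *markers]
    }

    channels: dict[str, np.ndarray] = {}
    true_masks: dict[str, np.ndarray] = {}
    cell_areas_px = np.zeros(n, dtype=int)
    nucleus_areas_px = np.zeros(n, dtype=int)
    for role in ["nuclei", *markers]:
        canvas = np.zeros((height, width))
        support = np.zeros((height, width), dtype=bool)
        for i in range(n):
            if role != "nuclei" and not labels[role][i]:
                continue
            area = nucleus_areas[i] if role == "nuclei" else areas[i]
            npx = _render_blob(
                canvas,
                support,
                centres[i, 0],
                centres[i, 1],
                float(area),
                float(brightness[role][i]),
                spec.rim_level,
            )
            if role == "nuclei":
                nucleus_areas_px[i] = npx
            else:
                cell_areas_px[i] = max(cell_areas_px[i], npx)
        channels[role] = canvas
        true_masks[role] = support

    # corruption: multiplicative ramp on (ambient + signal), then additive noise
    rows = np.arange(height)[:, None] / max(height - 1, 1)
    cols = np.arange(width)[None, :] / max(width - 1, 1)
    ramp = (rows - 0.5) + (cols - 0.5)
    fieldmap = np.clip(1.0 + spec.illumination_gradient_amplitude * ramp, 0.05, None)
    for role in channels:
        img = (channels[role] + spec.ambient_level) * fieldmap
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[role] = np.clip(img, 0.0, None)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "row": centres[:, 0] if n else np.empty(0),
            "col": centres[:, 1] if n else np.empty(0),
            "cell_area_px": cell_areas_px,
            "nucleus_area_px": nucleus_areas_px,
            **{m: labels[m] for m in markers},
        }
    )
    total_px = height * width
    marker_summary = {}
    for m in markers:
        n_pos = int(labels[m].sum())
        marker_summary[m] = {
            "n_positive": n_pos,
            "fraction_realized": n_pos / n if n else 0.0,
            "true_area_px": int(true_masks[m].sum()),
            "true_percent_area": 100.0 * true_masks[m].sum() / total_px,
        }
    realized_pcc: Optional[float] = None
    if len(markers) == 2 and n > 1:
        a, b = (labels[m].astype(float) for m in markers)
        if a.std() > 0 and b.std() > 0:
            realized_pcc = pearson_cc(a, b)
    micro = Micrograph(
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        metadata={"seed": spec.seed, "simulated": True, "markers": markers},
    )
    truth = ImageGroundTruth(cells, marker_summary, realized_pcc, true_masks, spec)
    return micro, truth


# ---------------------------------------------------------------------------
# calcium trace simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceSimSpec:
    """Parameters of one simulated coverslip recording.

    A responder trace is F(t) = F0 * (1 + A * s(t) + noise) with s = 0 before
    stimulus + latency, a linear rise to 1 over ``rise_duration_s`` (so the
    true 10-90% rise time is 0.8 * rise_duration_s), then
    (1 - p) * exp(-dt/tau) + p with plateau ratio p (monophasic when p = 0).
    ``treatment_attenuation`` scales A (1 = untreated; antagonist-treated
    cultures show stunted responses, e.g. 0.2).  ``noise_sd`` is per-sample
    Gaussian noise on the F/F0 scale.
    """

    n_roi: int = 8
    duration_s: float = 300.0
    sample_interval_s: float = 1.0
    baseline_f0: float = 100.0
    stimulus_time_s: float = 20.0
    latency_s: float = 23.0
    rise_duration_s: float = 6.0
    peak_amplitude_ratio: float = 1.0
    decay_tau_s: float = 60.0
    biphasic_plateau_ratio: float = 0.0
    nonresponder_fraction: float = 0.1
    treatment_attenuation: float = 1.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roi < 1:
            raise InvalidSpecError("n_roi must be >= 1")
        if self.sample_interval_s <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("duration and sample interval must be positive")
        if self.baseline_f0 <= 0:
            raise InvalidSpecError("baseline_f0 must be positive")
        if self.latency_s < 0 or self.rise_duration_s <= 0:
            raise InvalidSpecError("latency must be >= 0 and rise duration > 0")
        if self.peak_amplitude_ratio <= 0 or self.decay_tau_s <= 0:
            raise InvalidSpecError("amplitude and tau must be positive")
        if not 0.0 <= self.biphasic_plateau_ratio < 1.0:
            raise InvalidSpecError("biphasic_plateau_ratio must be in [0, 1)")
        if not 0.0 <= self.nonresponder_fraction <= 1.0:
            raise InvalidSpecError("nonresponder_fraction must be in [0, 1]")
        if not 0.0 <= self.treatment_attenuation <= 1.0:
            raise InvalidSpecError("treatment_attenuation must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.duration_s < (
            self.stimulus_time_s + self.latency_s + self.rise_duration_s
        ):
            raise InvalidSpecError(
                "duration must cover stimulus + latency + rise duration"
            )


@dataclass
class TraceGroundTruth:
    """True per-ROI kinetic parameters of one simulated recording."""

    traces: pd.DataFrame  # roi_id, responder, latency_s, rise_time_10_90_s, ...
    spec: TraceSimSpec


def response_shape(
    t: np.ndarray, t_on: float, rise_s: float, tau_s: float, plateau: float
) -> np.ndarray:
    """Unit transient shape: 0, linear rise to 1, exponential decay onto a plateau."""
    s = np.zeros_like(t, dtype=float)
    rising = (t >= t_on) & (t < t_on + rise_s)
    s[rising] = (t[rising] - t_on) / rise_s
    decaying = t >= t_on + rise_s
    s[decaying] = (1.0 - plateau) * np.exp(
        -(t[decaying] - t_on - rise_s) / tau_s
    ) + plateau
    return s


def generate_trace_set(
    spec: TraceSimSpec, group: Optional[Mapping[str, str]] = None
) -> tuple[list[CalciumTrace], TraceGroundTruth]:
    """Simulate one coverslip's ROI traces and their ground truth.

    round(nonresponder_fraction * n_roi) traces fluctuate about baseline only;
    the rest carry the transient with effective amplitude
    peak_amplitude_ratio * treatment_attenuation.  ``group`` labels (e.g. DIV,
    treatment) are attached to every trace's metadata.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = int(math.floor(spec.duration_s / spec.sample_interval_s)) + 1
    t = spec.sample_interval_s * np.arange(n_samples)
    n_non = int(round(spec.nonresponder_fraction * spec.n_roi))
    non_idx = set(rng.choice(spec.n_roi, size=n_non, replace=False).tolist())
    amp = spec.peak_amplitude_ratio * spec.treatment_attenuation
    t_on = spec.stimulus_time_s + spec.latency_s
    meta = dict(group or {})

    traces: list[CalciumTrace] = []
    records = []
    for i in range(spec.n_roi):
        responder = i not in non_idx and amp > 0
        s = (
            response_shape(
                t, t_on, spec.rise_duration_s, spec.decay_tau_s,
                spec.biphasic_plateau_ratio,
            )
            if responder
            else np.zeros_like(t)
        )
        noise = (
            rng.normal(0.0, spec.noise_sd, size=n_samples)
            if spec.noise_sd > 0
            else 0.0
        )
        f = spec.baseline_f0 * (1.0 + amp * s + noise)
        f = np.clip(f, 0.0, None)
        roi_id = f"roi_{i + 1}"
        traces.append(
            CalciumTrace(
                time_s=t.copy(),
                f=f,
                stimulus_time_s=spec.stimulus_time_s,
                roi_id=roi_id,
                metadata=dict(meta),
            )
        )
        if responder:
            phase = "biphasic" if spec.biphasic_plateau_ratio > 0 else "monophasic"
        else:
            phase = "none"
        records.append(
            {
                "roi_id": roi_id,
                "responder": responder,
                "latency_s": spec.latency_s if responder else np.nan,
                "rise_time_10_90_s": 0.8 * spec.rise_duration_s
                if responder
                else np.nan,
                "decay_tau_s": spec.decay_tau_s if responder else np.nan,
                "peak_amplitude": amp if responder else np.nan,
                "plateau_ratio": spec.biphasic_plateau_ratio if responder else np.nan,
                "phase": phase,
            }
        )
    truth = TraceGroundTruth(pd.DataFrame(records), spec)
    return traces, truth
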