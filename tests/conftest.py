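"""Shared fixtures: small, fast simulation specs used across the suite."""

import numpy as np
import pytest

from astroquant.simulate import ImageSimSpec, TraceSimSpec


@pytest.fixture
def small_image_spec():
    """Factory for a small clean field (fast to segment, exact to recover)."""

    def make(seed=0, **overrides):
        params = dict(
            width_px=320,
            height_px=320,
            n_cells=25,
            mean_cell_area_px=700,
            cell_area_dispersion=150,
            marker_positive_fractions={"GFAP": 0.5},
            illumination_gradient_amplitude=0.0,
            ambient_level=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        params.update(overrides)
        return ImageSimSpec(**params)

    return make


@pytest.fixture
def trace_spec():
    """Factory for a clean single-coverslip recording spec."""

    def make(seed=0, **overrides):
        params = dict(
            n_roi=5,
            latency_s=5.0,
            rise_duration_s=6.0,
            decay_tau_s=60.0,
            nonresponder_fraction=0.0,
            noise_sd=0.0,
            seed=seed,
        )
        params.update(overrides)
        return TraceSimSpec(**params)

    return make


@pytest.fixture
def flat_norm_trace():
    """Directly constructed normalized trace builder (time grid + values)."""
    from astroquant.kinetics import NormalizedTrace

    def make(time_s, f_over_f0, stimulus_time_s=20.0):
        return NormalizedTrace(
            time_s=np.asarray(time_s, float),
            f_over_f0=np.asarray(f_over_f0, float),
            f0=1.0,
            stimulus_time_s=stimulus_time_s,
        )

    return make
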