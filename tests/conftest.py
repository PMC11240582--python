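"""Shared fixtures: small phantoms and the seeded recovery sweep."""

from __future__ import annotations

import numpy as np
import pytest

from aortamorph import (
    ContourParams,
    PhantomSpec,
    extract_flap_volume,
    generate_phantom,
)

#: reference acquisition spacing (z, y, x) mm used throughout the tests
SPACING = (1.25, 0.8242, 0.8242)


@pytest.fixture(scope="session")
def small_phantom():
    """One modest phantom with asymmetric lumens and a drifting centreline."""
    spec = PhantomSpec(
        n_slices=8,
        grid_shape=(96, 96),
        spacing=SPACING,
        outer_diameter=50.0,
        flap_thickness=2.4,
        flap_offset=10.0,
        flap_angle=0.6,
        centerline_amplitude=3.0,
        seed=11,
    )
    return spec, generate_phantom(spec)


def sweep_specs() -> list[PhantomSpec]:
    """Ten seeded phantoms spanning the documented parameter ranges."""
    rng = np.random.default_rng(7)
    outer = np.linspace(35.0, 55.0, 10)
    thickness = rng.permutation(np.linspace(1.5, 3.5, 10))
    offset = rng.permutation(np.linspace(0.0, 12.0, 10))
    angle = (np.arange(10) * 2.399963) % np.pi  # golden-angle spread
    specs = []
    for i in range(10):
        specs.append(
            PhantomSpec(
                n_slices=10,
                grid_shape=(96, 96),
                spacing=SPACING,
                outer_diameter=float(outer[i]),
                flap_thickness=float(thickness[i]),
                flap_offset=float(offset[i]),
                flap_angle=float(angle[i]),
                centerline_amplitude=5.0,
                seed=100 + i,
            )
        )
    return specs


@pytest.fixture(scope="session")
def phantom_sweep():
    """(spec, phantom result, extracted flap volume) for the 10-phantom sweep."""
    params = ContourParams()
    out = []
    for spec in sweep_specs():
        result = generate_phantom(spec)
        flap_vol = extract_flap_volume(result.annotation, params)
        out.append((spec, result, flap_vol))
    return out
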