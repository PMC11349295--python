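"""Shared fixtures: toy channels (fast) and the reference device (one solve)."""

from __future__ import annotations

import numpy as np
import pytest

from idepsep.field import gate_thresholds, solve_potential
from idepsep.geometry import DomainMask, build_reference_geometry, rasterize


@pytest.fixture(scope="session")
def straight_mask() -> DomainMask:
    """Gate-free rectangular channel, 1000 × 80 μm at 1 μm spacing."""
    nx, ny = 1000, 80
    fluid = np.ones((nx, ny), dtype=bool)
    return DomainMask(
        spacing=1.0,
        fluid=fluid,
        inlet_cells=np.arange(ny),
        outlet_cells=np.arange(ny),
        throats=(),
    )


@pytest.fixture(scope="session")
def toy3_geometry():
    """Three-gate toy channel: widths 50, 40, 30 μm in an 80 μm channel."""
    return build_reference_geometry(
        widths=[50.0, 40.0, 30.0],
        group_size=1,
        length_cm=0.15,
        background_width=80.0,
    )


@pytest.fixture(scope="session")
def toy3_mask(toy3_geometry):
    return rasterize(toy3_geometry, 1.0)


@pytest.fixture(scope="session")
def toy3_solution(toy3_mask):
    return solve_potential(toy3_mask, 100.0)


@pytest.fixture(scope="session")
def toy3_profile(toy3_solution):
    return gate_thresholds(toy3_solution)


@pytest.fixture(scope="session")
def reference():
    """Reference 27-gate device: geometry + solved, calibrated gate profile.

    One full-channel Laplace solve shared across the whole session.
    """
    from idepsep.presets import reference_profile

    geometry, profile = reference_profile()
    return geometry, profile
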