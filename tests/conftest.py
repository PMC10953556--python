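"""Shared fixtures: scenario runs and vertex meshes are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from yapflow import experiments as ex
from yapflow import vertex as vx


@pytest.fixture(scope="session")
def scenario():
    """Factory returning (and caching) full scenario runs by preset name."""
    cache: dict = {}

    def run(name: str, **overrides):
        key = (name, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = ex.run_scenario(ex.preset(name, **overrides))
        return cache[key]

    return run


@pytest.fixture(scope="session")
def mesh64():
    return vx.build_monolayer(64, jitter=0.0, seed=1)


@pytest.fixture(scope="session")
def recoil_sweep(mesh64):
    """Recoil angles over the calibrated stress range (plus the s=0 control)."""
    interior = np.nonzero(~mesh64.boundary_cells())[0]
    target = int(interior[len(interior) // 2])
    svals = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    angles = tuple(
        vx.ablate_and_recoil(mesh64, target, s).recoil_angle for s in svals
    )
    return svals, angles


@pytest.fixture(scope="session")
def monolayer_pair(mesh64):
    """Relaxed homogeneous control and cap-heterogeneous monolayer at matched s."""
    hom = mesh64.copy()
    hom.fiber_stress[:] = 0.6
    hom = vx.relax(hom)
    het = vx.assign_cap_heterogeneity(mesh64, 0.5, cap_strength=1.0, seed=3)
    het.fiber_stress[:] = 0.6
    het = vx.relax(het)
    return hom, het
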