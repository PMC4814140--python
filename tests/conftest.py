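"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force
(exhaustive lateral grid search for pore radii, per-frame state scanning
for permeation events) so that they stay independent of the library code
paths they check.
"""

import numpy as np
import pytest

from aqpscope.pore_profiler import ChannelAxis, ProbeParams, fit_axis, profile_pore
from aqpscope.synthetic_data import (
    attip21_like_sequence,
    make_cylinder_structure,
    make_hourglass_structure,
)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def grid_slice_radius(structure, axis, z, lateral_bound=5.0, step=0.05,
                      cutoff=12.0):
    """Exhaustive lateral grid search for the best probe radius at one slice."""
    u, v = axis.frame()
    p = axis.origin + z * axis.direction
    coords = structure.coords
    radii = structure.radii
    near = np.linalg.norm(coords - p, axis=1) <= cutoff + lateral_bound
    coords, radii = coords[near], radii[near]
    if len(coords) == 0:
        return np.inf
    offsets = np.arange(-lateral_bound, lateral_bound + step / 2, step)
    a, b = np.meshgrid(offsets, offsets, indexing="ij")
    mask = a**2 + b**2 <= lateral_bound**2
    centers = p + a[mask, None] * u + b[mask, None] * v
    d = np.linalg.norm(centers[:, None, :] - coords[None, :, :], axis=2)
    best = np.max(np.min(d - radii[None, :], axis=1))
    return max(float(best), 0.0)


def brute_force_events(z, lat, z_lo, z_hi, lateral_radius=np.inf):
    """Per-molecule scan counting full traversals on continuous paths.

    ``z`` and ``lat`` are (n_frames, n_mol) arrays of axial and lateral
    coordinates (already unwrapped).  Written independently of the library's
    state machine: it records, for each visit to the inside region, the side
    of entry and the side of exit.
    """
    n_frames, n_mol = z.shape
    total = 0
    for j in range(n_mol):
        visit_start = None
        entered_side = None
        lateral_ok = True
        prev_region = None
        for i in range(n_frames):
            if z[i, j] < z_lo:
                region = "low"
            elif z[i, j] > z_hi:
                region = "high"
            else:
                region = "in"
            if region == "in":
                if prev_region in ("low", "high"):
                    entered_side = prev_region
                    lateral_ok = True
                    visit_start = i
                if visit_start is not None and lat[i, j] > lateral_radius:
                    lateral_ok = False
            else:
                if entered_side is not None:
                    if lateral_ok and region != entered_side:
                        total += 1
                    entered_side = None
                    visit_start = None
            prev_region = region
    return total


@pytest.fixture(scope="session")
def grid_oracle():
    return grid_slice_radius


@pytest.fixture(scope="session")
def event_oracle():
    return brute_force_events


# ---------------------------------------------------------------------------
# Structures and sequences
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def cylinder():
    """Short 2.0 A cylinder (dense wall) used across profiler tests."""
    return make_cylinder_structure(inner_radius=2.0, length=12.0)


@pytest.fixture(scope="session")
def hourglass():
    return make_hourglass_structure(throat_radius=1.5, cone_slope=0.15,
                                    length=12.0)


@pytest.fixture(scope="session")
def lab_z_axis():
    def _make(structure, span=None):
        z = structure.coords[:, 2]
        lo, hi = (z.min(), z.max()) if span is None else span
        return ChannelAxis(origin=np.zeros(3),
                           direction=np.array([0.0, 0.0, 1.0]),
                           z_min=float(lo), z_max=float(hi))
    return _make


@pytest.fixture(scope="session")
def tip2_sequence():
    return attip21_like_sequence()


@pytest.fixture(scope="session")
def fast_params():
    """Profiler parameters for quick tests (coarser z, fewer restarts)."""
    return ProbeParams(z_step=1.0, lateral_bound=5.0, n_restarts=4, seed=11)
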