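"""Trajectory observables: events, p_f, H-bonds, density, chi1, WHAM."""

import numpy as np
import pytest

from aqpscope.errors import (
    CoverageError,
    DomainError,
    ParameterError,
    TopologyError,
    UnwrapError,
)
from aqpscope.pore_profiler import ChannelAxis
from aqpscope.synthetic_data import (
    make_brownian_trajectory,
    make_umbrella_samples,
)
from aqpscope.traj_observables import (
    PMFProfile,
    Topology,
    Trajectory,
    UmbrellaWindow,
    barrier_height,
    barrier_permeability_ratio,
    chi1_populations,
    collective_pf,
    count_permeations,
    density_grid,
    dihedral_angle,
    hbond_profile,
    read_frame_matrix,
    wham_pmf,
    write_frame_matrix,
)

AXIS = ChannelAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]),
                   z_min=-50.0, z_max=50.0)


def _single_molecule_traj(zs, xy=(0.0, 0.0), box=None):
    n = len(zs)
    coords = np.zeros((n, 1, 3))
    coords[:, 0, 0] = xy[0]
    coords[:, 0, 1] = xy[1]
    coords[:, 0, 2] = zs
    return Trajectory(times=np.arange(n, dtype=float), coords=coords, box=box)


# ---------------------------------------------------------------------------
# Frame-matrix round trip
# ---------------------------------------------------------------------------

def test_frame_matrix_round_trip(tmp_path):
    traj, _ = make_brownian_trajectory(n_molecules=3, n_frames=20, seed=4)
    path = tmp_path / "t.traj"
    write_frame_matrix(traj, path)
    back = read_frame_matrix(path)
    np.testing.assert_allclose(back.coords, traj.coords, rtol=1e-6)
    np.testing.assert_allclose(back.times, traj.times, rtol=1e-6)
    assert list(back.topology.mol_ids) == list(traj.topology.mol_ids)


# ---------------------------------------------------------------------------
# Permeation events
# ---------------------------------------------------------------------------

def test_single_linear_traversal_is_one_event():
    traj = _single_molecule_traj(np.linspace(-20, 20, 100))
    events = count_permeations(traj, AXIS, (-10, 10))
    assert len(events) == 1
    assert events[0].direction == "+z"
    assert events[0].t_enter < events[0].t_exit


def test_oscillation_inside_bounds_is_no_event():
    t = np.arange(400)
    traj = _single_molecule_traj(5.0 * np.sin(t / 7.0))
    assert count_permeations(traj, AXIS, (-10, 10)) == []


def test_recrossing_out_the_entry_side_is_no_event():
    zs = np.concatenate([np.linspace(-15, 5, 40), np.linspace(5, -15, 40)])
    traj = _single_molecule_traj(zs)
    assert count_permeations(traj, AXIS, (-10, 10)) == []


def test_lateral_excursion_disqualifies_the_passage():
    zs = np.linspace(-20, 20, 100)
    xs = np.zeros(100)
    xs[50] = 8.0  # steps off-axis while between the bounds
    coords = np.zeros((100, 1, 3))
    coords[:, 0, 0] = xs
    coords[:, 0, 2] = zs
    traj = Trajectory(times=np.arange(100.0), coords=coords)
    assert count_permeations(traj, AXIS, (-10, 10), lateral_radius=5.0) == []
    assert len(count_permeations(traj, AXIS, (-10, 10))) == 1


def test_wrapped_coordinates_without_box_raise():
    zs = np.mod(np.linspace(0, 80, 200), 20.0) - 10.0
    traj = _single_molecule_traj(zs)
    with pytest.raises(UnwrapError):
        count_permeations(traj, AXIS, (-5, 5))


def test_event_counts_match_brute_force_oracle(event_oracle):
    """50 seeded random walkers: state machine vs independent enumeration."""
    traj, truth = make_brownian_trajectory(
        n_molecules=50, D=4.0, pore_z=(-8.0, 8.0), n_frames=10000, dt=0.01,
        seed=12, mode="reflecting", margin=6.0, lateral_sigma=0.5,
    )
    events = count_permeations(traj, AXIS, (-8.0, 8.0))
    z = traj.coords[:, :, 2]
    lat = np.hypot(traj.coords[:, :, 0], traj.coords[:, :, 1])
    assert len(events) == event_oracle(z, lat, -8.0, 8.0)
    assert len(events) == truth["events"]


def test_drift_walkers_cross_exactly_once():
    traj, truth = make_brownian_trajectory(
        n_molecules=10, D=0.05, pore_z=(-10.0, 10.0), n_frames=2000, dt=0.01,
        seed=3, mode="drift", drift=3.0, margin=10.0,
    )
    events = count_permeations(traj, AXIS, (-10.0, 10.0))
    assert len(events) == truth["events"] == 10
    assert all(e.direction == "+z" for e in events)


def test_frozen_walkers_have_no_events():
    traj, truth = make_brownian_trajectory(
        n_molecules=10, D=0.0, pore_z=(-10.0, 10.0), n_frames=500, dt=0.01,
        seed=5, mode="reflecting",
    )
    assert truth["events"] == 0
    assert count_permeations(traj, AXIS, (-10.0, 10.0)) == []


# ---------------------------------------------------------------------------
# Collective-diffusion permeability
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def brownian_pore():
    return make_brownian_trajectory(
        n_molecules=16, D=1.0, pore_z=(-10.0, 10.0), n_frames=100000,
        dt=0.05, seed=0, mode="periodic",
    )


def test_collective_diffusion_recovers_analytic_rate(brownian_pore):
    """D_n of N confined Brownian walkers approaches N * D / L^2."""
    traj, truth = brownian_pore
    est = collective_pf(traj, AXIS, (-10.0, 10.0), window_length=25.0)
    assert est.D_n == pytest.approx(truth["D_n_theory"], rel=0.15)
    assert est.pf == pytest.approx(est.v_w * est.D_n, rel=1e-12)


def test_pf_scales_linearly_with_molecular_volume(brownian_pore):
    traj, _ = brownian_pore
    est1 = collective_pf(traj, AXIS, (-10.0, 10.0), window_length=25.0,
                         v_w=1.0e-23)
    est2 = collective_pf(traj, AXIS, (-10.0, 10.0), window_length=25.0,
                         v_w=2.0e-23)
    assert est2.pf == pytest.approx(2.0 * est1.pf, rel=1e-9)


def test_frozen_waters_give_zero_pf():
    traj, _ = make_brownian_trajectory(n_molecules=8, D=0.0, n_frames=2000,
                                       dt=0.05, seed=1, mode="periodic")
    est = collective_pf(traj, AXIS, (-10.0, 10.0))
    assert est.pf == 0.0


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _hbond_traj(da_distances, n_frames=None):
    """Donor N at origin, H on the N-O axis, acceptor O at the given distance."""
    n_frames = n_frames or len(da_distances)
    coords = np.zeros((n_frames, 3, 3))
    for f, d in enumerate(da_distances):
        coords[f, 0] = (0.0, 0.0, 0.0)        # donor N (the solute)
        coords[f, 1] = (0.0, 0.0, 1.0)        # hydrogen
        coords[f, 2] = (0.0, 0.0, d)          # acceptor O
    return Trajectory(times=np.arange(n_frames, dtype=float), coords=coords)


def test_ideal_linear_hbond_counts_one():
    traj = _hbond_traj([2.9])
    prof = hbond_profile(traj, [(0, 1, 2)], ["HEP"], AXIS, solute_index=0,
                         bin_width=1.0, z_range=(-1.0, 1.0))
    assert prof.total().sum() == pytest.approx(1.0)


def test_long_distance_pair_counts_zero():
    traj = _hbond_traj([4.0])
    prof = hbond_profile(traj, [(0, 1, 2)], ["HEP"], AXIS, solute_index=0,
                         bin_width=1.0, z_range=(-1.0, 1.0))
    assert prof.total().sum() == 0.0


def test_bent_geometry_fails_angle_criterion():
    coords = np.zeros((1, 3, 3))
    coords[0, 1] = (1.0, 0.0, 0.0)    # hydrogen off the N-O axis (90 degrees)
    coords[0, 2] = (0.0, 0.0, 3.0)
    traj = Trajectory(times=[0.0], coords=coords)
    prof = hbond_profile(traj, [(0, 1, 2)], ["HEP"], AXIS, solute_index=0,
                         bin_width=1.0, z_range=(-1.0, 1.0))
    assert prof.total().sum() == 0.0


def test_scripted_duty_cycle_recovered_per_bin():
    """On/off bond script: per-bin averages equal the scripted duty cycle."""
    script = ([2.9] * 3 + [4.5] * 1) * 25     # 75% duty cycle, 100 frames
    traj = _hbond_traj(script)
    prof = hbond_profile(traj, [(0, 1, 2)], ["LCP"], AXIS, solute_index=0,
                         bin_width=1.0, z_range=(-1.0, 1.0))
    occupied = prof.visits > 0
    assert prof.counts[occupied, 0] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# Density grids
# ---------------------------------------------------------------------------

def test_single_static_particle_density():
    coords = np.full((5, 1, 3), 0.5)
    traj = Trajectory(times=np.arange(5.0), coords=coords)
    grid, edges = density_grid(traj, [0], voxel=1.0)
    assert grid.sum() * 1.0 == pytest.approx(1.0, rel=1e-12)
    assert np.count_nonzero(grid) == 1


def test_density_integral_conserved_across_voxel_sizes():
    rng = np.random.default_rng(8)
    coords = rng.uniform(0, 10, size=(50, 40, 3))
    traj = Trajectory(times=np.arange(50.0), coords=coords)
    bounds = np.array([[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
    for voxel in (1.0, 2.0):
        grid, _ = density_grid(traj, slice(None), voxel, bounds=bounds)
        assert grid.sum() * voxel**3 == pytest.approx(40.0, rel=1e-6)


def test_uniform_density_within_binomial_bounds():
    rng = np.random.default_rng(9)
    n_frames, n_atoms = 200, 100
    coords = rng.uniform(0, 8, size=(n_frames, n_atoms, 3))
    traj = Trajectory(times=np.arange(float(n_frames)), coords=coords)
    bounds = np.array([[0.0, 0.0, 0.0], [8.0, 8.0, 8.0]])
    grid, _ = density_grid(traj, slice(None), 2.0, bounds=bounds)
    counts = grid * n_frames * 8.0  # raw counts per voxel
    p = 8.0 / 8.0**3
    expected = n_frames * n_atoms * p
    sd = np.sqrt(n_frames * n_atoms * p * (1 - p))
    assert np.all(np.abs(counts - expected) < 5 * sd)


def test_density_rejects_bad_voxel():
    traj = Trajectory(times=[0.0], coords=np.zeros((1, 1, 3)))
    with pytest.raises(ParameterError):
        density_grid(traj, [0], voxel=0.0)


# ---------------------------------------------------------------------------
# Chi1 dihedrals
# ---------------------------------------------------------------------------

def _chi1_traj(chis):
    """Closed-form sidechain geometry: chi1 equals the planted angle.

    With N=(0,1,0), CA=(0,0,0), CB=(1,0,0) and CG placed on the unit circle
    perpendicular to CA-CB, the dihedral is the circle angle by construction.
    """
    n = len(chis)
    coords = np.zeros((n, 4, 3))
    for f, chi in enumerate(chis):
        rad = np.radians(chi)
        coords[f, 0] = (0.0, 1.0, 0.0)                        # N
        coords[f, 1] = (0.0, 0.0, 0.0)                        # CA
        coords[f, 2] = (1.0, 0.0, 0.0)                        # CB
        coords[f, 3] = (1.0, 1.5 * np.cos(rad), 1.5 * np.sin(rad))  # CG
    top = Topology(
        names=np.array(["N", "CA", "CB", "CG"]),
        elements=np.array(["N", "C", "C", "C"]),
        resnames=np.array(["HIS"] * 4),
        resnums=np.array([131] * 4),
        mol_ids=np.zeros(4, dtype=int),
    )
    return Trajectory(times=np.arange(float(n)), coords=coords, topology=top)


def test_dihedral_textbook_cases():
    assert dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0),
                          (1, 1, 0)) == pytest.approx(0.0, abs=1e-9)
    assert abs(dihedral_angle((0, 1, 0), (0, 0, 0), (1, 0, 0),
                              (1, -1, 0))) == pytest.approx(180.0, abs=1e-9)


def test_chi1_recovers_constructed_angle():
    series = chi1_populations(_chi1_traj([60.0]), residue=131)
    assert series.angles[0] == pytest.approx(60.0, abs=0.1)
    assert series.basins[0] == "g+"


def test_chi1_mirror_image_flips_sign():
    traj = _chi1_traj([60.0])
    mirrored = Trajectory(times=traj.times,
                          coords=traj.coords * np.array([1.0, 1.0, -1.0]),
                          topology=traj.topology)
    series = chi1_populations(mirrored, residue=131)
    assert series.angles[0] == pytest.approx(-60.0, abs=0.1)


def test_chi1_transition_count_matches_script():
    chis = ([-60.0] * 10 + [180.0] * 10) * 5   # 9 basin switches
    series = chi1_populations(_chi1_traj(chis), residue=131)
    assert series.transitions == 9
    assert series.populations["g-"] == pytest.approx(0.5)
    assert series.populations["t"] == pytest.approx(0.5)


def test_chi1_missing_atom_raises():
    traj = _chi1_traj([60.0])
    with pytest.raises(TopologyError, match="CG"):
        chi1_populations(
            Trajectory(times=traj.times, coords=traj.coords[:, :3, :],
                       topology=Topology(
                           names=traj.topology.names[:3],
                           elements=traj.topology.elements[:3],
                           resnames=traj.topology.resnames[:3],
                           resnums=traj.topology.resnums[:3],
                           mol_ids=traj.topology.mol_ids[:3])),
            residue=131)


# ---------------------------------------------------------------------------
# WHAM and barriers
# ---------------------------------------------------------------------------

CENTERS = np.linspace(-10, 10, 21)


def test_wham_flat_pmf_recovered_flat():
    windows = make_umbrella_samples(lambda z: np.zeros_like(np.asarray(z, dtype=float)),
                                    CENTERS, spring_k=8.0,
                                    n_per_window=40000, seed=1)
    pmf = wham_pmf(windows, 298.0)
    core = (pmf.z >= -9) & (pmf.z <= 9)
    assert pmf.G[core].max() - pmf.G[core].min() < 0.5


def test_wham_recovers_harmonic_curvature():
    a = 0.5
    windows = make_umbrella_samples(lambda z: 0.5 * a * np.asarray(z) ** 2,
                                    CENTERS, spring_k=8.0,
                                    n_per_window=4000, seed=2)
    pmf = wham_pmf(windows, 298.0)
    core = (pmf.z >= -8) & (pmf.z <= 8)
    coef = np.polyfit(pmf.z[core], pmf.G[core], 2)
    assert 2 * coef[0] == pytest.approx(a, rel=0.10)


def test_wham_error_shrinks_with_sample_count():
    a = 0.5

    def rms_error(n):
        windows = make_umbrella_samples(lambda z: 0.5 * a * np.asarray(z) ** 2,
                                        CENTERS, spring_k=8.0,
                                        n_per_window=n, seed=3)
        pmf = wham_pmf(windows, 298.0)
        core = (pmf.z >= -8) & (pmf.z <= 8)
        true = 0.5 * a * pmf.z[core] ** 2
        true = true - true.min()
        return np.sqrt(np.mean((pmf.G[core] - true) ** 2))

    assert rms_error(16000) < rms_error(1000)


def test_wham_rejects_non_overlapping_windows():
    rng = np.random.default_rng(0)
    windows = [
        UmbrellaWindow(center=-5.0, spring_constant=8.0,
                       samples=rng.normal(-5.0, 0.2, 500)),
        UmbrellaWindow(center=5.0, spring_constant=8.0,
                       samples=rng.normal(5.0, 0.2, 500)),
    ]
    with pytest.raises(CoverageError):
        wham_pmf(windows, 298.0)


def _pmf(zs, gs):
    gs = np.asarray(gs, dtype=float)
    return PMFProfile(z=np.asarray(zs, dtype=float), G=gs - gs.min(),
                      reference=0.0, n_windows=0, convergence_tol=0.0)


def test_barrier_height_of_constructed_profiles():
    z = np.linspace(-10, 10, 201)
    harmonic = _pmf(z, 12.0 - 0.12 * z**2)    # apex 12 above the flanks
    assert barrier_height(harmonic, (-5, 5)) == pytest.approx(12.0, abs=1e-9)
    flat = _pmf(z, np.zeros_like(z))
    assert barrier_height(flat, (-5, 5)) == 0.0
    double_well = _pmf(z, 5.0 * np.cos(np.pi * z / 10.0) ** 2)
    assert barrier_height(double_well, (-4, 4)) == pytest.approx(5.0, abs=1e-3)
    with pytest.raises(DomainError):
        barrier_height(flat, (50, 60))


def test_boltzmann_factor_between_channel_and_membrane_barriers():
    """A 15 vs 20 kJ/mol barrier pair at 298 K differs ~7.5-fold in rate."""
    ratio = barrier_permeability_ratio(15.0, 20.0, 298.0)
    assert ratio == pytest.approx(np.exp(5.0 / (8.314e-3 * 298.0)), rel=1e-12)
    assert ratio == pytest.approx(7.5, abs=0.1)
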