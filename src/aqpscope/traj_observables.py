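"""Trajectory-derived channel observables.

Implements the desk-scale MD analysis toolbox for single-file channels:

* permeation-event counting by a full-traversal state machine,
* single-channel osmotic permeability p_f via the collective-diffusion model
  (p_f = v_w * D_n, with D_n the diffusion constant of the collective water
  displacement coordinate n(t)),
* hydrogen-bond counts along the pore axis (geometric distance/angle criterion),
* 3-D number-density grids,
* chi1 side-chain dihedral series with rotamer-basin populations, and
* umbrella-sampling PMF reconstruction by self-consistent WHAM with barrier
  heights read off the profile.

Trajectories are plain in-memory arrays (plus a text frame-matrix dialect for
interchange), so every operation runs without any MD engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CoverageError,
    DomainError,
    EstimateError,
    FormatError,
    IterationError,
    ParameterError,
    TopologyError,
    UnwrapError,
)
from .pore_profiler import ChannelAxis

#: Gas constant in kJ mol^-1 K^-1.
R_KJ = 8.314e-3

#: Bulk water molecular volume in cm^3 (18.07 cm^3/mol / N_A).
V_WATER_CM3 = 2.99e-23


@dataclass
class Topology:
    """Per-atom metadata arrays (all length n_atoms)."""

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resnums: np.ndarray
    mol_ids: np.ndarray

    def __post_init__(self):
        lengths = {len(self.names), len(self.elements), len(self.resnames),
                   len(self.resnums), len(self.mol_ids)}
        if len(lengths) != 1:
            raise TopologyError("topology arrays must have equal length")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Trajectory:
    """Frames of coordinates for a fixed atom subset.

    times are in arbitrary but consistent units (ns by convention); coords is
    (n_frames, n_atoms, 3) in Angstrom; box holds per-frame orthorhombic box
    lengths (or None for non-periodic data).
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray | None = None
    topology: Topology | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("coords must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coords.shape[0]:
            raise ParameterError("times and coords disagree on frame count")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (len(self.times), 1))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times)))


@dataclass
class PermeationEvent:
    molecule_id: int
    t_enter: float
    t_exit: float
    direction: str  # "+z" | "-z"

    def __post_init__(self):
        if not self.t_enter < self.t_exit:
            raise ParameterError("event requires t_enter < t_exit")


@dataclass
class PermeabilityEstimate:
    """Collective-diffusion permeability: pf = v_w * D_n."""

    pf: float            # cm^3 s^-1 (mean over windows)
    pf_sd: float
    D_n: float           # collective coordinate diffusion, 1/time-unit
    L: float             # pore length, A
    v_w: float           # single-molecule volume, cm^3
    windows: list[float] = field(default_factory=list)


@dataclass
class HBondProfile:
    z_centers: np.ndarray
    counts: np.ndarray           # (n_bins, n_partners) mean bonds per frame visit
    partners: list[str]
    criterion: tuple[float, float]
    visits: np.ndarray = None    # frames in which the solute occupied each bin

    def total(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class PMFProfile:
    z: np.ndarray
    G: np.ndarray                # kJ/mol, zeroed at the reference minimum
    reference: float             # z where G = 0
    n_windows: int
    convergence_tol: float
    n_iterations: int = 0


@dataclass
class UmbrellaWindow:
    center: float                # A
    spring_constant: float       # kJ mol^-1 A^-2
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ParameterError("umbrella window has no samples")
        if self.spring_constant <= 0:
            raise ParameterError("spring constant must be positive")


@dataclass
class DihedralSeries:
    residue: int
    angles: np.ndarray           # degrees in (-180, 180]
    basins: np.ndarray           # labels from {"g-", "t", "g+"}
    populations: dict[str, float]
    transitions: int
    protonation: str = ""


# ---------------------------------------------------------------------------
# Text frame-matrix I/O
# ---------------------------------------------------------------------------

def write_frame_matrix(traj: Trajectory, path) -> None:
    """Write a trajectory as a plain text matrix with a JSON header comment.

    Row format: time, then x y z per atom, then the three box lengths
    (zeros when the trajectory is non-periodic).
    """
    header = {
        "format": "aqpscope-frame-matrix-1",
        "n_frames": traj.n_frames,
        "n_atoms": traj.n_atoms,
        "periodic": traj.box is not None,
    }
    if traj.topology is not None:
        header["topology"] = {
            "names": traj.topology.names.tolist(),
            "elements": traj.topology.elements.tolist(),
            "resnames": traj.topology.resnames.tolist(),
            "resnums": traj.topology.resnums.tolist(),
            "mol_ids": traj.topology.mol_ids.tolist(),
        }
    box = traj.box if traj.box is not None else np.zeros((traj.n_frames, 3))
    flat = np.hstack(
        [traj.times[:, None], traj.coords.reshape(traj.n_frames, -1), box]
    )
    np.savetxt(path, flat, header=json.dumps(header), fmt="%.8g")


def read_frame_matrix(path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing frame-matrix header")
    try:
        header = json.loads(first[1:].strip())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: bad header JSON: {exc}") from exc
    if header.get("format") != "aqpscope-frame-matrix-1":
        raise FormatError(f"{path}: not an aqpscope frame matrix")
    flat = np.atleast_2d(np.loadtxt(path))
    n_atoms = header["n_atoms"]
    times = flat[:, 0]
    coords = flat[:, 1 : 1 + 3 * n_atoms].reshape(len(flat), n_atoms, 3)
    box = flat[:, 1 + 3 * n_atoms :]
    topology = None
    if "topology" in header:
        t = header["topology"]
        topology = Topology(
            names=np.array(t["names"]),
            elements=np.array(t["elements"]),
            resnames=np.array(t["resnames"]),
            resnums=np.array(t["resnums"], dtype=int),
            mol_ids=np.array(t["mol_ids"], dtype=int),
        )
    return Trajectory(
        times=times,
        coords=coords,
        box=box if header.get("periodic") else None,
        topology=topology,
    )


# ---------------------------------------------------------------------------
# Axial projections and unwrapping
# ---------------------------------------------------------------------------

def molecule_positions(traj: Trajectory, mol_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, n_mol, 3) molecule centers and the molecule id array.

    Molecules are groups of atoms sharing a topology ``mol_id``; without a
    topology each atom is its own molecule.
    """
    if traj.topology is None:
        ids = np.arange(traj.n_atoms)
        return traj.coords, ids
    all_ids = traj.topology.mol_ids
    uniq = np.unique(all_ids) if mol_ids is None else np.asarray(mol_ids)
    centers = np.empty((traj.n_frames, len(uniq), 3))
    for j, m in enumerate(uniq):
        centers[:, j, :] = traj.coords[:, all_ids == m, :].mean(axis=1)
    return centers, uniq


def unwrap_axial(z: np.ndarray, period: np.ndarray | float | None) -> np.ndarray:
    """Minimum-image unwrap of axial coordinates (n_frames, n_mol)."""
    z = np.asarray(z, dtype=float)
    if period is None:
        return z
    dz = np.diff(z, axis=0)
    per = np.asarray(period, dtype=float)
    if per.ndim == 0:
        per = np.full(len(dz), float(per))
    per = per[: len(dz), None] if per.ndim == 1 else per
    dz = dz - per * np.round(dz / per)
    out = np.empty_like(z)
    out[0] = z[0]
    out[1:] = z[0] + np.cumsum(dz, axis=0)
    return out


def _axial_and_lateral(traj, axis, mol_ids=None):
    centers, ids = molecule_positions(traj, mol_ids)
    flat = centers.reshape(-1, 3)
    z = axis.axial(flat).reshape(traj.n_frames, len(ids))
    lat = axis.lateral_distance(flat).reshape(traj.n_frames, len(ids))
    return z, lat, ids


# ---------------------------------------------------------------------------
# Permeation events
# ---------------------------------------------------------------------------

def count_permeations(
    traj: Trajectory,
    axis: ChannelAxis,
    z_bounds: tuple[float, float],
    lateral_radius: float = np.inf,
    mol_ids=None,
) -> list[PermeationEvent]:
    """Full-traversal permeation events through [z_lo, z_hi].

    An event is recorded when a molecule moves from below z_lo to above z_hi
    (direction ``+z``) or the reverse, via a path that stays within
    ``lateral_radius`` of the axis while between the bounds.  Partial entries
    and re-crossings that exit the side they entered are not events.
    """
    z_lo, z_hi = z_bounds
    if not z_lo < z_hi:
        raise DomainError("z_bounds must satisfy z_lo < z_hi")
    z, lat, ids = _axial_and_lateral(traj, axis, mol_ids)
    span = z_hi - z_lo
    if traj.box is not None:
        # axial period: projection of the box onto the axis (orthorhombic
        # boxes aligned with the lab frame)
        period = np.abs(traj.box @ np.abs(axis.direction))
        z = unwrap_axial(z, period)
    elif np.any(np.abs(np.diff(z, axis=0)) > span):
        raise UnwrapError(
            "frame-to-frame axial jumps exceed the pore span and no box "
            "information is available for unwrapping"
        )
    events: list[PermeationEvent] = []
    for j, mol in enumerate(ids):
        state = None         # None | [entry_side, t_enter, lateral_ok]
        prev_region = None   # molecules starting inside never get an entry side
        zj = z[:, j]
        latj = lat[:, j]
        for i in range(traj.n_frames):
            if zj[i] < z_lo:
                region = "low"
            elif zj[i] > z_hi:
                region = "high"
            else:
                region = "in"
            if region == "in":
                if state is None and prev_region in ("low", "high"):
                    state = [prev_region, traj.times[i - 1], True]
                if state is not None and latj[i] > lateral_radius:
                    state[2] = False
            else:
                if state is not None:
                    side, t_enter, valid = state
                    if valid and region != side:
                        events.append(
                            PermeationEvent(
                                molecule_id=int(mol),
                                t_enter=float(t_enter),
                                t_exit=float(traj.times[i]),
                                direction="+z" if region == "high" else "-z",
                            )
                        )
                    state = None
            prev_region = region
    return events


# ---------------------------------------------------------------------------
# Collective-diffusion permeability
# ---------------------------------------------------------------------------

def _msd_diffusion(n: np.ndarray, dt: float,
                   lag_fraction: tuple[float, float]) -> float:
    """Diffusion constant of a 1-D series from MSD(tau) = 2 D tau."""
    m = len(n)
    lo = max(1, int(lag_fraction[0] * m))
    hi = max(lo + 1, int(lag_fraction[1] * m))
    lags = np.arange(lo, hi + 1)
    msd = np.array([np.mean((n[lag:] - n[:-lag]) ** 2) for lag in lags])
    taus = lags * dt
    # least squares through the origin
    slope = float((taus @ msd) / (taus @ taus))
    return slope / 2.0


def collective_displacement(
    traj: Trajectory,
    axis: ChannelAxis,
    pore_z: tuple[float, float],
    lateral_radius: float = np.inf,
    mol_ids=None,
) -> np.ndarray:
    """Cumulative collective coordinate n(t) (length n_frames).

    Per frame pair, dn = sum_i dz_i / L over molecules inside the pore region
    at both endpoints; n(t) is its cumulative sum, n(0) = 0.
    """
    z_lo, z_hi = pore_z
    if not z_lo < z_hi:
        raise DomainError("pore_z must satisfy z_lo < z_hi")
    L = z_hi - z_lo
    z, lat, _ = _axial_and_lateral(traj, axis, mol_ids)
    if traj.box is not None:
        period = np.abs(traj.box @ np.abs(axis.direction))
        zu = unwrap_axial(z, period)
    else:
        zu = z
    # pore membership is judged on the coordinates as given (wrapped)
    inside = (z >= z_lo) & (z <= z_hi) & (lat <= lateral_radius)
    both = inside[:-1] & inside[1:]
    if not np.any(both):
        raise EstimateError("no molecules inside the pore region")
    dz = np.diff(zu, axis=0)
    dn = np.where(both, dz, 0.0).sum(axis=1) / L
    n = np.concatenate([[0.0], np.cumsum(dn)])
    return n


def collective_pf(
    traj: Trajectory,
    axis: ChannelAxis,
    pore_z: tuple[float, float],
    window_length: float | None = None,
    v_w: float = V_WATER_CM3,
    lateral_radius: float = np.inf,
    lag_fraction: tuple[float, float] = (0.1, 0.5),
    mol_ids=None,
) -> PermeabilityEstimate:
    """Osmotic permeability from the collective-diffusion model.

    n(t) is accumulated from per-frame axial displacements of pore molecules;
    its MSD slope over the lag range gives D_n, and pf = v_w * D_n.  The
    trajectory is split into windows of ``window_length`` (time units of the
    trajectory; default: the whole trajectory) and pf is reported as mean
    +/- SD across windows.
    """
    n = collective_displacement(traj, axis, pore_z, lateral_radius, mol_ids)
    dt = traj.dt
    total_time = traj.times[-1] - traj.times[0]
    if window_length is None or window_length >= total_time:
        frames_per_window = len(n)
    else:
        frames_per_window = max(4, int(round(window_length / dt)))
    pfs, dns = [], []
    for start in range(0, len(n) - frames_per_window + 1, frames_per_window):
        seg = n[start : start + frames_per_window]
        d_n = _msd_diffusion(seg - seg[0], dt, lag_fraction)
        dns.append(d_n)
        pfs.append(v_w * d_n)
    if not pfs:
        raise EstimateError("window_length longer than the trajectory")
    z_lo, z_hi = pore_z
    return PermeabilityEstimate(
        pf=float(np.mean(pfs)),
        pf_sd=float(np.std(pfs, ddof=0)),
        D_n=float(np.mean(dns)),
        L=float(z_hi - z_lo),
        v_w=v_w,
        windows=[float(p) for p in pfs],
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_count_frame(coords: np.ndarray, triples, criterion=(3.5, 150.0)):
    """Per-triple bond flags for one frame.

    ``triples`` is a sequence of (donor_idx, hydrogen_idx, acceptor_idx).
    A bond requires donor-acceptor distance <= cutoff and D-H...A angle >=
    the angle cutoff (degrees).
    """
    d_cut, a_cut = criterion
    flags = []
    for d, h, a in triples:
        da = np.linalg.norm(coords[a] - coords[d])
        if da > d_cut:
            flags.append(False)
            continue
        v1 = coords[d] - coords[h]
        v2 = coords[a] - coords[h]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            flags.append(False)
            continue
        cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        flags.append(np.degrees(np.arccos(cosang)) >= a_cut)
    return np.array(flags, dtype=bool)


def hbond_profile(
    traj: Trajectory,
    triples,
    partner_labels,
    axis: ChannelAxis,
    solute_index: int,
    bin_width: float = 0.5,
    z_range: tuple[float, float] | None = None,
    criterion: tuple[float, float] = (3.5, 150.0),
) -> HBondProfile:
    """Mean hydrogen-bond count per solute z-bin, stratified by partner.

    ``triples`` are (donor, hydrogen, acceptor) atom indices;
    ``partner_labels`` assigns each triple to a named partner (e.g. the
    filter position of the protein residue involved).
    """
    if len(triples) != len(partner_labels):
        raise TopologyError("one partner label per donor-H-acceptor triple")
    partners = sorted(set(partner_labels))
    col = {p: i for i, p in enumerate(partners)}
    z_sol = axis.axial(traj.coords[:, solute_index, :]).ravel()
    if z_range is None:
        z_range = (float(z_sol.min()), float(z_sol.max()) + 1e-9)
    edges = np.arange(z_range[0], z_range[1] + bin_width, bin_width)
    n_bins = len(edges) - 1
    if n_bins < 1:
        raise ParameterError("empty z range for binning")
    counts = np.zeros((n_bins, len(partners)))
    visits = np.zeros(n_bins)
    for f in range(traj.n_frames):
        b = np.searchsorted(edges, z_sol[f], side="right") - 1
        if not 0 <= b < n_bins:
            continue
        visits[b] += 1
        flags = hbond_count_frame(traj.coords[f], triples, criterion)
        for flag, lab in zip(flags, partner_labels):
            if flag:
                counts[b, col[lab]] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_counts = np.where(visits[:, None] > 0, counts / visits[:, None], 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return HBondProfile(z_centers=centers, counts=mean_counts,
                        partners=partners, criterion=criterion, visits=visits)


# ---------------------------------------------------------------------------
# Density grids
# ---------------------------------------------------------------------------

def density_grid(
    traj: Trajectory,
    indices,
    voxel: float,
    bounds: np.ndarray | None = None,
):
    """Time-averaged number-density grid for the selected atoms.

    Returns (grid, edges) where grid has units of count / A^3 and integrates
    (sum * voxel volume) to the mean selected-atom count inside the bounds.
    """
    if voxel <= 0:
        raise ParameterError("voxel size must be positive")
    pts = traj.coords[:, indices, :].reshape(-1, 3)
    if bounds is None:
        lo = pts.min(axis=0) - 0.5 * voxel
        hi = pts.max(axis=0) + 0.5 * voxel
    else:
        bounds = np.asarray(bounds, dtype=float)
        lo, hi = bounds[0], bounds[1]
    edges = [np.arange(lo[k], hi[k] + voxel, voxel) for k in range(3)]
    grid, _ = np.histogramdd(pts, bins=edges)
    grid = grid / (traj.n_frames * voxel**3)
    return grid, edges


def write_density_grid(grid: np.ndarray, edges, path) -> None:
    """Simple text voxel format: JSON header (origin, voxel, dims) + values."""
    origin = [float(e[0]) for e in edges]
    voxel = float(edges[0][1] - edges[0][0])
    header = {
        "format": "aqpscope-density-1",
        "origin": origin,
        "voxel": voxel,
        "dims": list(grid.shape),
    }
    np.savetxt(path, grid.reshape(-1, grid.shape[-1]),
               header=json.dumps(header), fmt="%.8g")


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees (-180, 180] following the IUPAC convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang != -180.0 else 180.0)


_BASIN_CENTERS = {"g-": -60.0, "t": 180.0, "g+": 60.0}


def _assign_basin(angle: float) -> str:
    best, best_d = None, 1e9
    for name, c in _BASIN_CENTERS.items():
        d = abs((angle - c + 180.0) % 360.0 - 180.0)
        if d < best_d:
            best, best_d = name, d
    return best


def chi1_populations(traj: Trajectory, residue: int,
                     protonation: str = "") -> DihedralSeries:
    """Chi1 (N-CA-CB-CG) series with rotamer-basin populations and transitions."""
    if traj.topology is None:
        raise TopologyError("chi1 requires a topology")
    idx = {}
    for name in ("N", "CA", "CB", "CG"):
        where = np.where(
            (traj.topology.resnums == residue) & (traj.topology.names == name)
        )[0]
        if len(where) == 0:
            raise TopologyError(f"residue {residue}: missing atom {name}")
        idx[name] = int(where[0])
    angles = np.array(
        [
            dihedral_angle(
                traj.coords[f, idx["N"]],
                traj.coords[f, idx["CA"]],
                traj.coords[f, idx["CB"]],
                traj.coords[f, idx["CG"]],
            )
            for f in range(traj.n_frames)
        ]
    )
    basins = np.array([_assign_basin(a) for a in angles])
    pops = {b: float(np.mean(basins == b)) for b in _BASIN_CENTERS}
    transitions = int(np.sum(basins[1:] != basins[:-1]))
    return DihedralSeries(residue=residue, angles=angles, basins=basins,
                          populations=pops, transitions=transitions,
                          protonation=protonation)


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham_pmf(
    windows: list[UmbrellaWindow],
    temperature: float,
    grid: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 50000,
    bulk_region: tuple[float, float] | None = None,
) -> PMFProfile:
    """Self-consistent WHAM reconstruction of an umbrella-sampled PMF.

    Iterates the standard coupled equations for the unbiased bin
    probabilities and per-window free-energy shifts f_k until the largest
    change in any f_k is below ``tol`` (kJ/mol).  G is shifted so that the
    minimum over ``bulk_region`` (default: the whole grid) is zero.
    """
    if len(windows) < 2:
        raise CoverageError("need at least two umbrella windows")
    ordered = sorted(windows, key=lambda w: w.center)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if a.samples.max() < b.samples.min():
            raise CoverageError(
                f"windows at {a.center} and {b.center} do not overlap"
            )
    kt = R_KJ * temperature
    all_samples = np.concatenate([w.samples for w in windows])
    if grid is None:
        lo, hi = np.percentile(all_samples, [0.1, 99.9])
        grid = np.linspace(lo, hi, 121)
    edges = np.asarray(grid, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    n_win = len(windows)
    hist = np.zeros((n_win, n_bins))
    n_k = np.zeros(n_win)
    for k, w in enumerate(windows):
        h, _ = np.histogram(w.samples, bins=edges)
        hist[k] = h
        n_k[k] = h.sum()
    total = hist.sum(axis=0)
    if not np.any(total > 0):
        raise CoverageError("no samples fall on the grid")
    bias = np.array(
        [0.5 * w.spring_constant * (centers - w.center) ** 2 for w in windows]
    )  # (n_win, n_bins), kJ/mol
    f = np.zeros(n_win)
    boltz = np.exp(-bias / kt)
    residual = np.inf
    for it in range(max_iter):
        denom = (n_k[:, None] * np.exp(f[:, None] / kt) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        z_k = (p[None, :] * boltz).sum(axis=1)
        f_new = -kt * np.log(z_k)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tol:
            break
    else:
        raise IterationError(
            f"WHAM did not converge in {max_iter} iterations", residual=residual
        )
    mask = p > 0
    g = np.full(n_bins, np.nan)
    g[mask] = -kt * np.log(p[mask])
    if bulk_region is not None:
        sel = mask & (centers >= bulk_region[0]) & (centers <= bulk_region[1])
        if not np.any(sel):
            raise DomainError("bulk region contains no occupied bins")
    else:
        sel = mask
    ref_idx = np.where(sel)[0][np.nanargmin(g[sel])]
    g -= g[ref_idx]
    return PMFProfile(z=centers[mask], G=g[mask],
                      reference=float(centers[ref_idx]),
                      n_windows=n_win, convergence_tol=tol, n_iterations=it + 1)


def barrier_height(pmf: PMFProfile, region: tuple[float, float]) -> float:
    """max G inside the region minus min G over the flanking bulk (kJ/mol)."""
    z_lo, z_hi = region
    inside = (pmf.z >= z_lo) & (pmf.z <= z_hi)
    if not np.any(inside):
        raise DomainError(f"region {region} not covered by the PMF grid")
    outside = ~inside
    baseline = float(np.nanmin(pmf.G[outside])) if np.any(outside) else float(
        np.nanmin(pmf.G)
    )
    return float(np.nanmax(pmf.G[inside]) - baseline)


def barrier_permeability_ratio(barrier_low: float, barrier_high: float,
                               temperature: float = 298.0) -> float:
    """Boltzmann permeability ratio exp((G_high - G_low) / RT) between two barriers."""
    return float(np.exp((barrier_high - barrier_low) / (R_KJ * temperature)))
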