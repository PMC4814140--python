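"""Synthetic fixtures with known ground truth.

Everything the analysis pipeline consumes can be generated here at desk
scale: toy channel structures whose true pore radius is known by
construction, Brownian single-file trajectories with known diffusion
constants and logged traversals, umbrella-sampling windows drawn from an
analytic free-energy profile, noisy single-exponential stopped-flow traces,
and the packaged yeast-assay fixtures (selectivity-filter codes with
complementation outcomes, and the raw construct rate table).

Every generator is deterministic given (parameters, seed); the seed and the
ground truth are returned alongside the data so downstream tests never
re-derive them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .kinetics import Trace
from .structure_io import Atom, SequenceRecord, Structure
from .traj_observables import R_KJ, Topology, Trajectory, UmbrellaWindow

# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _ring_atoms(radius, z, n_atoms, vdw, serial0, resnum0):
    atoms = []
    for i in range(n_atoms):
        ang = 2 * np.pi * i / n_atoms
        atoms.append(
            Atom(
                serial=serial0 + i,
                name="W",
                element="C",
                residue_name="WAL",
                residue_number=resnum0,
                chain="A",
                position=(radius * np.cos(ang), radius * np.sin(ang), z),
                vdw_radius=vdw,
            )
        )
    return atoms


def make_cylinder_structure(
    inner_radius: float = 2.0,
    length: float = 30.0,
    atoms_per_ring: int = 24,
    vdw: float = 1.70,
    ring_spacing: float = 0.5,
    seed: int = 0,
) -> Structure:
    """Cylindrical pseudo-pore whose true sphere-fit radius is ``inner_radius``.

    Wall atoms of vdW radius ``vdw`` sit on rings of radius
    ``inner_radius + vdw`` so the largest non-overlapping probe sphere on the
    axis has exactly the requested radius.  The default vdw equals the carbon
    table radius so the construction survives a PDB round trip.  Geometry is
    deterministic; the seed is accepted only to keep the generator signature
    uniform.
    """
    if inner_radius <= 0:
        raise ParameterError("inner_radius must be positive")
    if atoms_per_ring < 6:
        raise ParameterError("atoms_per_ring < 6 leaves a leaky wall")
    del seed
    atoms = []
    zs = np.arange(-length / 2, length / 2 + 0.5 * ring_spacing, ring_spacing)
    serial = 1
    for r, z in enumerate(zs):
        ring = _ring_atoms(inner_radius + vdw, z, atoms_per_ring, vdw,
                           serial, 900 + r)
        atoms.extend(ring)
        serial += atoms_per_ring
    return Structure(atoms=atoms, id=f"cylinder_R{inner_radius:g}")


def make_hourglass_structure(
    throat_radius: float = 1.5,
    cone_slope: float = 0.15,
    length: float = 30.0,
    atoms_per_ring: int = 24,
    vdw: float = 1.70,
    ring_spacing: float = 0.5,
) -> Structure:
    """Two cones meeting at z = 0 with the given throat radius."""
    if throat_radius <= 0:
        raise ParameterError("throat_radius must be positive")
    if atoms_per_ring < 6:
        raise ParameterError("atoms_per_ring < 6 leaves a leaky wall")
    atoms = []
    zs = np.arange(-length / 2, length / 2 + 0.5 * ring_spacing, ring_spacing)
    serial = 1
    for r, z in enumerate(zs):
        inner = throat_radius + cone_slope * abs(z)
        ring = _ring_atoms(inner + vdw, z, atoms_per_ring, vdw, serial, 900 + r)
        atoms.extend(ring)
        serial += atoms_per_ring
    return Structure(atoms=atoms, id=f"hourglass_R{throat_radius:g}")


#: (position, z along the pore axis, lateral distance from the axis)
_FILTER_GEOMETRY = {
    "H2P": (5.0, 3.4),
    "LCP": (8.0, 2.6),
    "H5P": (7.0, 3.6),
    "LEP": (10.0, 3.0),
    "HEP": (9.0, 3.2),
}

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def make_filter_structure(annotation, lcp_lep_distance: float = 3.0) -> Structure:
    """Toy channel decorated with the five filter residues of *annotation*.

    A cylindrical wall (3 A pore) carries, at the positions recorded in a
    sequence :class:`~aqpscope.filter_annotator.FilterAnnotation`, one
    side-chain marker atom per filter residue inside the selectivity-filter
    window, a backbone carbonyl O for LEP, an ND2 amide nitrogen for an LCP
    asparagine (placed ``lcp_lep_distance`` from the LEP O), and the two NPA
    asparagine CG atoms straddling z = 0.  Sequence and structure annotation
    therefore agree by construction.
    """
    base = make_cylinder_structure(inner_radius=4.0, length=36.0)
    atoms = list(base.atoms)
    serial = max(a.serial for a in atoms) + 1
    lep_o_pos = None
    for pos, (z, lat) in _FILTER_GEOMETRY.items():
        entry = annotation.positions[pos]
        if entry is None:
            continue
        resnum, aa = entry
        resname = _ONE_TO_THREE[aa]
        # side-chain marker atom pointing into the pore
        name = "CG" if aa not in ("G",) else "CA2"
        atoms.append(Atom(serial=serial, name=name, element="C",
                          residue_name=resname, residue_number=resnum,
                          chain="A", position=(lat, 0.0, z)))
        serial += 1
        if pos == "LEP":
            lep_o_pos = np.array([lat, 0.8, z])
            atoms.append(Atom(serial=serial, name="O", element="O",
                              residue_name=resname, residue_number=resnum,
                              chain="A", position=lep_o_pos))
            serial += 1
        if pos == "LCP" and aa == "N":
            # amide nitrogen at the requested distance from the LEP carbonyl O
            z_lep, lat_lep = _FILTER_GEOMETRY["LEP"]
            o = np.array([lat_lep, 0.8, z_lep])
            direction = np.array([0.0, 0.0, -1.0])
            atoms.append(Atom(serial=serial, name="ND2", element="N",
                              residue_name=resname, residue_number=resnum,
                              chain="A",
                              position=o + lcp_lep_distance * direction))
            serial += 1
    for resnum, z in ((annotation.npa1, -1.0), (annotation.npa2, 1.0)):
        atoms.append(Atom(serial=serial, name="CG", element="C",
                          residue_name="ASN", residue_number=resnum,
                          chain="A", position=(0.5, 0.5, z)))
        serial += 1
    return Structure(atoms=atoms, id="filter_toy")


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def attip21_like_sequence(seq_id: str = "AtTIP2;1-like") -> SequenceRecord:
    """Synthetic AtTIP2;1 stand-in sequence (the real sequence is not bundled).

    A 250-residue scaffold carrying the two NPA motifs at 83 and 197 and the
    extended-selectivity-filter residues at their native AtTIP2;1 numbers:
    His63 (H2P), His131 (LCP), Ile185 (H5P), Gly194 (LEP), Arg200 (HEP).
    The filler alphabet (G/A/V/L/I/M/T/S) contains no His/Phe/Asn/Trp/Tyr/Pro,
    so motif and loop-C searches resolve uniquely.
    """
    filler = "GAVLIMTS"
    seq = [filler[i % len(filler)] for i in range(250)]
    plant = {63: "H", 83: "N", 84: "P", 85: "A", 131: "H", 185: "I",
             194: "G", 197: "N", 198: "P", 199: "A", 200: "R"}
    for pos, aa in plant.items():
        seq[pos - 1] = aa
    return SequenceRecord(id=seq_id, residues="".join(seq))


def mutate(sequence: SequenceRecord, position: int, aa: str,
           seq_id: str | None = None) -> SequenceRecord:
    """Point mutation at a 1-based position."""
    if not 1 <= position <= len(sequence.residues):
        raise ParameterError(f"position {position} outside sequence")
    residues = (
        sequence.residues[: position - 1] + aa + sequence.residues[position:]
    )
    old = sequence.residues[position - 1]
    return SequenceRecord(
        id=seq_id or f"{sequence.id}_{old}{position}{aa}", residues=residues
    )


# ---------------------------------------------------------------------------
# Brownian pore trajectories
# ---------------------------------------------------------------------------

def _scan_traversals(z_path: np.ndarray, z_lo: float, z_hi: float) -> int:
    """Full traversals of [z_lo, z_hi] on one continuous 1-D path."""
    events = 0
    side = None
    entered_from = None
    for z in z_path:
        if z < z_lo:
            if entered_from == "high":
                events += 1
            side, entered_from = "low", None
        elif z > z_hi:
            if entered_from == "low":
                events += 1
            side, entered_from = "high", None
        else:
            if entered_from is None and side is not None:
                entered_from = side
    return events


def make_brownian_trajectory(
    n_molecules: int = 20,
    D: float = 1.0,
    pore_z: tuple[float, float] = (-10.0, 10.0),
    n_frames: int = 2000,
    dt: float = 0.01,
    seed: int = 0,
    mode: str = "reflecting",
    drift: float = 0.0,
    margin: float = 10.0,
    lateral_sigma: float = 1.0,
):
    """Brownian walkers in a pseudo-pore, with logged ground truth.

    D is in A^2 per time unit; axial motion is Euler-Maruyama with step
    variance 2 D dt plus ``drift * dt``.  Modes:

    * ``"periodic"``   - walkers wrap axially over the pore span (constant
      molecule count in the pore; the collective-diffusion test bed).
    * ``"reflecting"`` - walkers reflect at ``pore_z`` widened by ``margin``.
    * ``"drift"``      - reflecting boundaries far out; combined with a
      nonzero ``drift`` this drives every walker across once.

    Returns ``(trajectory, truth)`` where truth records the seed, D, the
    theoretical collective diffusion N*D/L^2 and, for non-periodic modes, the
    number of full traversals of ``pore_z`` per the generator's own scan of
    the continuous paths.
    """
    if D < 0:
        raise ParameterError("D must be non-negative")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    rng = np.random.default_rng(seed)
    z_lo, z_hi = pore_z
    span = z_hi - z_lo
    steps = drift * dt + np.sqrt(2 * D * dt) * rng.standard_normal(
        (n_frames - 1, n_molecules)
    )
    if mode == "periodic":
        z0 = rng.uniform(z_lo, z_hi, n_molecules)
        lo, hi = z_lo, z_hi
    elif mode == "reflecting":
        lo, hi = z_lo - margin, z_hi + margin
        z0 = rng.uniform(lo, hi, n_molecules)
    elif mode == "drift":
        lo, hi = z_lo - 2 * margin, z_hi + 2 * margin
        z0 = np.full(n_molecules, z_lo - 0.5 * margin)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    z_true = np.empty((n_frames, n_molecules))
    z_true[0] = z0
    for t in range(1, n_frames):
        z_true[t] = z_true[t - 1] + steps[t - 1]
        if mode != "periodic":  # reflect at the domain walls
            over = z_true[t] > hi
            under = z_true[t] < lo
            z_true[t][over] = 2 * hi - z_true[t][over]
            z_true[t][under] = 2 * lo - z_true[t][under]
            z_true[t] = np.clip(z_true[t], lo, hi)
    if mode == "periodic":
        z_out = np.mod(z_true - z_lo, span) + z_lo
        box = np.array([4 * span, 4 * span, span])
    else:
        z_out = z_true
        box = None
    xy = lateral_sigma * rng.standard_normal((n_frames, n_molecules, 2))
    coords = np.empty((n_frames, n_molecules, 3))
    coords[:, :, 0] = xy[:, :, 0]
    coords[:, :, 1] = xy[:, :, 1]
    coords[:, :, 2] = z_out
    topology = Topology(
        names=np.array(["OW"] * n_molecules),
        elements=np.array(["O"] * n_molecules),
        resnames=np.array(["SOL"] * n_molecules),
        resnums=np.arange(1, n_molecules + 1),
        mol_ids=np.arange(n_molecules),
    )
    traj = Trajectory(
        times=np.arange(n_frames) * dt,
        coords=coords,
        box=box,
        topology=topology,
    )
    truth = {
        "seed": seed,
        "mode": mode,
        "D": D,
        "n_molecules": n_molecules,
        "L": span,
        "D_n_theory": n_molecules * D / span**2,
        "events": None
        if mode == "periodic"
        else sum(_scan_traversals(z_true[:, j], z_lo, z_hi)
                 for j in range(n_molecules)),
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Umbrella sampling
# ---------------------------------------------------------------------------

def make_umbrella_samples(
    pmf_fn,
    centers,
    spring_k: float,
    n_per_window: int = 2000,
    temperature: float = 298.0,
    seed: int = 0,
) -> list[UmbrellaWindow]:
    """Exact samples from exp(-(G(z) + k/2 (z-c)^2) / RT) per window.

    Uses rejection sampling with the harmonic-bias Gaussian as the proposal
    and an acceptance bound taken from a dense local grid of G, so samples
    are independent and the draw is reproducible from the seed.
    """
    if spring_k <= 0:
        raise ParameterError("spring_k must be positive")
    kt = R_KJ * temperature
    sigma = np.sqrt(kt / spring_k)
    windows = []
    for i, c in enumerate(centers):
        rng = np.random.default_rng([seed, i])
        zg = np.linspace(c - 6 * sigma, c + 6 * sigma, 601)
        g_min = float(np.min(pmf_fn(zg)))
        samples = np.empty(n_per_window)
        kept = 0
        while kept < n_per_window:
            draw = rng.normal(c, sigma, size=2 * (n_per_window - kept) + 64)
            accept_p = np.exp(-(np.asarray(pmf_fn(draw)) - g_min) / kt)
            keep = draw[rng.uniform(size=len(draw)) < accept_p]
            take = min(len(keep), n_per_window - kept)
            samples[kept : kept + take] = keep[:take]
            kept += take
        windows.append(
            UmbrellaWindow(center=float(c), spring_constant=spring_k,
                           samples=samples)
        )
    return windows


# ---------------------------------------------------------------------------
# Stopped-flow traces
# ---------------------------------------------------------------------------

def make_trace(
    k: float,
    amplitude: float = 1.0,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    n_points: int = 200,
    direction: str = "rising",
    t_max: float | None = None,
    seed: int = 0,
    channel: str = "scattering",
) -> Trace:
    """Single-exponential trace with optional Gaussian noise; truth in meta."""
    if k <= 0:
        raise ParameterError("k must be positive")
    if n_points < 10:
        raise ParameterError("n_points must be >= 10")
    t = np.linspace(0.0, t_max if t_max is not None else 6.0 / k, n_points)
    if direction == "rising":
        s = amplitude * (1.0 - np.exp(-k * t)) + offset
    elif direction == "falling":
        s = amplitude * np.exp(-k * t) + offset
    else:
        raise ParameterError(f"unknown direction {direction!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.normal(0.0, noise_sd, n_points)
    return Trace(
        times=t,
        signal=s,
        channel=channel,
        meta={"true_k": k, "amplitude": amplitude, "offset": offset,
              "noise_sd": noise_sd, "direction": direction, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Packaged assay fixtures
# ---------------------------------------------------------------------------

def complementation_codes() -> pd.DataFrame:
    """Selectivity-filter codes with yeast complementation outcomes.

    Codes are ordered H2P, LCP, H5P, LEP, HEP.  ``complements`` is the
    observed growth outcome; the three constructs flagged
    ``in_vivo_exception`` are ammonia-specific in vitro yet fail to
    complement, attributed to insufficient water permeability (an H5P
    isoleucine without a small LEP residue).
    """
    rows = [
        # panel, construct, code, complements, in_vivo_exception
        ("TIP2;1 panel", "AtTIP2;1", "HHIGR", "+", False),
        ("TIP2;1 panel", "AtTIP2;1 H63F", "FHIGR", "-", False),
        ("TIP2;1 panel", "AtTIP2;1 H131F", "HFIGR", "+", False),
        ("TIP2;1 panel", "AtTIP2;1 G194C", "HHICR", "+", False),
        ("TIP2;1 panel", "AtTIP2;1 I185H G194C", "HHHCR", "-", False),
        ("TIP2;1 panel", "AtTIP2;1 quadruple", "FNHCR", "-", False),
        ("TIP2;1 panel", "HsAQP1", "FNHCR", "-", False),
        ("AQP1 panel", "HsAQP1 wt", "FNHCR", "-", False),
        ("AQP1 panel", "HsAQP1 N127H", "FHHCR", "-", False),
        ("AQP1 panel", "HsAQP1 F56H N127H", "HHHCR", "-", False),
        ("AQP1 panel", "HsAQP1 H180I", "FNICR", "-", True),
        ("AQP1 panel", "HsAQP1 N127H H180I", "FHICR", "-", True),
        ("AQP1 panel", "HsAQP1 F56H N127H H180I", "HHICR", "-", True),
        ("AQP1 panel", "HsAQP1 quadruple", "HHIGR", "+", False),
    ]
    return pd.DataFrame(
        rows,
        columns=["panel", "construct", "code", "complements",
                 "in_vivo_exception"],
    )


def table2_rates() -> pd.DataFrame:
    """Raw yeast stopped-flow rates per construct.

    Ammonia rates (alkalisation) are in units of 1e-2 s^-1, water rates
    (swelling) in s^-1; ``_se`` columns are standard errors of the fit.  The
    'Empty vector' row is the background strain.
    """
    rows = [
        ("Empty vector", None, 6.7, 0.1, 0.25, 0.01),
        ("AtTIP2;1", "HHIGR", 39.1, 0.1, 10.5, 0.1),
        ("HsAQP1 wt", "FNHCR", 6.3, 0.04, 33.5, 0.2),
        ("N127H", "FHHCR", 4.7, 0.03, 1.4, 0.001),
        ("F56H N127H", "HHHCR", 6.1, 0.04, 1.9, 0.01),
        ("H180I", "FNICR", 11.5, 0.1, 0.57, 0.0005),
        ("N127H H180I", "FHICR", 5.5, 0.03, 0.31, 0.0004),
        ("F56H N127H H180I", "HHICR", 9.9, 0.1, 0.33, 0.0005),
        ("F56H N127H H180I C189G", "HHIGR", 12.4, 0.1, 2.2, 0.02),
    ]
    return pd.DataFrame(
        rows,
        columns=["construct", "filter_code", "ammonia_rate", "ammonia_se",
                 "water_rate", "water_se"],
    )


def assay_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(complementation codes, raw rate table) for the yeast-assay pipeline."""
    return complementation_codes(), table2_rates()
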