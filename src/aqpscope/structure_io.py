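"""Structure and sequence I/O.

Reads PDB/mmCIF coordinate files into a lightweight atom container with
van der Waals radii assigned from a documented element table, writes PDB,
reads/writes FASTA, and performs rigid-body (Kabsch) superposition.

Parsing and serialisation of the standard formats are delegated to biotite
(structures) and Biopython (sequences); only the thin domain layer lives here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, GeometryError

#: Element -> van der Waals radius in Angstrom (Bondi-style values).
#: Unknown elements fall back to :data:`DEFAULT_VDW_RADIUS` with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.09,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS = 1.70

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def vdw_radius(element: str) -> float:
    """Van der Waals radius for *element*; warns and falls back on unknowns."""
    el = element.strip().upper()
    if el in VDW_RADII:
        return VDW_RADII[el]
    warnings.warn(
        f"unknown element {element!r}: using default vdW radius "
        f"{DEFAULT_VDW_RADIUS} A",
        stacklevel=2,
    )
    return DEFAULT_VDW_RADIUS


@dataclass
class Atom:
    """One atom with coordinates in Angstrom and an assigned vdW radius."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    vdw_radius: float | None = None
    insertion_code: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise GeometryError(
                f"atom {self.serial} ({self.name}): position must be a finite 3-vector"
            )
        if self.vdw_radius is None:
            self.vdw_radius = vdw_radius(self.element)
        if self.vdw_radius <= 0:
            raise GeometryError(f"atom {self.serial}: vdw_radius must be positive")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """An ordered atom collection from one model of a coordinate file."""

    atoms: list[Atom] = field(default_factory=list)
    id: str = ""
    model_number: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def select(
        self,
        chain: str | None = None,
        residue_numbers=None,
        residue_names=None,
        names=None,
        predicate=None,
    ) -> "Structure":
        """Subset of atoms matching all given filters (None = no filter)."""
        resnums = set(residue_numbers) if residue_numbers is not None else None
        resnames = set(residue_names) if residue_names is not None else None
        atom_names = set(names) if names is not None else None
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if resnums is not None and a.residue_number not in resnums:
                continue
            if resnames is not None and a.residue_name not in resnames:
                continue
            if atom_names is not None and a.name not in atom_names:
                continue
            if predicate is not None and not predicate(a):
                continue
            out.append(a)
        return Structure(atoms=out, id=self.id, model_number=self.model_number)

    def residues(self):
        """Iterate (residue_id, residue_name, [atoms]) in file order."""
        seen: dict[tuple, tuple[str, list[Atom]]] = {}
        for a in self.atoms:
            key = a.residue_id
            if key not in seen:
                seen[key] = (a.residue_name, [])
            seen[key][1].append(a)
        for key, (resname, atoms) in seen.items():
            yield key, resname, atoms

    def find_atom(self, residue_number: int, name: str, chain: str | None = None):
        for a in self.atoms:
            if a.residue_number == residue_number and a.name == name:
                if chain is None or a.chain == chain:
                    return a
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """New structure with positions ``R @ x + t``."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        atoms = []
        for a in self.atoms:
            atoms.append(
                Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element,
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain=a.chain,
                    position=rotation @ a.position + translation,
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                    vdw_radius=a.vdw_radius,
                    insertion_code=a.insertion_code,
                )
            )
        return Structure(atoms=atoms, id=self.id, model_number=self.model_number)


@dataclass
class SequenceRecord:
    """A protein sequence with one-letter residues (20 standard + X)."""

    id: str
    residues: str

    def __post_init__(self):
        self.residues = self.residues.upper()
        bad = set(self.residues) - STANDARD_AA - {"X"}
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: non-standard letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif", ".pdbx"}:
        return "mmcif"
    return "pdb"


def _from_atom_array(arr, structure_id: str, model_number: int) -> Structure:
    import biotite.structure as bst  # noqa: F401  (annotation access)

    n = arr.array_length()
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, n + 1)
    )
    occ = (
        arr.get_annotation("occupancy")
        if "occupancy" in arr.get_annotation_categories()
        else np.ones(n)
    )
    bfac = (
        arr.get_annotation("b_factor")
        if "b_factor" in arr.get_annotation_categories()
        else np.zeros(n)
    )
    ins = (
        arr.get_annotation("ins_code")
        if "ins_code" in arr.get_annotation_categories()
        else np.array([""] * n)
    )
    atoms = []
    for i in range(n):
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
                position=arr.coord[i],
                occupancy=float(occ[i]),
                b_factor=float(bfac[i]),
                insertion_code=str(ins[i]),
            )
        )
    return Structure(atoms=atoms, id=structure_id, model_number=model_number)


def read_structure(path, dialect: str | None = None, model: int = 1) -> Structure:
    """Read one model from a PDB or mmCIF file.

    Alternate locations are resolved to the highest-occupancy conformer.
    vdW radii are assigned from :data:`VDW_RADII`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    extra = ["atom_id", "occupancy", "b_factor"]
    try:
        if dialect == "pdb":
            from biotite.structure.io.pdb import PDBFile

            f = PDBFile.read(str(path))
            arr = f.get_structure(model=model, altloc="occupancy", extra_fields=extra)
        elif dialect == "mmcif":
            from biotite.structure.io.pdbx import CIFFile, get_structure

            f = CIFFile.read(str(path))
            arr = get_structure(f, model=model, altloc="occupancy", extra_fields=extra)
        else:
            raise FormatError(f"unknown dialect {dialect!r}")
    except FormatError:
        raise
    except Exception as exc:  # biotite raises InvalidFileError and friends
        raise FormatError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return _from_atom_array(arr, structure_id=path.stem, model_number=model)


def write_structure(structure: Structure, path) -> None:
    """Write a structure as PDB (coordinates at the format's 1e-3 A precision)."""
    import biotite.structure as bst
    from biotite.structure.io.pdb import PDBFile

    n = len(structure.atoms)
    arr = bst.AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.set_annotation("occupancy", np.array([a.occupancy for a in structure.atoms]))
    arr.set_annotation("b_factor", np.array([a.b_factor for a in structure.atoms]))
    arr.set_annotation(
        "ins_code", np.array([a.insertion_code for a in structure.atoms])
    )
    f = PDBFile()
    f.set_structure(arr)
    f.write(str(path))


def read_fasta(path) -> list[SequenceRecord]:
    """Read protein sequences from a FASTA file."""
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def _paired_coords(structure: Structure, pairing) -> np.ndarray:
    coords = []
    for pair in pairing:
        if len(pair) == 3:
            chain, resnum, name = pair
        else:
            resnum, name = pair
            chain = None
        atom = structure.find_atom(resnum, name, chain)
        if atom is None:
            raise GeometryError(f"pairing atom not found: {pair}")
        coords.append(atom.position)
    return np.array(coords)


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid-body transform (R, t) minimising RMSD of mobile onto reference."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = rc - r @ mc
    return r, t


def superpose(mobile: Structure, reference: Structure, pairing=None):
    """Least-squares rigid superposition of *mobile* onto *reference*.

    ``pairing`` is a list of ``(residue_number, atom_name)`` or
    ``(chain, residue_number, atom_name)`` tuples resolved in both structures;
    if omitted, atoms are paired by index (structures must be equal length).

    Returns ``(transformed_structure, rmsd)``.
    """
    if pairing is None:
        if len(mobile) != len(reference):
            raise GeometryError(
                "implicit pairing requires equal atom counts "
                f"({len(mobile)} vs {len(reference)})"
            )
        mob = mobile.coords
        ref = reference.coords
    else:
        mob = _paired_coords(mobile, pairing)
        ref = _paired_coords(reference, pairing)
    if len(mob) < 3:
        raise GeometryError("superposition needs at least 3 paired atoms")
    # collinearity: centered reference must span a plane
    centered = ref - ref.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("paired atoms are collinear")
    r, t = kabsch(mob, ref)
    moved = mobile.transformed(r, t)
    rmsd = float(np.sqrt(np.mean(np.sum((mob @ r.T + t - ref) ** 2, axis=1))))
    return moved, rmsd
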