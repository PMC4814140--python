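"""Extended selectivity-filter annotation and specificity classification.

Aquaporin substrate specificity is governed by an extended, five-position
selectivity filter: H2P (helix 2), LCP (loop C), H5P (helix 5), LEP (loop E,
contributing its backbone carbonyl) and HEP (the near-universal helix E
arginine).  This module locates the two NPA signature motifs in a sequence,
derives the five positions from NPA-anchored offsets (calibrated on AtTIP2;1:
His63, His131, Ile185, Gly194, Arg200 with NPA asparagines 83 and 197),
reconciles them with pore geometry when a structure is available, classifies
the resulting five-letter filter code, and assigns the LEP-carbonyl spatial
group (group II when an LCP asparagine hydrogen-bonds the carbonyl, group I
otherwise).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguityError, AnnotationError, GeometryError
from .pore_profiler import ChannelAxis
from .structure_io import THREE_TO_ONE, SequenceRecord, Structure

POSITIONS = ("H2P", "LCP", "H5P", "LEP", "HEP")

#: NPA-relative sequence offsets of the filter positions (1-based residue math).
DEFAULT_ANCHORS: dict[str, int] = {
    "H2P": -20,   # relative to npa1
    "H5P": -12,   # relative to npa2
    "LEP": -3,    # relative to npa2
    "HEP": +3,    # relative to npa2
    "LCP": +48,   # search center relative to npa1 (loop C motif search)
}

#: Residues eligible at LCP in the loop-C motif search.
LCP_CANDIDATES = set("HFNWY")

#: Aromatic set accepted at LCP for the aquaammoniaporin rule (H/F from
#: observed channels, W/Y as a conservative extension).
LCP_AROMATIC = set("HFWY")

#: Small/hydrophobic residues accepted at H5P for aquaammoniaporins.
H5P_OPEN = set("IVLAG")

#: Small residues at LEP that leave the carbonyl free to engage substrates.
LEP_SMALL = set("GA")

_BULKY = set("FWYRKEQMHLID")


@dataclass
class FilterAnnotation:
    """Residue numbers and one-letter identities at the five filter positions."""

    positions: dict[str, tuple[int, str] | None]
    npa1: int
    npa2: int
    source: str  # sequence | structure | alignment
    conflicts: list[str] = field(default_factory=list)

    def resolved(self) -> bool:
        return all(self.positions.get(p) is not None for p in POSITIONS)

    @property
    def code(self) -> "FilterCode":
        if not self.resolved():
            missing = [p for p in POSITIONS if self.positions.get(p) is None]
            raise AnnotationError(f"unresolved filter positions: {missing}")
        return FilterCode("".join(self.positions[p][1] for p in POSITIONS))


@dataclass(frozen=True)
class FilterCode:
    """Five-letter filter code ordered H2P, LCP, H5P, LEP, HEP."""

    code: str

    def __post_init__(self):
        if len(self.code) != 5 or not set(self.code) <= set(
            "ACDEFGHIKLMNPQRSTVWY"
        ):
            raise AnnotationError(f"invalid filter code {self.code!r}")

    def __str__(self) -> str:
        return self.code

    def __getitem__(self, position: str) -> str:
        return self.code[POSITIONS.index(position)]


@dataclass
class SpecificityCall:
    """Mechanism-level specificity inferred from a filter code alone."""

    call: str  # water_specific | aquaammoniaporin | glycerol_like | unknown
    rationale: str
    requires_dual_permeability: bool = False


@dataclass
class CarbonylGroupCall:
    """Spatial group of the LEP backbone carbonyl (I free, II Asn-pinned)."""

    group: str  # "I" | "II"
    hbond_distance: float | None


# ---------------------------------------------------------------------------
# Sequence annotation
# ---------------------------------------------------------------------------

def locate_npa(sequence: SequenceRecord) -> tuple[int, int]:
    """1-based indices of the asparagines of the two NPA motifs.

    The first motif must lie in the N-terminal half, the second in the
    C-terminal half.  If fewer than two strict NPA matches exist, the relaxed
    pattern N-P-[AST] is also searched, with a warning.
    """
    seq = sequence.residues
    if len(seq) < 100:
        raise AnnotationError(f"sequence {sequence.id!r} too short for an AQP fold")
    strict = [m.start() + 1 for m in re.finditer("(?=NPA)", seq)]
    candidates = strict
    if len(strict) < 2:
        relaxed = [m.start() + 1 for m in re.finditer("(?=NP[AST])", seq)]
        if len(relaxed) > len(strict):
            warnings.warn(
                f"sequence {sequence.id!r}: relaxed N-P-[AST] motif used",
                stacklevel=2,
            )
        candidates = sorted(set(relaxed))
    half = len(seq) / 2
    n_half = [i for i in candidates if i <= half]
    c_half = [i for i in candidates if i > half]
    if len(candidates) != 2 or len(n_half) != 1 or len(c_half) != 1:
        raise AmbiguityError(
            f"sequence {sequence.id!r}: expected one NPA per half, "
            f"found candidates at {candidates}"
        )
    return n_half[0], c_half[0]


def annotate_filter_sequence(
    sequence: SequenceRecord,
    anchors: dict[str, int] | None = None,
    lcp_position: int | None = None,
) -> FilterAnnotation:
    """Filter positions from NPA-anchored offsets.

    H2P/H5P/LEP/HEP come from fixed offsets; LCP is the H/F/N/W/Y residue in
    loop C (between H2P and H5P) nearest to ``npa1 + anchors['LCP']``, unless
    ``lcp_position`` pins it explicitly (e.g. from an alignment).
    """
    anchors = {**DEFAULT_ANCHORS, **(anchors or {})}
    npa1, npa2 = locate_npa(sequence)
    seq = sequence.residues

    def residue(pos: int, label: str) -> tuple[int, str]:
        if not 1 <= pos <= len(seq):
            raise AnnotationError(f"{label} offset falls outside sequence: {pos}")
        return pos, seq[pos - 1]

    positions: dict[str, tuple[int, str] | None] = {
        "H2P": residue(npa1 + anchors["H2P"], "H2P"),
        "H5P": residue(npa2 + anchors["H5P"], "H5P"),
        "LEP": residue(npa2 + anchors["LEP"], "LEP"),
        "HEP": residue(npa2 + anchors["HEP"], "HEP"),
    }
    if lcp_position is not None:
        positions["LCP"] = residue(lcp_position, "LCP")
    else:
        lo = positions["H2P"][0] + 1
        hi = positions["H5P"][0] - 1
        target = npa1 + anchors["LCP"]
        best = None
        for i in range(lo, hi + 1):
            if seq[i - 1] in LCP_CANDIDATES:
                d = abs(i - target)
                if best is None or d < best[0]:
                    best = (d, i)
        if best is None:
            positions["LCP"] = None
        else:
            positions["LCP"] = residue(best[1], "LCP")
    ann = FilterAnnotation(positions=positions, npa1=npa1, npa2=npa2,
                           source="sequence")
    if positions["LCP"] is None:
        raise AnnotationError(
            f"sequence {sequence.id!r}: no LCP candidate (H/F/N/W/Y) in loop C"
        )
    return ann


# ---------------------------------------------------------------------------
# Structure annotation
# ---------------------------------------------------------------------------

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def annotate_filter_structure(
    structure: Structure,
    axis: ChannelAxis,
    prior: FilterAnnotation | None = None,
    sf_window: tuple[float, float] = (2.0, 15.0),
    cutoff: float = 4.5,
) -> FilterAnnotation:
    """Filter positions from pore geometry, reconciled with a sequence prior.

    Candidate residues have at least one side-chain atom within ``cutoff`` of
    the axis inside the selectivity-filter z window (between the NPA origin
    and the non-cytosolic mouth).  When a sequence prior is available its
    assignment is checked against the candidates; geometry wins on conflict
    and the conflict is recorded.  The window is mirrored automatically if
    the axis points the other way.
    """
    lo, hi = sorted(sf_window)

    def candidates_in(window_lo, window_hi):
        found = {}
        for key, resname, atoms in structure.residues():
            side = [a for a in atoms if a.name not in _BACKBONE]
            if not side:
                continue
            coords = np.array([a.position for a in side])
            z = axis.axial(coords)
            lat = axis.lateral_distance(coords)
            near = (lat <= cutoff) & (z >= window_lo) & (z <= window_hi)
            if np.any(near):
                found[key[1]] = (resname, float(lat[near].min()))
        return found

    cands = candidates_in(lo, hi)
    if not cands:
        cands = candidates_in(-hi, -lo)  # axis oriented the other way
    if not cands:
        raise AnnotationError("no side chains near the axis in the SF window")

    one = {num: THREE_TO_ONE.get(resname, "X") for num, (resname, _) in cands.items()}
    conflicts: list[str] = []
    positions: dict[str, tuple[int, str] | None] = {p: None for p in POSITIONS}

    if prior is not None:
        positions.update({p: prior.positions.get(p) for p in POSITIONS})
        for p in ("H2P", "LCP", "H5P", "HEP"):
            entry = positions[p]
            if entry is None:
                continue
            num, aa = entry
            if num not in cands:
                # geometry preferred: take an unassigned candidate of same type
                assigned = {e[0] for e in positions.values() if e}
                repl = [n for n in cands if one[n] == aa and n not in assigned]
                if repl:
                    positions[p] = (repl[0], aa)
                    conflicts.append(
                        f"{p}: sequence residue {num} not at the pore; "
                        f"geometric candidate {repl[0]} used"
                    )
                else:
                    conflicts.append(
                        f"{p}: sequence residue {num} has no side chain within "
                        f"{cutoff} A of the axis"
                    )
        npa1, npa2 = prior.npa1, prior.npa2
    else:
        # LEP contributes its backbone carbonyl, not a side chain: nearest
        # backbone O to the axis in the window, if any
        best = None
        for key, resname, atoms in structure.residues():
            for a in atoms:
                if a.name != "O":
                    continue
                z = float(axis.axial(a.position[None, :])[0])
                lat = float(axis.lateral_distance(a.position[None, :])[0])
                if lo <= abs(z) <= hi and lat <= cutoff:
                    if best is None or lat < best[0]:
                        best = (lat, key[1], THREE_TO_ONE.get(resname, "X"))
        assigned: set[int] = set()
        if best is not None:
            positions["LEP"] = (best[1], best[2])
            assigned.add(best[1])
        # remaining positions from residue identities and axial proximity
        by_dist = sorted(cands, key=lambda n: cands[n][1])

        def take(pred):
            for n in by_dist:
                if n not in assigned and pred(one[n]):
                    assigned.add(n)
                    return (n, one[n])
            return None

        positions["HEP"] = take(lambda a: a == "R")
        positions["LCP"] = take(lambda a: a in LCP_CANDIDATES)
        positions["H2P"] = take(lambda a: a in set("HFWY"))
        positions["H5P"] = take(lambda a: a in set("IVLAGHFC"))
        npa1 = npa2 = 0
    return FilterAnnotation(positions=positions, npa1=npa1, npa2=npa2,
                            source="structure", conflicts=conflicts)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_specificity(code: FilterCode | str) -> SpecificityCall:
    """Rule-based specificity call from a five-letter filter code.

    Rules, applied in order:

    1. H5P His with LCP Asn  -> water_specific (canonical water channel).
    2. H2P His, aromatic LCP, small/hydrophobic H5P -> aquaammoniaporin.
    3. H2P Trp/Phe, small H5P, bulky LEP -> glycerol_like.
    4. otherwise unknown (rationale lists the failed clauses).

    A separate ``requires_dual_permeability`` flag marks codes whose H5P is
    hydrophobic while LEP is not small (G/A): such filters can conduct
    ammonia in vitro yet may lack the water permeability needed in vivo.
    """
    if isinstance(code, str):
        code = FilterCode(code)
    h2p, lcp, h5p, lep, _hep = code.code
    dual_flag = h5p in set("IVLMF") and lep not in LEP_SMALL
    if h5p == "H" and lcp == "N":
        return SpecificityCall(
            "water_specific",
            "H5P histidine with LCP asparagine: canonical water-specific filter",
            dual_flag,
        )
    if h2p == "H" and lcp in LCP_AROMATIC and h5p in H5P_OPEN:
        return SpecificityCall(
            "aquaammoniaporin",
            "H2P histidine, aromatic LCP and open H5P: ammonia-permeable filter",
            dual_flag,
        )
    if h2p in set("WF") and h5p in set("GAS") and lep in _BULKY:
        return SpecificityCall(
            "glycerol_like",
            "aromatic H2P with small H5P and bulky LEP: aquaglyceroporin-like",
            dual_flag,
        )
    failed = []
    if not (h5p == "H" and lcp == "N"):
        failed.append("water rule (H5P=H & LCP=N)")
    if not (h2p == "H" and lcp in LCP_AROMATIC and h5p in H5P_OPEN):
        failed.append("ammonia rule (H2P=H & LCP aromatic & H5P open)")
    if not (h2p in set("WF") and h5p in set("GAS") and lep in _BULKY):
        failed.append("glycerol rule")
    return SpecificityCall("unknown", "no rule matched: " + "; ".join(failed),
                           dual_flag)


def carbonyl_group(
    structure: Structure,
    annotation: FilterAnnotation,
    cutoff: float = 3.5,
) -> CarbonylGroupCall:
    """LEP-carbonyl spatial group from the LCP-Asn hydrogen-bond rule.

    Group II iff the LCP residue is an asparagine whose side-chain amide
    nitrogen (ND2) lies within ``cutoff`` of the LEP backbone carbonyl
    oxygen; every other filter is group I.
    """
    for p in ("LCP", "LEP"):
        if annotation.positions.get(p) is None:
            raise GeometryError(f"{p} unresolved in annotation")
    lcp_num, lcp_aa = annotation.positions["LCP"]
    lep_num, _ = annotation.positions["LEP"]
    lep_o = structure.find_atom(lep_num, "O")
    if lep_o is None:
        raise GeometryError(f"missing atom O of LEP residue {lep_num}")
    if lcp_aa != "N":
        return CarbonylGroupCall(group="I", hbond_distance=None)
    nd2 = structure.find_atom(lcp_num, "ND2")
    if nd2 is None:
        raise GeometryError(f"missing atom ND2 of LCP residue {lcp_num}")
    d = float(np.linalg.norm(nd2.position - lep_o.position))
    return CarbonylGroupCall(group="II" if d <= cutoff else "I", hbond_distance=d)


def complementation_prediction(call: SpecificityCall) -> str:
    """Map a specificity call onto an expected yeast complementation outcome."""
    return "+" if call.call == "aquaammoniaporin" else "-"
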