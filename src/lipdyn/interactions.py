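"""Non-covalent interaction censuses and site geometry.

Criteria implemented here are the geometric rules used throughout the
analysis: a Lys NZ within 4.0 A of a carboxylate oxygen (or Arg NE/NH
within 3.5 A) is a salt bridge; hydrophobic carbons (CH3 / CH2-like /
aromatic CH classes) within 5.0 A form a hydrophobic contact; a
donor-acceptor heavy-atom pair under 3.5 A (or a donor-H...acceptor
geometry scoring above an energy threshold) is a hydrogen bond.

The hydrogen-bond energy model is

    E = 25 * (2.6 - max(d_HA, 2.1)) / 0.5 * Scale_DHA * Scale_HAX   [kJ/mol]

with a maximum of 25 kJ/mol at ideal geometry and zero from d_HA = 2.6 A
outward.  The two angular scale factors are linear ramps (their exact
shape is a package convention, configurable):

    Scale_DHA = clamp((theta_DHA - 100) / 80, 0, 1)
    Scale_HAX = clamp((theta_HAX -  80) / 100, 0, 1)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import AROMATIC_CH_RING_ATOMS, implicit_hydrogen_count
from .core import Selection, Structure, Trajectory
from .errors import DegenerateGeometryError
from .geometry import (
    BACKBONE_ATOM_NAMES,
    MetricSeries,
    angle,
    apply_transform,
    distance,
    kabsch_superpose,
    rmsd,
)

logger = logging.getLogger(__name__)

HBOND_MAX_ENERGY = 25.0
HBOND_DISTANCE_CUTOFF = 3.5      # heavy donor-acceptor rule
HBOND_ENERGY_THRESHOLD = 6.25    # 25% of the maximum
SALT_BRIDGE_LYS_CUTOFF = 4.0
SALT_BRIDGE_ARG_CUTOFF = 3.5
HYDROPHOBIC_CONTACT_CUTOFF = 5.0


@dataclass
class HBond:
    donor: int
    acceptor: int
    hydrogen: int | None
    d_HA: float
    energy: float

    def __post_init__(self) -> None:
        if self.d_HA <= 0:
            raise ValueError("d_HA must be positive")
        if self.energy > HBOND_MAX_ENERGY + 1e-9:
            raise ValueError("hydrogen-bond energy exceeds the 25 kJ/mol maximum")


@dataclass
class ContactRecord:
    atom_i: int
    atom_j: int
    distance: float
    contact_class: str           # hydrophobic | salt_bridge | coordination
    residue_i: tuple[str, int, str] | None = None
    residue_j: tuple[str, int, str] | None = None


# --- connectivity inference -------------------------------------------------

_XH_CUTOFF = 1.25
_HEAVY_CUTOFF = 1.7
_S_CUTOFF = 1.95


def infer_bonds(structure: Structure) -> list[set[int]]:
    """Per-atom bonded-neighbour sets from distance rules.

    X-H pairs bond below 1.25 A; heavy-heavy pairs below 1.7 A (1.95 A
    when sulfur is involved).  Ions bond to nothing.
    """
    atoms = structure.atoms
    coords = structure.coords
    n = len(atoms)
    neighbours: list[set[int]] = [set() for _ in range(n)]
    if n < 2:
        return neighbours
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(_S_CUTOFF):
        ai, aj = atoms[i], atoms[j]
        if ai.category == "ion" or aj.category == "ion":
            continue
        ei, ej = ai.element.upper(), aj.element.upper()
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if "H" in (ei, ej):
            if ei == ej:   # H-H never bonds
                continue
            limit = _XH_CUTOFF
        elif "S" in (ei, ej):
            limit = _S_CUTOFF
        else:
            limit = _HEAVY_CUTOFF
        if d < limit:
            neighbours[i].add(j)
            neighbours[j].add(i)
    return neighbours


def _has_explicit_hydrogens(structure: Structure) -> bool:
    return any(a.element.upper() == "H" for a in structure.atoms)


def _hydrogen_count(structure: Structure, i: int, neighbours, explicit: bool) -> int | None:
    if explicit:
        return sum(1 for j in neighbours[i] if structure.atoms[j].element.upper() == "H")
    a = structure.atoms[i]
    return implicit_hydrogen_count(a.resname, a.name)


# --- hydrogen bonds ---------------------------------------------------------

def scale_dha(theta_deg: float) -> float:
    return float(np.clip((theta_deg - 100.0) / 80.0, 0.0, 1.0))


def scale_hax(theta_deg: float) -> float:
    return float(np.clip((theta_deg - 80.0) / 100.0, 0.0, 1.0))


def hbond_energy(d_HA: float, theta_DHA: float = 180.0,
                 theta_HAX: float = 180.0) -> float:
    """Hydrogen-bond energy in kJ/mol; 25 at ideal geometry, 0 beyond
    2.6 A."""
    if d_HA <= 0:
        raise ValueError("d_HA must be positive")
    if not (0.0 <= theta_DHA <= 180.0 and 0.0 <= theta_HAX <= 180.0):
        raise ValueError("angles must be within [0, 180] degrees")
    bracket = (2.6 - max(d_HA, 2.1)) / 0.5
    if bracket <= 0.0:
        return 0.0
    return HBOND_MAX_ENERGY * bracket * scale_dha(theta_DHA) * scale_hax(theta_HAX)


def _polar_roles(structure: Structure, neighbours, explicit: bool):
    """Classify N/O atoms as donor (has H) and/or acceptor."""
    donors: set[int] = set()
    acceptors: set[int] = set()
    for i, a in enumerate(structure.atoms):
        el = a.element.upper()
        if el not in ("N", "O"):
            continue
        n_h = _hydrogen_count(structure, i, neighbours, explicit)
        if n_h is None:
            n_h = 0
        if n_h > 0:
            donors.add(i)
        if el == "O" or n_h == 0:
            acceptors.add(i)
    return donors, acceptors


def find_hbonds(structure: Structure, selection_a: Selection,
                selection_b: Selection, mode: str = "distance",
                distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
                energy_threshold: float = HBOND_ENERGY_THRESHOLD):
    """Hydrogen bonds between two selections.

    ``distance`` mode counts donor-heavy/acceptor pairs under the 3.5 A
    rule (the fallback for hydrogen-less crystal structures); ``energy``
    mode requires explicit hydrogens and counts donor-H...acceptor
    geometries whose energy exceeds ``energy_threshold`` kJ/mol (6.25 =
    25% of the maximum, by default).  Returns ``(bonds, count)`` with
    bonds sorted by (donor, acceptor); one bond per donor-acceptor pair.
    """
    if mode not in ("distance", "energy"):
        raise ValueError(f"unknown hbond mode {mode!r}")
    neighbours = infer_bonds(structure)
    explicit = _has_explicit_hydrogens(structure)
    if mode == "energy" and not explicit:
        logger.warning("energy-mode hbond search on a hydrogen-less structure; "
                       "falling back to the <%.1f A heavy-atom rule", distance_cutoff)
        mode = "distance"
    donors, acceptors = _polar_roles(structure, neighbours, explicit)
    set_a, set_b = set(selection_a), set(selection_b)
    coords = structure.coords
    atoms = structure.atoms
    best: dict[tuple[int, int], HBond] = {}

    def same_residue(i: int, j: int) -> bool:
        return (atoms[i].chain, atoms[i].resid) == (atoms[j].chain, atoms[j].resid)

    def consider(d_idx: int, a_idx: int):
        if d_idx == a_idx or same_residue(d_idx, a_idx) or a_idx in neighbours[d_idx]:
            return
        if mode == "distance":
            d = distance(coords[d_idx], coords[a_idx])
            if d < distance_cutoff:
                energy = hbond_energy(max(d - 1.0, 0.1))
                key = (d_idx, a_idx)
                if key not in best or d < best[key].d_HA:
                    best[key] = HBond(d_idx, a_idx, None, d, energy)
            return
        # energy mode: iterate hydrogens on the donor
        for h_idx in neighbours[d_idx]:
            if atoms[h_idx].element.upper() != "H":
                continue
            d_ha = distance(coords[h_idx], coords[a_idx])
            if d_ha >= 2.6 or d_ha <= 0.0:
                continue
            theta_dha = angle(coords[d_idx], coords[h_idx], coords[a_idx])
            heavy_x = [j for j in neighbours[a_idx] if atoms[j].element.upper() != "H"]
            if heavy_x:
                theta_hax = max(
                    angle(coords[h_idx], coords[a_idx], coords[x]) for x in heavy_x
                )
            else:
                theta_hax = 180.0
            e = hbond_energy(d_ha, theta_dha, theta_hax)
            if e > energy_threshold:
                key = (d_idx, a_idx)
                if key not in best or e > best[key].energy:
                    best[key] = HBond(d_idx, a_idx, h_idx, d_ha, e)

    for d_idx in donors:
        for a_idx in acceptors:
            if (d_idx in set_a and a_idx in set_b) or (d_idx in set_b and a_idx in set_a):
                consider(d_idx, a_idx)
    bonds = [best[k] for k in sorted(best)]
    return bonds, len(bonds)


# --- salt bridges -----------------------------------------------------------

_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def count_salt_bridges(structure: Structure,
                       lys_cutoff: float = SALT_BRIDGE_LYS_CUTOFF,
                       arg_cutoff: float = SALT_BRIDGE_ARG_CUTOFF):
    """Salt bridges: Lys NZ under 4.0 A, or Arg NE/NH1/NH2 under 3.5 A,
    from an Asp OD / Glu OE carboxylate oxygen.

    Several qualifying atom pairs between one basic and one acidic
    residue count as a single bridge.  Returns ``(count, records)``.
    """
    atoms = structure.atoms
    coords = structure.coords
    basic = [
        (i, lys_cutoff if a.resname in ("LYS",) else arg_cutoff)
        for i, a in enumerate(atoms)
        if a.category == "protein" and a.name in _BASIC_ATOMS.get(a.resname, ())
    ]
    acidic = [
        i for i, a in enumerate(atoms)
        if a.category == "protein" and a.name in _ACIDIC_ATOMS.get(a.resname, ())
    ]
    best: dict[tuple, ContactRecord] = {}
    for i, cutoff in basic:
        for j in acidic:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < cutoff:
                ai, aj = atoms[i], atoms[j]
                key = ((ai.chain, ai.resid), (aj.chain, aj.resid))
                rec = ContactRecord(
                    i, j, d, "salt_bridge",
                    (ai.chain, ai.resid, ai.resname),
                    (aj.chain, aj.resid, aj.resname),
                )
                if key not in best or d < best[key].distance:
                    best[key] = rec
    records = [best[k] for k in sorted(best)]
    return len(records), records


# --- hydrophobic typing and contacts ----------------------------------------

def assign_hydrophobic_types(structure: Structure) -> list[int | None]:
    """Type carbons as 1 (>=3 H, -CH3), 2 (2 H, or 1 H + 3 C) or
    3 (aromatic C-H ring); everything else is None.

    Hydrogen counts come from explicit hydrogens when the structure has
    any, else from standard-residue templates; carbons that cannot be
    resolved are left untyped with a warning.
    """
    atoms = structure.atoms
    neighbours = infer_bonds(structure)
    explicit = _has_explicit_hydrogens(structure)
    types: list[int | None] = [None] * len(atoms)
    for i, a in enumerate(atoms):
        if a.element.upper() != "C":
            continue
        ring = AROMATIC_CH_RING_ATOMS.get(a.resname, ())
        if a.name in ring:
            types[i] = 3
            continue
        n_h = _hydrogen_count(structure, i, neighbours, explicit)
        if n_h is None:
            logger.warning("cannot resolve hydrogen count for %s %s%d %s; left untyped",
                           a.resname, a.chain, a.resid, a.name)
            continue
        n_c = sum(1 for j in neighbours[i] if atoms[j].element.upper() == "C")
        if n_h >= 3:
            types[i] = 1
        elif n_h == 2 or (n_h == 1 and n_c == 3):
            types[i] = 2
    return types


def count_hydrophobic_contacts(structure: Structure,
                               partner: str = "intra_protein",
                               cutoff: float = HYDROPHOBIC_CONTACT_CUTOFF):
    """Count unordered pairs of hydrophobic-typed atoms within ``cutoff``.

    ``intra_protein`` pairs protein atoms of different residues;
    ``protein_to_hetgroup`` pairs a typed protein atom with a typed atom
    of any non-protein molecule (all solvent treated as one group).
    Returns ``(count, records)``.
    """
    if partner not in ("intra_protein", "protein_to_hetgroup"):
        raise ValueError(f"unknown partner mode {partner!r}")
    atoms = structure.atoms
    coords = structure.coords
    types = assign_hydrophobic_types(structure)
    typed = [i for i, t in enumerate(types) if t is not None]
    if not typed:
        return 0, []
    tree = cKDTree(coords[typed])
    records: list[ContactRecord] = []
    for ii, jj in sorted(tree.query_pairs(cutoff)):
        i, j = typed[ii], typed[jj]
        ai, aj = atoms[i], atoms[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d >= cutoff:
            continue
        if partner == "intra_protein":
            if ai.category != "protein" or aj.category != "protein":
                continue
            if (ai.chain, ai.resid) == (aj.chain, aj.resid):
                continue
        else:
            cats = {ai.category, aj.category}
            if "protein" not in cats or cats == {"protein"}:
                continue
        records.append(ContactRecord(
            i, j, d, "hydrophobic",
            (ai.chain, ai.resid, ai.resname),
            (aj.chain, aj.resid, aj.resname),
        ))
    return len(records), records


# --- metal coordination and active site -------------------------------------

def metal_coordination(structure: Structure, ion,
                       shell: list[tuple[int, str, str]]) -> list[float]:
    """Distances from a metal ion to each shell atom (resid, resname,
    atom name), in shell order."""
    if isinstance(ion, int):
        ion_idx = ion
    else:
        ion_idx = structure.find_atom(*ion)
    ion_xyz = structure.atoms[ion_idx].coords
    distances = []
    for resid, resname, atom_name in shell:
        try:
            idx = structure.find_atom(resid, atom_name)
        except KeyError:
            raise KeyError(
                f"shell atom {resname}{resid} {atom_name} not found"
            ) from None
        a = structure.atoms[idx]
        if a.resname != resname:
            raise KeyError(
                f"shell atom resid {resid} is {a.resname}, expected {resname}"
            )
        distances.append(distance(ion_xyz, a.coords))
    return distances


@dataclass
class ActiveSiteGeometry:
    ca_angle: float                  # Ser-Asp-His Calpha angle, vertex Asp
    d_asp_od2_his_nd1: float
    d_ser_og_his_ne2: float
    hbond_asp_his: bool
    hbond_ser_his: bool


def active_site_geometry(structure: Structure, ser_resid: int = 113,
                         asp_resid: int = 317, his_resid: int = 358,
                         hbond_cutoff: float = HBOND_DISTANCE_CUTOFF) -> ActiveSiteGeometry:
    """Catalytic-triad geometry: the Ser/Asp/His Calpha angle (vertex at
    the Asp) and the two catalytic heavy-atom distances, each flagged as
    a hydrogen bond when under 3.5 A."""
    ca = {r: structure.atoms[structure.find_atom(r, "CA")].coords
          for r in (ser_resid, asp_resid, his_resid)}
    ca_ang = angle(ca[ser_resid], ca[asp_resid], ca[his_resid])
    od2 = structure.atoms[structure.find_atom(asp_resid, "OD2")].coords
    nd1 = structure.atoms[structure.find_atom(his_resid, "ND1")].coords
    og = structure.atoms[structure.find_atom(ser_resid, "OG")].coords
    ne2 = structure.atoms[structure.find_atom(his_resid, "NE2")].coords
    d1 = distance(od2, nd1)
    d2 = distance(og, ne2)
    return ActiveSiteGeometry(ca_ang, d1, d2, d1 < hbond_cutoff, d2 < hbond_cutoff)


# --- lid metrics ------------------------------------------------------------

def lid_metrics(traj: Trajectory, lid_range: tuple[int, int] = (175, 230),
                reference: Structure | None = None):
    """Lid-opening observables per frame.

    * distance between the Calpha atoms of the first and last lid
      residues (Asp175/Arg230 in the system this models);
    * backbone RMSD of the lid residues after superposing each frame on
      the reference over all non-lid backbone atoms (so the lid's own
      motion does not bias the fit).

    Returns ``(distance_series, lid_rmsd_series)``.
    """
    ref = reference if reference is not None else traj.topology
    lo, hi = lid_range
    top = traj.topology
    try:
        i_lo = top.find_atom(lo, "CA")
        i_hi = top.find_atom(hi, "CA")
    except KeyError as exc:
        raise KeyError(f"lid residues missing: {exc}") from exc
    lid_bb = [
        i for i, a in enumerate(top.atoms)
        if a.category == "protein" and lo <= a.resid <= hi
        and a.name in BACKBONE_ATOM_NAMES
    ]
    core_bb = [
        i for i, a in enumerate(top.atoms)
        if a.category == "protein" and not (lo <= a.resid <= hi)
        and a.name in BACKBONE_ATOM_NAMES
    ]
    if not lid_bb:
        raise KeyError(f"no lid backbone atoms in resid range {lo}:{hi}")
    ref_coords = ref.coords
    dist_vals = np.empty(traj.n_frames)
    rmsd_vals = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        frame = traj.frames[k]
        dist_vals[k] = distance(frame[i_lo], frame[i_hi])
        if len(core_bb) >= 3:
            rot, trans, _ = kabsch_superpose(frame[core_bb], ref_coords[core_bb])
            lid_fitted = apply_transform(frame[lid_bb], rot, trans)
        else:
            lid_fitted = frame[lid_bb]
        rmsd_vals[k] = rmsd(lid_fitted, ref_coords[lid_bb])
    times = traj.times.copy()
    return (
        MetricSeries("lid_distance", "A", times, dist_vals),
        MetricSeries("lid_rmsd", "A", times, rmsd_vals),
    )
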