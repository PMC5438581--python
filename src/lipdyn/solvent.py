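"""Solvent-box composition arithmetic and solvent-penetration census.

Molecule counts follow the equal-volume rule used when a 50% (v/v)
co-solvent box is built from a water reference: the number of co-solvent
molecules occupying the same volume as ``n_water_ref`` waters at each
species' experimental density,

    n_s = round_half_up( n_w * (rho_s / M_s) / (rho_w / M_w) ).

"Penetration" of a solvent molecule into the protein is operationalized
by molecular burial: a molecule contacts the protein when any heavy atom
is within 5 A of a protein atom, and has penetrated when its total SASA,
computed in the protein+molecule complex, falls below 5 A^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import Selection, Structure
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, sasa


@dataclass(frozen=True)
class SolventSpecies:
    name: str
    molar_mass: float          # g/mol
    density: float             # g/cm^3, experimental at 298 K
    atoms_per_molecule: int
    resname: str

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.density <= 0:
            raise ValueError("molar mass and density must be positive")


#: The species used in the water/alcohol mixture study this package
#: models, with their experimental densities at 298 K / 1 bar.
BUILTIN_SPECIES = {
    "water": SolventSpecies("water", 18.015, 0.997, 3, "HOH"),
    "methanol": SolventSpecies("methanol", 32.04, 0.7872, 6, "MOH"),
    "ethanol": SolventSpecies("ethanol", 46.07, 0.7873, 9, "EOH"),
    "propanol": SolventSpecies("propanol", 60.09, 0.8020, 12, "POH"),
    "butanol": SolventSpecies("butanol", 74.12, 0.8061, 15, "BOH"),
    "pentanol": SolventSpecies("pentanol", 88.15, 0.8110, 18, "PNL"),
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def solvent_molecule_count(n_water_ref: int, water: SolventSpecies,
                           solvent: SolventSpecies) -> int:
    """Co-solvent molecules occupying the volume of ``n_water_ref``
    waters at the solvent's experimental density (round-half-up)."""
    if n_water_ref <= 0:
        raise ValueError("n_water_ref must be positive")
    ratio = (solvent.density / solvent.molar_mass) / (water.density / water.molar_mass)
    return _round_half_up(n_water_ref * ratio)


def composition_report(n_water_ref: int,
                       species: dict[str, SolventSpecies] | None = None) -> list[dict]:
    """Per-species molecule counts for a 50% mixture box, as table rows."""
    species = species if species is not None else BUILTIN_SPECIES
    water = species["water"]
    rows = []
    for name, sp in species.items():
        rows.append({
            "name": name,
            "resname": sp.resname,
            "atoms_per_molecule": sp.atoms_per_molecule,
            "molecules": solvent_molecule_count(n_water_ref, water, sp),
            "density": sp.density,
        })
    return rows


def count_penetrating_solvent(frame: Structure, protein: Selection,
                              solvent_resname: str,
                              contact_cutoff: float = 5.0,
                              burial_sasa_cutoff: float = 5.0,
                              probe_radius: float = DEFAULT_PROBE_RADIUS,
                              n_points: int = DEFAULT_N_POINTS) -> tuple[int, int]:
    """(molecules contacting the protein, molecules buried inside it).

    A molecule is in contact when any heavy atom lies within
    ``contact_cutoff`` of a protein atom; the penetrating subset is the
    contacting molecules whose total molecular SASA in the
    protein+molecule complex is below ``burial_sasa_cutoff``.
    """
    resname = solvent_resname.strip().upper()
    molecules: list[list[int]] = []
    for (chain, resid, rn), members in frame.residues():
        if rn.upper() == resname:
            molecules.append(members)
    if not molecules:
        raise KeyError(f"no solvent molecules with resname {solvent_resname!r}")
    prot_idx = protein.as_array()
    if len(prot_idx) == 0:
        raise ValueError("empty protein selection")
    coords = frame.coords
    tree = cKDTree(coords[prot_idx])
    prot_atoms = [frame.atoms[i] for i in prot_idx]
    n_contact = 0
    n_penetrating = 0
    for members in molecules:
        heavy = [m for m in members if frame.atoms[m].element.upper() != "H"]
        d, _ = tree.query(coords[heavy if heavy else members])
        if np.min(d) >= contact_cutoff:
            continue
        n_contact += 1
        # complex = protein + this molecule only; other solvent removed
        complex_atoms = prot_atoms + [frame.atoms[m] for m in members]
        complex_structure = Structure(atoms=list(complex_atoms), title="complex")
        mol_sel = Selection.from_indices(
            range(len(prot_atoms), len(complex_atoms)), n_atoms=len(complex_atoms)
        )
        result = sasa(complex_structure, probe_radius=probe_radius,
                      n_points=n_points, subset=mol_sel)
        if result.total < burial_sasa_cutoff:
            n_penetrating += 1
    return n_contact, n_penetrating
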