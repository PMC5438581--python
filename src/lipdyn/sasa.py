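"""Solvent-accessible surface area by Shrake-Rupley sphere sampling.

Each atom is inflated by the probe radius (1.4 A water probe by default)
and sampled with a deterministic golden-spiral point lattice; a point is
accessible when it lies outside every neighbouring inflated sphere.  The
per-atom area is the accessible fraction of the inflated sphere's area.

The van der Waals radii in use (:data:`lipdyn.constants.VDW_RADII`,
Bondi-style) are part of every report's provenance because absolute SASA
values depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from .constants import VDW_RADII
from .core import Selection, Structure
from .interactions import assign_hydrophobic_types

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960


@lru_cache(maxsize=8)
def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts.setflags(write=False)
    return pts


def atom_radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {element!r}") from None


@dataclass
class SASAResult:
    total: float
    per_atom: np.ndarray           # area per atom, file order
    per_residue: list[dict]        # chain/resid/resname/area rows

    def residue_areas(self) -> dict[tuple[str, int], float]:
        return {(r["chain"], r["resid"]): r["area"] for r in self.per_residue}


def sasa(structure: Structure, probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_points: int = DEFAULT_N_POINTS,
         subset: Selection | None = None) -> SASAResult:
    """Shrake-Rupley SASA of a structure (or of a subset of its atoms,
    still occluded by all atoms).

    Returns total area, a per-atom array (zeros outside the subset) and
    per-residue sums.
    """
    if n_points < 32:
        raise ValueError("n_points must be >= 32")
    atoms = structure.atoms
    coords = structure.coords
    radii = np.array([atom_radius(a.element) for a in atoms]) + probe_radius
    n = len(atoms)
    per_atom = np.zeros(n)
    if n == 0:
        return SASAResult(0.0, per_atom, [])
    targets = subset.as_array() if subset is not None else np.arange(n)
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    for i in targets:
        ri = radii[i]
        sphere = coords[i] + ri * pts
        neighbours = [
            j for j in tree.query_ball_point(coords[i], ri + max_r)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + radii[j]
        ]
        if neighbours:
            nb_xyz = coords[neighbours]
            nb_r = radii[neighbours]
            d2 = ((sphere[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 >= (nb_r**2)[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = frac * 4.0 * np.pi * ri * ri
    rows = []
    for (chain, resid, resname), members in structure.residues():
        area = float(per_atom[members].sum())
        rows.append({"chain": chain, "resid": resid, "resname": resname, "area": area})
    return SASAResult(float(per_atom[targets].sum()), per_atom, rows)


def hydrophobic_sasa_per_residue(structure: Structure,
                                 probe_radius: float = DEFAULT_PROBE_RADIUS,
                                 n_points: int = DEFAULT_N_POINTS) -> list[dict]:
    """Per-residue solvent-accessible *hydrophobic* area.

    Counts the surface of carbons typed hydrophobic (CH3/CH2/aromatic-CH
    classes) plus their attached hydrogens, for residues in the
    hydrophobic set; other residues report 0.  The whole structure still
    occludes.
    """
    types = assign_hydrophobic_types(structure)
    hydro_idx = {i for i, t in enumerate(types) if t in (1, 2, 3)}
    # attach explicit hydrogens to their nearest typed carbon
    coords = structure.coords
    for i, a in enumerate(structure.atoms):
        if a.element.upper() != "H":
            continue
        d = np.linalg.norm(coords[list(hydro_idx)] - coords[i], axis=1) if hydro_idx else []
        if len(d) and d.min() < 1.25:
            hydro_idx.add(i)
    result = sasa(structure, probe_radius=probe_radius, n_points=n_points)
    rows = []
    for (chain, resid, resname), members in structure.residues():
        area = float(sum(result.per_atom[m] for m in members if m in hydro_idx))
        rows.append({"chain": chain, "resid": resid, "resname": resname, "area": area})
    return rows


def classify_exposure(per_residue_hydrophobic_sasa, threshold: float = 20.0):
    """Label residues buried/exposed by hydrophobic surface area.

    A residue whose solvent-accessible hydrophobic area is below the
    threshold (20 A^2 by default) is buried; at or above it, exposed.
    Accepts either the row dicts from
    :func:`hydrophobic_sasa_per_residue` or a bare sequence of values.
    """
    labels = []
    for item in per_residue_hydrophobic_sasa:
        value = item["area"] if isinstance(item, dict) else float(item)
        if value < 0:
            raise ValueError("hydrophobic area cannot be negative")
        labels.append("buried" if value < threshold else "exposed")
    return labels
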