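"""Core in-memory containers: atoms, structures, trajectories, selections.

A :class:`Structure` is an ordered list of atoms with author residue
numbering preserved exactly as read (residue 113 in the file is residue
113 here, always — catalytic-triad and lid labels depend on it).  A
:class:`Trajectory` pairs one topology with an ``F x A x 3`` coordinate
array and per-frame times in ps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .constants import (
    ATOMIC_MASSES,
    ION_RESNAMES,
    ORGANIC_SOLVENT_RESNAMES,
    STANDARD_AMINO_ACIDS,
    WATER_RESNAMES,
)

CATEGORIES = ("protein", "water", "organic_solvent", "ion", "other")


def categorize_resname(resname: str, extra_organic: frozenset[str] | set[str] = frozenset()) -> str:
    """Deterministic residue-name -> category lookup.

    Order matters: waters and ions are checked before the protein set so
    that a CA ion record is never mistaken for an alpha-carbon's residue.
    """
    resname = resname.strip().upper()
    if resname in WATER_RESNAMES:
        return "water"
    if resname in ION_RESNAMES:
        return "ion"
    if resname in ORGANIC_SOLVENT_RESNAMES or resname in extra_organic:
        return "organic_solvent"
    if resname in STANDARD_AMINO_ACIDS:
        return "protein"
    return "other"


@dataclass
class Atom:
    """One atom record with author numbering and a solvent/protein category."""

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coords: np.ndarray
    bfactor: float | None = None
    category: str = "other"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def mass(self) -> float:
        try:
            return ATOMIC_MASSES[self.element.upper()]
        except KeyError:
            raise KeyError(
                f"no mass tabulated for element {self.element!r} "
                f"(atom {self.serial} {self.name})"
            ) from None


@dataclass
class Structure:
    """Ordered atom list; residues are contiguous runs of (chain, resid)."""

    atoms: list[Atom]
    title: str = ""
    source: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """A x 3 coordinate array (cached view; invalidated by with_coords)."""
        if self._coords is None:
            self._coords = np.array([a.coords for a in self.atoms], dtype=float)
        return self._coords

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms=atoms, title=self.title, source=self.source)

    def residues(self) -> Iterator[tuple[tuple[str, int, str], list[int]]]:
        """Yield ((chain, resid, resname), atom index list) per residue,
        in file order."""
        key: tuple[str, int, str] | None = None
        members: list[int] = []
        for i, a in enumerate(self.atoms):
            k = (a.chain, a.resid, a.resname)
            if k != key:
                if members:
                    yield key, members  # type: ignore[misc]
                key, members = k, []
            members.append(i)
        if members:
            yield key, members  # type: ignore[misc]

    def validate(self) -> None:
        """Enforce the container invariants (unique atom ids, contiguous
        residues)."""
        seen_atoms: set[tuple[str, int, str]] = set()
        seen_res: set[tuple[str, int, str]] = set()
        prev_res: tuple[str, int, str] | None = None
        for a in self.atoms:
            ak = (a.chain, a.resid, a.name)
            if ak in seen_atoms:
                raise ValueError(f"duplicate atom (chain={a.chain!r}, resid={a.resid}, name={a.name!r})")
            seen_atoms.add(ak)
            rk = (a.chain, a.resid, a.resname)
            if rk != prev_res:
                if rk in seen_res:
                    raise ValueError(f"residue {rk} is not contiguous")
                seen_res.add(rk)
                prev_res = rk

    def find_atom(self, resid: int, name: str, chain: str | None = None) -> int:
        """Index of the unique atom matching (resid, name[, chain])."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.resid == resid and a.name == name and (chain is None or a.chain == chain)
        ]
        if not hits:
            raise KeyError(f"no atom resid={resid} name={name!r}" + (f" chain={chain!r}" if chain else ""))
        if len(hits) > 1:
            raise KeyError(f"ambiguous atom resid={resid} name={name!r}: {len(hits)} matches")
        return hits[0]


@dataclass(frozen=True)
class Selection:
    """Ordered, duplicate-free atom indices into a Structure."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=int)

    @classmethod
    def from_indices(cls, indices: Sequence[int], n_atoms: int | None = None) -> "Selection":
        idx = tuple(int(i) for i in indices)
        if n_atoms is not None:
            bad = [i for i in idx if i < 0 or i >= n_atoms]
            if bad:
                raise IndexError(f"selection indices out of range: {bad[:5]}")
        return cls(idx)


@dataclass
class Trajectory:
    """Topology + frames (F x A x 3, Angstrom) + times (ps, strictly
    increasing)."""

    topology: Structure
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, A, 3)")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{len(self.topology.atoms)}"
            )
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    def frame_structure(self, k: int) -> Structure:
        """Materialize frame ``k`` as a Structure."""
        return self.topology.with_coords(self.frames[k])

    def window(self, t_min: float | None = None, t_max: float | None = None,
               last_fraction: float | None = None) -> "Trajectory":
        """Sub-trajectory restricted by time bounds or a trailing fraction."""
        if last_fraction is not None:
            n = max(2, int(round(self.n_frames * last_fraction)))
            mask = np.zeros(self.n_frames, dtype=bool)
            mask[-n:] = True
        else:
            mask = np.ones(self.n_frames, dtype=bool)
            if t_min is not None:
                mask &= self.times >= t_min
            if t_max is not None:
                mask &= self.times <= t_max
        if not mask.any():
            raise ValueError("window selects no frames")
        return Trajectory(self.topology, self.frames[mask], self.times[mask])
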