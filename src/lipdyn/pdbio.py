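"""Reading and writing structures and trajectories.

Single-frame and multi-model PDB are parsed with a fixed-column reader
(ATOM/HETATM/MODEL/ENDMDL/TER/END records only).  DCD and XTC trajectories
are routed through MDAnalysis when that optional dependency is installed.

Elements missing from the PDB element column are inferred from the atom
name using PDB v3 alignment rules; each inference is logged at DEBUG level.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np

from .constants import DEFAULT_FRAME_SPACING_PS, ION_RESNAMES, TWO_LETTER_ELEMENTS
from .core import Atom, Structure, Trajectory, categorize_resname
from .errors import ParseError, TopologyError

logger = logging.getLogger(__name__)


def _infer_element(raw_name: str, resname: str) -> str:
    """Element from a 4-column PDB atom-name field (PDB v3 rules).

    A two-letter element (CA the calcium, ZN, CL...) starts in column 13;
    single-letter elements are preceded by a blank or a digit there.  Ion
    residues are resolved from the residue name first, which settles the
    'CA' alpha-carbon vs 'CA' calcium ambiguity.
    """
    resname = resname.strip().upper()
    if resname in ION_RESNAMES and raw_name.strip().upper() == resname:
        return resname
    name = raw_name.strip().upper()
    if len(raw_name) >= 2 and raw_name[0] not in (" ", *"0123456789"):
        two = raw_name[:2].strip().upper()
        if two in TWO_LETTER_ELEMENTS:
            return two
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element from atom name {raw_name!r}")
    return stripped[0]


def _parse_atom_line(line: str, lineno: int, extra_organic: set[str]) -> Atom:
    try:
        serial = int(line[6:11])
        raw_name = line[12:16]
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"malformed coordinate record at line {lineno}: {line.rstrip()!r}") from exc
    bfactor: float | None = None
    bf_field = line[60:66].strip()
    if bf_field:
        try:
            bfactor = float(bf_field)
        except ValueError:
            bfactor = None
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(raw_name, resname)
        logger.debug("line %d: inferred element %s for atom %r", lineno, element, raw_name)
    category = categorize_resname(resname, extra_organic)
    return Atom(
        serial=serial,
        name=raw_name.strip(),
        element=element,
        resname=resname,
        resid=resid,
        chain=chain,
        coords=np.array([x, y, z]),
        bfactor=bfactor,
        category=category,
    )


def read_structure(path: str | os.PathLike, format: str = "pdb",
                   extra_organic_resnames: Iterable[str] = ()) -> Structure:
    """Parse the first model of a PDB file into a Structure.

    HETATM ions are categorized as ``ion`` and waters as ``water`` via the
    residue-name table; ``extra_organic_resnames`` extends the organic
    co-solvent mapping for run-specific residue names.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    extra = {s.strip().upper() for s in extra_organic_resnames}
    atoms: list[Atom] = []
    title = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("TITLE"):
                title = (title + " " + line[10:].strip()).strip()
            elif rec in ("ATOM  ", "HETATM"):
                atoms.append(_parse_atom_line(line, lineno, extra))
            elif rec.startswith("ENDMDL"):
                break
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms=atoms, title=title, source=str(path))


def _iter_models(path: str | os.PathLike, extra: set[str]):
    """Yield lists of Atom, one per MODEL (or one for a model-less file)."""
    current: list[Atom] = []
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno, extra))
            elif rec.startswith("ENDMDL"):
                yield current
                current = []
    if current and (not saw_model):
        yield current
    elif current:
        # trailing model without ENDMDL
        yield current


def read_trajectory(topology: Structure, path: str | os.PathLike,
                    format: str = "pdb",
                    frame_spacing_ps: float = DEFAULT_FRAME_SPACING_PS) -> Trajectory:
    """Read coordinate frames against a fixed topology.

    Multi-model PDB is native; ``dcd``/``xtc`` require MDAnalysis.  Times
    default to ``frame_spacing_ps`` spacing when the file carries none.
    """
    n_top = len(topology.atoms)
    if format == "pdb":
        frames = []
        extra: set[str] = set()
        for k, model_atoms in enumerate(_iter_models(path, extra)):
            if len(model_atoms) != n_top:
                raise TopologyError(
                    f"{path}: model {k + 1} has {len(model_atoms)} atoms, "
                    f"topology has {n_top}"
                )
            frames.append(np.array([a.coords for a in model_atoms]))
        if not frames:
            raise ParseError(f"{path}: no coordinate models found")
        coords = np.stack(frames)
        times = np.arange(len(frames), dtype=float) * frame_spacing_ps
        return Trajectory(topology=topology, frames=coords, times=times)
    if format in ("dcd", "xtc"):
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                f"reading {format} trajectories requires the MDAnalysis "
                "optional dependency (pip install lipdyn[traj])"
            ) from exc
        u = mda.Universe.empty(n_top, trajectory=True)
        u.load_new(str(path))
        if u.atoms.n_atoms != n_top:
            raise TopologyError(
                f"{path}: trajectory has {u.atoms.n_atoms} atoms, topology has {n_top}"
            )
        frames = [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
        times = np.array([ts.time for ts in u.trajectory], dtype=float)
        if len(times) > 1 and np.allclose(np.diff(times), 0):
            times = np.arange(len(frames), dtype=float) * frame_spacing_ps
        return Trajectory(topology=topology, frames=np.stack(frames), times=times)
    raise ValueError(f"unsupported trajectory format {format!r}")


# --- writing ----------------------------------------------------------------

def _format_atom_line(a: Atom, serial: int, coords: np.ndarray) -> str:
    record = "ATOM  " if a.category == "protein" else "HETATM"
    name = a.name
    # PDB v3 name alignment: 1-letter elements start in column 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    name = name.ljust(4)[:4]
    bf = a.bfactor if a.bfactor is not None else 0.0
    return (
        f"{record}{serial:>5d} {name}{'':1s}{a.resname:>3s} {a.chain:1s}"
        f"{a.resid:>4d}    {coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{bf:6.2f}          {a.element:>2s}\n"
    )


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a single-frame PDB preserving atom order, names and resids."""
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title}\n")
        for i, a in enumerate(structure.atoms, start=1):
            fh.write(_format_atom_line(a, i, a.coords))
        fh.write("END\n")


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write a multi-model PDB readable by :func:`read_trajectory`."""
    with open(path, "w") as fh:
        if traj.topology.title:
            fh.write(f"TITLE     {traj.topology.title}\n")
        for k in range(traj.n_frames):
            fh.write(f"MODEL     {k + 1:>4d}\n")
            for i, a in enumerate(traj.topology.atoms, start=1):
                fh.write(_format_atom_line(a, i, traj.frames[k, i - 1]))
            fh.write("ENDMDL\n")
        fh.write("END\n")
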