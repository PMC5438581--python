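"""Per-residue secondary-structure assignment (DSSP-style) and content
fractions.

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

and exist when E < -0.5 kcal/mol.  Amide hydrogens absent from the file
are synthesized 1.0 A from N, anti to the carbonyl of the preceding
residue.  Assignments use five classes: H (alpha-helix, from i->i+4
bonds), G (3-10 helix, i->i+3), E (sheet, bridge/ladder patterns),
T (turn) and C (coil), with priority H > E > G > T > C.
"""

from __future__ import annotations

import numpy as np

from .core import Structure, Trajectory
from .errors import DegenerateGeometryError

KS_COUPLING = 0.084 * 332.0          # kcal/mol * Angstrom
KS_HBOND_CUTOFF = -0.5               # kcal/mol
SS_CLASSES = ("H", "G", "E", "T", "C")

_CHAIN_BREAK_CN = 2.5                # C(i)-N(i+1) distance implying a break
_CA_PREFILTER = 9.0                  # skip KS energy beyond this CA-CA range


def ks_backbone_hbond_energy(C, O, N, H) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol for one
    C=O...H-N geometry."""
    C, O, N, H = (np.asarray(v, dtype=float) for v in (C, O, N, H))
    pts = (C, O, N, H)
    for a in range(4):
        for b in range(a + 1, 4):
            if np.linalg.norm(pts[a] - pts[b]) < 1e-6:
                raise DegenerateGeometryError("coincident backbone atoms in KS energy")
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    return float(KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _backbone_frames(structure: Structure):
    """Extract per-residue backbone coordinates and segment (chain-break)
    ids for protein residues with complete N/CA/C/O backbones."""
    residues = []
    for (chain, resid, resname), members in structure.residues():
        if structure.atoms[members[0]].category != "protein":
            continue
        names = {structure.atoms[m].name: m for m in members}
        if not all(n in names for n in ("N", "CA", "C", "O")):
            continue
        residues.append({
            "chain": chain, "resid": resid, "resname": resname,
            "N": structure.atoms[names["N"]].coords,
            "CA": structure.atoms[names["CA"]].coords,
            "C": structure.atoms[names["C"]].coords,
            "O": structure.atoms[names["O"]].coords,
            "H": structure.atoms[names["H"]].coords if "H" in names else None,
        })
    # segment ids: split at chain changes or broken C-N links
    seg = 0
    for k, res in enumerate(residues):
        if k > 0:
            prev = residues[k - 1]
            linked = (
                prev["chain"] == res["chain"]
                and np.linalg.norm(res["N"] - prev["C"]) < _CHAIN_BREAK_CN
            )
            if not linked:
                seg += 1
        res["segment"] = seg
    return residues


def _amide_hydrogens(residues) -> None:
    """Synthesize missing amide H: 1.0 A from N, anti to the previous
    carbonyl O (no H for segment-start residues or prolines)."""
    for k, res in enumerate(residues):
        if res["H"] is not None:
            continue
        if res["resname"] == "PRO":
            continue
        if k == 0 or residues[k - 1]["segment"] != res["segment"]:
            continue
        prev = residues[k - 1]
        direction = prev["C"] - prev["O"]
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            continue
        res["H"] = res["N"] + direction / norm


def _ks_hbond_matrix(residues) -> np.ndarray:
    """hb[i, j] is True when the N-H of residue i donates to the C=O of
    residue j."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    ca = np.array([r["CA"] for r in residues]) if n else np.empty((0, 3))
    for i in range(n):
        h = residues[i]["H"]
        if h is None:
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            if np.linalg.norm(ca[i] - ca[j]) > _CA_PREFILTER:
                continue
            e = ks_backbone_hbond_energy(residues[j]["C"], residues[j]["O"],
                                         residues[i]["N"], h)
            if e < KS_HBOND_CUTOFF:
                hb[i, j] = True
    return hb


def assign_secondary_structure(frame: Structure) -> dict[tuple[str, int], str]:
    """DSSP-style five-class assignment for one conformation.

    Returns ``{(chain, resid): class}`` for every protein residue with a
    complete backbone.  Deterministic; segments split at chain breaks
    and patterns never cross a break.
    """
    residues = _backbone_frames(frame)
    n = len(residues)
    _amide_hydrogens(residues)
    hb = _ks_hbond_matrix(residues)
    seg = [r["segment"] for r in residues]

    def same_seg(*ks: int) -> bool:
        return len({seg[k] for k in ks}) == 1

    # n-turns: turn_n[i] means hbond from N-H(i+n) to C=O(i)
    turns = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in turns:
        for i in range(n - m):
            if same_seg(i, i + m) and hb[i + m, i]:
                turns[m][i] = True

    cls = np.array(["C"] * n, dtype="<U1")

    # beta bridges (parallel / antiparallel), marked E
    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hb[i, j - 1] and hb[j + 1, i]) or (hb[j, i - 1] and hb[i + 1, j])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or anti:
                bridge[i] = True
                bridge[j] = True

    # helices: two consecutive n-turns
    helix4 = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turns[4][i - 1] and turns[4][i]:
            helix4[i:i + 4] = True
    helix3 = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if turns[3][i - 1] and turns[3][i]:
            helix3[i:i + 3] = True

    # turn residues: interior of any isolated n-turn
    turn_mask = np.zeros(n, dtype=bool)
    for m in turns:
        for i in np.flatnonzero(turns[m]):
            turn_mask[i + 1:i + m] = True

    cls[turn_mask] = "T"
    cls[helix3] = "G"
    cls[bridge] = "E"
    cls[helix4] = "H"

    return {(r["chain"], r["resid"]): str(c) for r, c in zip(residues, cls)}


def ss_content(traj: Trajectory) -> list[dict[str, float]]:
    """Per-frame class fractions over {H, G, E, T, C}; each row sums to 1."""
    out = []
    for k in range(traj.n_frames):
        assignment = assign_secondary_structure(traj.frame_structure(k))
        total = len(assignment)
        counts = {c: 0 for c in SS_CLASSES}
        for c in assignment.values():
            counts[c] += 1
        if total == 0:
            raise ValueError("no assignable protein residues in frame")
        row = {c: counts[c] / total for c in SS_CLASSES}
        row["time"] = float(traj.times[k])
        out.append(row)
    return out
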