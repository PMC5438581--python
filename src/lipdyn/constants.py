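"""Lookup tables shared across the package.

Every table is fixed in code so that results are reproducible and
reportable: the vdW radii and masses used for a given run are part of
its provenance and are echoed into run manifests by the pipeline.
"""

from __future__ import annotations

# --- residue categorization -------------------------------------------------

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation/terminal variants
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O"}

# Organic co-solvent residue names are not standardized between MD packages;
# this is the package's default mapping and RunConfig may extend it.
ORGANIC_SOLVENT_RESNAMES = {"MOH", "EOH", "POH", "BOH", "PNL", "MEO", "ETO"}

ION_RESNAMES = {"CA", "ZN", "NA", "CL", "MG", "K", "MN", "FE", "CU"}

#: Bondi-style van der Waals radii in Angstrom, keyed by element symbol.
#: Used by the Shrake-Rupley surface calculation; an element missing here
#: raises rather than silently defaulting.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "MN": 1.97,
    "FE": 1.94,
    "CU": 1.40,
    "SE": 1.90,
}

#: Atomic masses (u) for the elements that occur in protein/solvent systems.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "MN": 54.938,
    "FE": 55.845,
    "CU": 63.546,
    "SE": 78.971,
}

#: Two-letter element symbols recognised when inferring elements from
#: PDB atom names (PDB v3 rules: right-justified name field, columns 13-16).
TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "MN", "FE", "CU", "SE", "CA"}

#: Default trajectory frame spacing in ps when the file carries no times
#: (snapshots saved every 30 ps in the study this package models).
DEFAULT_FRAME_SPACING_PS = 30.0

# --- hydrophobic residue side chains ----------------------------------------

#: Residues whose carbon surface contributes to the "hydrophobic area"
#: census.  Gly is included because its CA behaves as a -CH2- group.
HYDROPHOBIC_RESNAMES = {
    "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP", "GLY",
}

#: Aromatic ring carbons, per residue, whose bonded partners are carbons or
#: hydrogens only (His ring carbons touch ring nitrogens; Tyr CZ touches OH;
#: Trp CG/CE2 touch the indole nitrogen -- all excluded).
AROMATIC_CH_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2"},
    "TRP": {"CD2", "CE3", "CZ2", "CZ3", "CH2"},
}

#: Implicit hydrogen counts for standard-residue heavy atoms, used to type
#: carbons in crystal structures that carry no explicit hydrogens.
IMPLICIT_HYDROGENS = {
    # backbone (all residues; Gly CA overridden below)
    ("*", "N"): 1, ("*", "CA"): 1, ("*", "C"): 0, ("*", "O"): 0,
    ("GLY", "CA"): 2, ("PRO", "N"): 0,
    ("ALA", "CB"): 3,
    ("VAL", "CB"): 1, ("VAL", "CG1"): 3, ("VAL", "CG2"): 3,
    ("LEU", "CB"): 2, ("LEU", "CG"): 1, ("LEU", "CD1"): 3, ("LEU", "CD2"): 3,
    ("ILE", "CB"): 1, ("ILE", "CG1"): 2, ("ILE", "CG2"): 3, ("ILE", "CD1"): 3,
    ("PRO", "CB"): 2, ("PRO", "CG"): 2, ("PRO", "CD"): 2,
    ("PHE", "CB"): 2, ("PHE", "CG"): 0, ("PHE", "CD1"): 1, ("PHE", "CD2"): 1,
    ("PHE", "CE1"): 1, ("PHE", "CE2"): 1, ("PHE", "CZ"): 1,
    ("TYR", "CB"): 2, ("TYR", "CG"): 0, ("TYR", "CD1"): 1, ("TYR", "CD2"): 1,
    ("TYR", "CE1"): 1, ("TYR", "CE2"): 1, ("TYR", "CZ"): 0, ("TYR", "OH"): 1,
    ("TRP", "CB"): 2, ("TRP", "CG"): 0, ("TRP", "CD1"): 1, ("TRP", "CD2"): 0,
    ("TRP", "NE1"): 1, ("TRP", "CE2"): 0, ("TRP", "CE3"): 1, ("TRP", "CZ2"): 1,
    ("TRP", "CZ3"): 1, ("TRP", "CH2"): 1,
    ("MET", "CB"): 2, ("MET", "CG"): 2, ("MET", "SD"): 0, ("MET", "CE"): 3,
    ("SER", "CB"): 2, ("SER", "OG"): 1,
    ("THR", "CB"): 1, ("THR", "OG1"): 1, ("THR", "CG2"): 3,
    ("CYS", "CB"): 2, ("CYS", "SG"): 1,
    ("ASN", "CB"): 2, ("ASN", "CG"): 0, ("ASN", "OD1"): 0, ("ASN", "ND2"): 2,
    ("GLN", "CB"): 2, ("GLN", "CG"): 2, ("GLN", "CD"): 0, ("GLN", "OE1"): 0,
    ("GLN", "NE2"): 2,
    ("ASP", "CB"): 2, ("ASP", "CG"): 0, ("ASP", "OD1"): 0, ("ASP", "OD2"): 0,
    ("GLU", "CB"): 2, ("GLU", "CG"): 2, ("GLU", "CD"): 0, ("GLU", "OE1"): 0,
    ("GLU", "OE2"): 0,
    ("LYS", "CB"): 2, ("LYS", "CG"): 2, ("LYS", "CD"): 2, ("LYS", "CE"): 2,
    ("LYS", "NZ"): 3,
    ("ARG", "CB"): 2, ("ARG", "CG"): 2, ("ARG", "CD"): 2, ("ARG", "NE"): 1,
    ("ARG", "CZ"): 0, ("ARG", "NH1"): 2, ("ARG", "NH2"): 2,
    ("HIS", "CB"): 2, ("HIS", "CG"): 0, ("HIS", "ND1"): 1, ("HIS", "CD2"): 1,
    ("HIS", "CE1"): 1, ("HIS", "NE2"): 0,
}


def implicit_hydrogen_count(resname: str, atom_name: str) -> int | None:
    """Template hydrogen count for a heavy atom of a standard residue.

    Returns ``None`` when the (residue, atom) pair has no template entry.
    """
    resname = {"HID": "HIS", "HIE": "HIS", "HIP": "HIS", "CYX": "CYS"}.get(
        resname, resname
    )
    if (resname, atom_name) in IMPLICIT_HYDROGENS:
        return IMPLICIT_HYDROGENS[(resname, atom_name)]
    if ("*", atom_name) in IMPLICIT_HYDROGENS and resname in STANDARD_AMINO_ACIDS:
        return IMPLICIT_HYDROGENS[("*", atom_name)]
    return None
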