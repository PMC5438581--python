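"""Interaction criteria on constructed fixtures.

Walks each census rule at its boundary: hydrogen-bond energy, the
salt-bridge distance cutoffs, a hydrophobic contact pair, and metal-ion
coordination distances.
"""

from lipdyn import (
    Selection,
    count_hydrophobic_contacts,
    count_salt_bridges,
    find_hbonds,
    hbond_energy,
    make_interaction_fixture,
    metal_coordination,
)

print("H-bond energy model (kJ/mol):")
for d in (2.0, 2.1, 2.35, 2.6):
    print(f"  d_HA={d:4.2f} A, ideal angles -> {hbond_energy(d, 180, 180):5.2f}")

hb = make_interaction_fixture("hbond", d_ha=2.0)
sel = Selection.from_indices(range(len(hb.atoms)))
bonds, n = find_hbonds(hb, sel, sel, mode="energy")
print(f"collinear N-H...O=C fixture: {n} bond, energy {bonds[0].energy:.1f} kJ/mol")

print("\nSalt bridges (Lys NZ < 4.0 A, Arg NE/NH < 3.5 A from Asp/Glu O):")
for d in (3.9, 4.1):
    n, _ = count_salt_bridges(make_interaction_fixture("salt_bridge", d=d))
    print(f"  Lys NZ ... Glu OE1 at {d} A -> {n} bridge(s)")

print("\nHydrophobic contacts (typed carbons < 5.0 A, cross-residue):")
for d in (4.9, 5.1):
    s = make_interaction_fixture("hydrophobic_pair", d=d)
    n, recs = count_hydrophobic_contacts(s, "intra_protein")
    cb = sum(1 for r in recs if s.atoms[r.atom_i].name == s.atoms[r.atom_j].name == "CB")
    print(f"  CH3 carbons at {d} A -> {cb} carbon-carbon contact(s)")

print("\nCa2+ coordination shell (synthetic fixture at crystal distances):")
site = make_interaction_fixture("metal_site", element="CA", shell=[
    (286, "GLY", "O", 2.2), (360, "GLU", "OE2", 2.32),
    (365, "ASP", "OD2", 2.44), (366, "PRO", "O", 2.37),
])
ion = next(i for i, a in enumerate(site.atoms) if a.category == "ion")
shell = [(286, "GLY", "O"), (360, "GLU", "OE2"), (365, "ASP", "OD2"),
         (366, "PRO", "O")]
for (resid, resname, name), dist in zip(shell, metal_coordination(site, ion, shell)):
    print(f"  Ca2+ ... {resname}{resid} {name}: {dist:.2f} A")
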