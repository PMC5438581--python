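"""Dynamic cross-correlation map with prescribed correlation blocks.

Builds a trajectory in which the first four Calpha atoms share pairwise
displacement correlation rho = 0.8 while the rest move independently,
then recovers the block from the correlation matrix.
"""

from lipdyn import Selection, SyntheticSpec, block_summary, dccm
from lipdyn.correlations import ca_selection
from lipdyn.synthetic import make_gaussian_trajectory, make_toy_protein

ref = make_toy_protein(12, "alpha_helix")
ca_idx = list(ca_selection(ref))
spec = SyntheticSpec(
    n_atoms=len(ref.atoms), variances=0.25,
    correlation_blocks=[(ca_idx[:4], 0.8)],
    n_frames=2000, seed=2,
)
traj = make_gaussian_trajectory(spec, ref)

matrix = dccm(traj, last_fraction=1.0,
              fit_selection=Selection.from_indices([0]))
blocks = block_summary(matrix, {"lid": (1, 4), "core": (5, 12)})

print(f"matrix size : {matrix.matrix.shape[0]} x {matrix.matrix.shape[1]} residues")
print(f"diagonal    : min {matrix.matrix.diagonal().min():.3f} (always +1)")
print(f"lid-lid     : {blocks[('lid', 'lid')]:+.3f}  (prescribed 0.8 off-diagonal)")
print(f"lid-core    : {blocks[('lid', 'core')]:+.3f}  (independent -> near 0)")
print()
print("A block mean near the prescription shows correlated collective motion")
print("of that residue group, the signature used to link lid motion to the")
print("active-site region in correlation maps.")
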