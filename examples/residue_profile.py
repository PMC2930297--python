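"""Find the residues that shape a cavity: per-residue overlap volumes.

Places three single-atom 'residues' — one buried inside a target cavity,
one at its rim, one far away — and measures V(S_a ∩ cavity) for each
residue surface S_a. Residues with large overlap are the ones that would
force a differently shaped cavity in their own structure.
"""

import numpy as np

from cavcsg import residue_overlap_profile
from cavcsg.fixtures import icosphere
from cavcsg.structure import Structure

coords = np.array([[0.0, 0.0, 0.0], [3.9, 0.0, 0.0], [20.0, 0.0, 0.0]])
names = ["buried", "rim", "distant"]
st = Structure(
    coords=coords,
    radii=np.full(3, 1.7),
    element=np.array(["C"] * 3, dtype=object),
    chain=np.array(["A"] * 3, dtype=object),
    resseq=np.arange(1, 4),
    icode=np.array([""] * 3, dtype=object),
    resname=np.array(["TOY"] * 3, dtype=object),
    atom_name=np.array(["C1", "C2", "C3"], dtype=object),
)

cavity = icosphere(radius=4.0, subdivisions=3)  # the aligned target cavity
profile = residue_overlap_profile(st, [cavity], spacing=0.25)

print("residue  overlap with target cavity (Å³)")
for name, (_, row) in zip(names, profile.table.iterrows()):
    print(f"{name:8s} {row['mean']:8.2f}")
print()
print("The buried residue overlaps with its full van der Waals volume (~21 Å³),")
print("the rim residue only partially, the distant residue not at all — the")
print("profile pinpoints which amino acids intrude into an aligned cavity.")
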