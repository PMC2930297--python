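"""Volumetrically conserved and varying regions across cavity sets.

Mimics the subfamily comparison: the region conserved in every member of
set 1 but occupied by no member of set 2 is (∩ set1) − (∪ set2) — e.g. a
specificity protrusion present in one protease subfamily and absent from
another.
"""

from cavcsg import conserved_region, enclosed_volume, set_difference_region, union_region
from cavcsg.fixtures import icosphere

# set 1: three nearly coincident cavities with a protrusion along +x
set1 = [icosphere(center=(0.2 * i, 0, 0), radius=5.0, subdivisions=3) for i in range(3)]
# set 2: cavities covering only the −x half of that region
set2 = [icosphere(center=(-4.0, 0.4 * i, 0), radius=5.0, subdivisions=3) for i in range(2)]

v_cons = enclosed_volume(conserved_region(set1, 0.5))
v_union = enclosed_volume(union_region(set2, 0.5))
v_diff = enclosed_volume(set_difference_region(set1, set2, 0.5))

print(f"conserved in all of set 1 (∩):        {v_cons:.1f} Å³")
print(f"occupied by any of set 2 (∪):         {v_union:.1f} Å³")
print(f"conserved-in-1, absent-from-2 (∩−∪):  {v_diff:.1f} Å³")
print()
print("The difference region is the part of the shared set-1 volume that no")
print("set-2 cavity reaches — the volumetric signature separating the sets.")
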