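"""Ideal chromosome group-bin vectors from the reference genome.

Chromosome areas in a metaphase image are roughly proportional to DNA
content, so the reference genome predicts how many chromosomes of a
normal cell fall in each ISCN-derived size group (AB > 2.9% of the
diploid genome, C between 2% and 2.9%, DG below 2%).  An image's distance
from this ideal vector measures its segmentation quality.
"""

import numpy as np

from dicecurator.image_selection import group_bin_distance
from dicecurator.karyotype import ideal_group_counts, relative_lengths

for sex in ("female", "male"):
    ab, c, dg = ideal_group_counts(sex)
    print(f"{sex:6s}: AB={ab}  C={c}  DG={dg}")

# a well-segmented cell scores distance 0; losing two small chromosomes
# to overlap (counted as one large object each) moves counts and distance
areas = relative_lengths("female")
counts, dist = group_bin_distance(areas, sex="female")
print(f"clean female cell: counts={counts}, distance={dist:.2f}")

merged = np.concatenate([areas[:-4], [areas[-4:-2].sum(), areas[-2:].sum()]])
counts, dist = group_bin_distance(merged, sex="female")
print(f"two overlap clusters: counts={counts}, distance={dist:.2f}")
print("larger distances flag poorer metaphase images")
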