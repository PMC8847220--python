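"""Compute natural vectors and divided natural vectors for short sequences.

The natural vector condenses a DNA sequence into 12 numbers — per-base
counts, mean positions, and normalized second central moments — so that
Euclidean distance between vectors measures sequence dissimilarity
without alignment. The divided variant concatenates the NVs of k
contiguous segments, adding local composition signal.
"""

from dnvphylo import divided_natural_vector, euclidean_distance, natural_vector

for seq in ("ACGT", "AATT", "TGCA"):
    print(f"NV({seq}) =", natural_vector(seq).flat().tolist())

# same base composition, different order: the vectors differ
d = euclidean_distance(natural_vector("ACGT").flat(), natural_vector("TGCA").flat())
print(f"distance NV(ACGT) vs NV(TGCA) = {d:.4f}  (position-sensitive, not 0)")

dnv = divided_natural_vector("AACCGGTT", k=2)
print("DNV(AACCGGTT, k=2) =", dnv.flat().tolist())
print("first 12 entries describe segment AACC, last 12 describe GGTT")
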