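"""Pedigree relatedness on a small three-generation family.

Builds a pedigree by hand and prints Wright's r for a few canonical
relationships: the values are the expected shares of identical-by-
descent genes that drive kin-selection predictions.
"""

from gssrm import Pedigree, PedigreeRecord, relatedness_matrix

pedigree = Pedigree(
    [
        PedigreeRecord("grandma"),
        PedigreeRecord("grandpa"),
        PedigreeRecord("mother", "grandma", "grandpa"),
        PedigreeRecord("aunt", "grandma", "grandpa"),
        PedigreeRecord("father"),
        PedigreeRecord("daughter", "mother", "father"),
        PedigreeRecord("son", "mother", "father"),
    ]
)

pairs = [
    ("mother", "daughter"),
    ("daughter", "son"),
    ("daughter", "aunt"),
    ("daughter", "grandma"),
    ("father", "grandma"),
]
for a, b in pairs:
    print(f"r({a}, {b}) = {pedigree.relatedness(a, b):.4f}")

matrix = relatedness_matrix(pedigree, ["mother", "daughter", "son", "aunt"])
print("\npairwise relatedness matrix:")
print(matrix.round(3))

# Expected output: parent-offspring and full siblings share r = 0.5,
# aunt-niece and grandparent-grandchild r = 0.25, and the married-in
# father is unrelated to his mother-in-law (r = 0).
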