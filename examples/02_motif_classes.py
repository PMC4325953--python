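"""Standardized motif classes under rotation and reverse complement.

AG, GA, CT and TC are the same dinucleotide repeat read in different frames
and strands; standardization names each such orbit by its lexicographically
smallest member. The class counts per motif length (2, 4, 10, 33, 102, 350)
are what make per-class frequency tables comparable between genomes.
"""

from ssrkit import canonical_motif, enumerate_motif_classes

for m in ("AG", "GA", "CT", "TC"):
    print(f"{m} -> {canonical_motif(m).canonical}")
print("ATAT ->", canonical_motif("ATAT").canonical, "(reduced to its primitive root)")

print("\nmotif length : classes")
for period in range(1, 7):
    classes = enumerate_motif_classes(period)
    print(f"{period:>12} : {len(classes)}")

di = enumerate_motif_classes(2)
print("\nDinucleotide classes:", ", ".join(c.canonical for c in di))
print("Orbit of AG:", ", ".join(sorted(canonical_motif('AG').orbit)))
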