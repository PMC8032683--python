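"""Negative controls: structures the detector must NOT call beta-sheet.

The distinct-peptide constraint means a single helix (however locally
collinear), a two-strand sheet, and a random coil produce no aligned
triples or very few.
"""

from cgbeta import (SheetSpec, find_aligned_triples, make_helix,
                    make_parallel_sheet, make_random_coil)

helix = make_helix(30)
two_strand = make_parallel_sheet(SheetSpec(n_strands=2, strand_len=32))
coil = make_random_coil(n_peptides=20, gl=10, box=20.0, seed=0)

print(f"helix (1 peptide, 30 residues): {len(find_aligned_triples(helix))} triples")
print(f"sheet with only 2 strands:      {len(find_aligned_triples(two_strand))} triples")
print(f"dilute random coil (20x10):     {len(find_aligned_triples(coil))} triples")

# A triple needs three grains on three different peptides within 0.7 nm and
# nearly collinear: one peptide can never qualify, two strands lack a third,
# and a dilute coil rarely brings three peptides into that geometry.
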