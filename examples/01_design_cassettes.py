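"""Design barcoded WT/scrambled motif cassettes.

For each motif in a small PFM library this designs the wild-type cassette
(consensus motif flanked by 6 bp cytosine-free-strand barcodes) and a
scrambled control that keeps every CG dinucleotide in place while dropping
the normalized binding score by at least 0.3 — so both loci expose the same
CpGs but only one recruits the factor.
"""

from hitransmet import pipeline as pl

library = pl.toy_pfm_library()
cassettes = pl.design_cassettes(library, seed=7)

print(f"{'motif':<8} {'variant':<4} {'barcode5':<8} {'sequence':<18} score")
for c in cassettes:
    print(
        f"{c.motif_name:<8} {c.variant:<4} {c.barcode5:<8} "
        f"{c.motif:<18} {c.normalized_score:.3f}"
    )
print(
    "\nEach WT scores > 0.7 against its own matrix; the scramble scores at\n"
    "least 0.3 lower, and neither cassette matches any other library motif\n"
    "at the 90% PWM threshold."
)
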