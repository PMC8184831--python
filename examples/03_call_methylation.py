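"""Recover per-CpG methylation from a simulated library.

Runs the full read-processing chain — mean-Phred quality filter,
barcode+adaptor demultiplexing at 0 mismatches, UMI extraction,
bisulfite-aware motif classification, three-letter alignment, the 2%
non-CG conversion filter, UMI deduplication and aggregation at >= 10
molecules per CpG — and compares the estimate with the generator's mean.
"""

from hitransmet import pipeline as pl

res = pl.estimate_condition_mean("ESC_plusSssI", seed=7, n_molecules=500)

print(res["demux_summary"].to_string(index=False))
print(f"drops: {res['drops']}")
print(f"deduplicated molecules: {len(res['molecule_calls'])}")
table = res["cg_table"]
print("\nfirst CpGs (offset is bp from the motif 5' end):")
print(table.head(8)[["offset", "n_meth", "n_total", "pct", "masked"]].to_string(index=False))
print(
    f"\ncoverage-weighted mean CpG methylation: {res['cg_mean']:.1f}% "
    "(generator condition mean: 79.1%)"
)
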