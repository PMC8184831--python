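"""Simulate one bisulfite amplicon sequencing library with known truth.

Builds a 600 bp neutral backbone (3.6% CpG) carrying a scrambled-motif
cassette, draws 200 molecules at the unmethylated-insertion condition mean
(52.4% CpG methylation), applies bisulfite chemistry, PCR duplication under
8-nt UMIs and sequencing error, and writes paired FASTQ plus the truth
table that downstream stages can be scored against.
"""

import numpy as np

import hitransmet as ht
from hitransmet import pipeline as pl

config = pl.RunConfig(seed=7, n_molecules=200)
library = pl.toy_pfm_library()
cassettes = pl.design_cassettes(library, 7, motif_names=[library[0].name])
refs = pl.build_references(cassettes, config)
sc = next(c for c in cassettes if c.variant == "Sc")
ref = refs[sc.label]

profile = ht.get_preset("ESC_minusSssI")
rng = pl.rng_for(7, "simulate", profile.name, ref.name)
reads, truth, molecules = ht.simulate_library(ref, profile, "Sc", 200, rng)

ht.write_fastq_pair(reads, "simulated_R1.fastq", "simulated_R2.fastq")
truth.to_csv("simulated_truth.tsv", sep="\t", index=False)

true_table = ht.truth_cpg_means(ref, molecules)
true_mean = 100 * true_table["n_meth"].sum() / true_table["n_total"].sum()
print(f"amplicon: {len(ref.sequence)} bp, {len(ref.cpg_positions)} CpGs")
print(f"molecules: {len(molecules)}, read pairs (with PCR duplicates): {len(reads)}")
print(f"true mean CpG methylation in the reporting window: {true_mean:.1f}%")
print("wrote simulated_R1/R2.fastq and simulated_truth.tsv")
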