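# Methods

This note documents the models, parameter choices and numerical decisions
behind `hitransmet`, and what the simulation-based tests do and do not
demonstrate about real data.

## Motif design

A position frequency matrix (PFM) is stored as per-column probabilities
(columns sum to 1; counts are normalised on input, optionally with a
pseudocount). Two scores are used for different purposes:

- **Normalized score** — the mean over motif positions of the probability
  the PFM assigns to the observed base, a value in [0, 1] used to compare
  WT motifs (>0.7 expected) with scrambled controls (accepted only when at
  least 0.3 lower). It uses raw probabilities: a zero column simply
  contributes zero, and no pseudocount is wanted because the score is an
  average, not a product.
- **Log-odds scan score** — Σᵢ log₂((pᵢ(b)+ε)/0.25) with ε = 0.01 applied
  inside the log only, to avoid −∞ on one-hot columns. The fractional
  threshold follows the `countPWM` convention
  S_min + f·(S_max − S_min) (f = 0.9 reproduces `min.score = "90%"`); the
  absolute mode compares the raw log-odds against a fixed cutoff (6 in the
  HOMER-style screen). Scans cover both strands by default, since binding
  is strand-agnostic; a forward-only flag exists for deterministic tests.

Scrambling permutes the bases outside CG-locked positions and redraws
(up to 10,000 times) whenever the permutation would create a CG absent
from the WT, so CpG number *and* position are conserved exactly — the two
loci present identical substrates to the methylation machinery. The first
accepted draw under the seeded generator is returned, making designs
reproducible. Barcodes are drawn over {A, G, T} (top strand cytosine-free;
the mirror-image rule, no G on top, is equally valid and accepted by the
validator) and a candidate cassette is rejected if any other library PFM
scores a hit at the fractional 0.9 threshold anywhere on it.

One edge case surfaced by testing: a CG can form at the junction between
the motif and a barcode in one variant but not the other (the scramble may
move a terminal C). Such junction CpGs have no partner offset in the other
table and are dropped from Δmet profiles with a warning.

## Simulator

The generator reproduces the experiment's structure, not its biology:

- **Backbone** — ≥600 bp drawn CG-free (G never follows C), after which
  the exact target number of CG dinucleotides is planted at
  non-overlapping positions; the realised CpG ratio (#CG / length) matches
  the 3.6% target to rounding. Cassette barcodes never occur by chance.
- **Methylation** — each molecule draws one CpG methylation probability
  from Beta(ms, (1−m)s) with s = 1/overdispersion (default s = 50,
  modelling clone-to-clone heterogeneity); per-CpG states are then
  independent Bernoulli draws. A WT-only "HMR effect" subtracts a fixed
  delta at the CpGs nearest the motif (at least `n_cpgs`, extended until
  they span `span_bp`). Non-CpG cytosines methylate independently at the
  condition's non-CG rate.
- **Condition presets** — the five assay arms at their reported Sc-motif
  means (ESC −SssI 52.4%, ESC +SssI 79.1%, NP −SssI 81.7%, NP +SssI
  85.9%, TET-TKO +SssI 88.6% CG / 6.3% non-CG with the conversion filter
  bypassed), plus the knockdown contrast around the OCT4SOX2 WT motif
  (16% baseline, 39% after knockdown — the midpoint of the reported
  38–40% range). Conversion is 0.995 everywhere; baseline non-CG
  methylation is 0.2% outside the TET-knockout arm.
- **Reads** — R1 = 6 bp library barcode + 4 bp adaptor + 8-nt UMI +
  amplicon 5′ segment; R2 = reverse complement of the 3′ segment (PE300
  geometry). Each molecule is sequenced 1 + Poisson(dup_mean) times with
  the same UMI; substitution errors hit every base independently. With a
  ~636 bp amplicon and 300 bp reads, a ~54 bp mid-amplicon stripe is
  covered by neither mate; CpGs there are reported as masked. The cassette
  is placed at offset 150 so the classification anchor falls entirely
  inside R1.

Only top-strand (barcode-C-free-strand) chemistry is simulated by
default, matching the assay's strand-resolved PCR. Mates are processed
independently and reconciled per molecule rather than overlap-merged.
What the simulator does **not** model: indels, chimeric PCR artifacts,
bisulfite-induced degradation, position-dependent quality decay, motif-
dependent TF biology. Passing parameter-recovery tests therefore shows
the pipeline's estimators are unbiased under the generative model, not
that the model captures every artifact of real libraries.

## Read processing

- **Quality filter** — a pair is discarded when either mate's mean Phred
  is strictly below 20 (the read-level reading of a "quality <20"
  discard rule).
- **Demultiplexing** — exact match of the 10 bp barcode+adaptor key;
  the UMI is the 8 nt that follow it. UMIs containing N are excluded from
  deduplication.
- **Classification** — the search pattern covers barcode5+motif+barcode3
  on the C-free-barcode strand: CpG cytosines become `Y` (methylation-
  dependent C/T), other cytosines become `T` (full conversion assumed,
  because classification runs before the conversion filter; a strict mode
  renders them `Y`). Patterns are validated pairwise at load time — any
  two that can match a common string under IUPAC expansion are a
  configuration error. A pair is assigned when exactly one cassette is
  found across both mates (each scanned forward and reverse-complement,
  0 mismatches); conflicts leave it unassigned.
- **Alignment** — read and reference are C→T collapsed and the read is
  slid along the reference at every offset in both orientations; the
  placement with the best identity wins and must reach 0.9. Since no
  indels are simulated, a gapless semi-global scan is exact here and keeps
  the implementation transparent. At each reference cytosine the original
  read base gives the call (C→M, T→U, other or base quality <20 →
  missing).
- **Conversion filter** — a pair whose methylated fraction over observed
  non-CpG cytosines is ≥2% is discarded as an incomplete conversion;
  pairs observing no non-CpG cytosine cannot be assessed and are kept.
  TET-knockout mode bypasses the filter entirely (genuine non-CG
  methylation there sits above the threshold).
- **Deduplication** — exact mode groups identical UMIs; directional mode
  additionally merges UMI b into a when hamming(a,b)=1 and
  count(a) ≥ 2·count(b) − 1, processed from the most abundant UMI
  outwards with lexicographic tie-breaks for determinism. Consensus per
  cytosine is the majority over all reads of the group; ties are missing.
- **Aggregation** — per-CpG counts over deduplicated molecules, reported
  as signed offsets from the motif 5′ end inside the −300/+250 bp window;
  the ≥10 coverage minimum is applied to molecules (deduplication
  precedes extraction). Summary means are coverage-weighted
  (Σ n_meth / Σ n_total over unmasked CpGs).

## Differential methylation

Counts are modelled as beta-binomial with
Var = n·p(1−p)·(1+(n−1)φ). For each CpG the squared difference of the WT
and Sc proportions gives a one-degree-of-freedom method-of-moments
estimate of φ. A single CpG carries almost no information about its own
dispersion, and weighting its own estimate is self-normalising (the
estimate grows with the very difference being tested, which measurably
deflates the Wald tail), so the shrinkage limit is taken: every CpG
receives one profile-wide φ. That pooled estimate must also resist the
minority of genuinely differential CpGs, which would otherwise inflate
the dispersion and mask their own signal; it is therefore computed as an
iterated trimmed mean — initialise at φ = 0, trim CpGs whose provisional
Wald statistic exceeds 2.5, re-estimate from the rest with a χ²₁
truncation-bias correction (retained mass 0.9113 of the full mean), and
repeat to a fixed point. Ascending from zero settles on the lowest
consistent fixed point: genuine dispersion pulls the estimate up to its
true value while well-separated signal stays outside the trim. Under a
beta-binomial null this holds the 5% level at 0.045–0.050 across the
means, coverages and dispersions probed by the test suite.

The Wald statistic uses the pooled proportion in its standard error, so
with φ → 0 it reduces exactly to the classical two-proportion z-test.
p-values come from the normal reference, two-sided; q-values are
Benjamini–Hochberg within the profile (the "corrected p" of the HMR
rule). The test runs on raw per-CpG proportions: testing smoothed
proportions would correlate neighbouring statistics and invalidate the
nominal reference without an effective-sample-size correction.

Smoothing (for mean estimation and HMR qualification, as in
dispersion-shrinkage DMR callers) is a coverage-weighted running mean
over a 50 bp window (±25 bp, the CpG itself included); isolated CpGs are
unchanged and constant profiles are fixed points.

**HMR rule** — maximal runs of consecutive CpGs with smoothed
Δmet ≤ −10 points *and* q ≤ 0.05, reported when the run has ≥3 CpGs and
its first-to-last span strictly exceeds 50 bp. The sign convention
follows Δmet = WT − Sc: hypomethylation around the WT motif is negative.
A `direction` flag allows hyper- or magnitude-based calling. Both the
per-CpG q gate and the run rule are required.

**ΔΔmet** — the per-motif mean over shared CpG offsets of
Δmet_ESC − Δmet_NP (one value per motif, matching one point per motif on
a correlation plot); association with differential expression uses the
two-sided Pearson test. Motif clustering is agglomerative complete
linkage on Euclidean distances over the motifs × CpG-offsets Δmet
matrix; rows are pre-sorted by name so merge ties resolve
deterministically, all-missing rows are dropped with a warning and
remaining missing cells are imputed with their column mean. Dendrograms
serialise to Newick with branch lengths.

## Numerical and design choices

- All randomness flows from one integer seed through named substreams
  (`rng_for(seed, stage, ...)`), so any stage can be re-run in isolation
  and full runs are byte-identical (checksummed manifests).
- The boundary of the conversion filter is "≥2% discards"; the boundary
  of the quality filter is "mean <20 discards"; HMR span is strict
  (">50 bp"); fractional PWM thresholds use a 1e-12 tolerance against
  rounding at the cutoff.
- Dispersion trimming needs ≥3 retained CpGs; degenerate profiles fall
  back to the median-based initial estimate, which is conservative when
  nearly every CpG is differential (dispersion and signal are then not
  identifiable from a single profile).
- Test problem sizes: condition-recovery runs use 500 molecules per
  library (matching the coverage scale at which the assay reports
  condition means); calibration uses 1,000 CpGs × 200 replicates; HMR
  spike-in power uses 100 seeds at 500× coverage with four spiked CpGs at
  offsets −40/−12/12/40 — spanning 80 bp with both interior triples
  >50 bp and interior gaps inside the smoothing window, the geometry of a
  natural CpG cluster. With evenly spaced spikes (27 bp gaps) smoothing
  is inert and per-CpG binomial noise alone caps run detection near
  92–94%; the measured power under the documented geometry is 96%, with
  0/100 false HMRs under the matched null.

## Known limitations

- The aligner is gapless; real indel-bearing reads would be dropped at
  the identity threshold rather than aligned.
- Bottom-strand chemistry is not called; bottom-strand reads (if enabled
  in simulation) fail the collapsed-space identity threshold and are
  counted as alignment drops.
- The dispersion model pools one φ per profile; CpG-specific dispersion
  structure within a profile is not represented.
- The knockdown fold-change estimate divides two stochastic means of
  ~16% and ~39%; at 500 molecules its seed-to-seed standard deviation is
  about 0.1, so individual seeds can land near the edges of a ±0.3
  acceptance band around 2.5.
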