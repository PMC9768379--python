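# Methods

This note documents the models, statistical procedures, parameter defaults,
and design choices behind `poliseq`, and what the synthetic-data tests do and
do not establish about real data.

## Template model

The package operates on a single rDNA transcription unit: the nontemplate
(RNA-like) strand sequence plus an ordered region annotation that tiles the
unit without gaps or overlap. Internal coordinates are 0-based half-open;
every user-facing report is 1-based relative to the transcription start site
(so the first encoded C after a 55-nt C-less leader is reported as +56).
Region boundaries follow the half-open convention: a boundary position belongs
to the downstream region. Non-ACGT characters are rejected rather than masked
because PWM and entropy arithmetic downstream assume a four-letter alphabet.
The ~200 genomic tandem repeats are collapsed onto one template; libraries are
treated as independent draws from it, which is how a single-locus reference
sees collapsed multi-copy data.

The bundled default template is synthetic: pseudo-random sequence with
per-region GC content, region lengths ETS1 700, 18S 1800, ITS1 360, 5.8S 160,
ITS2 230, 25S 3050, ETS2 400 (total 6,700 nt, so a 10%-of-gene bin is 670 bp).
The proportions are plausible yeast-like choices, not measured boundaries; any
real annotation can be supplied as FASTA + BED-like region TSV.

## Pause/dwell model

Steady-state occupancy is read as a snapshot: the probability that a NET-Seq
read's 3′ end falls at position *i* is dwell(*i*)/Σ dwell. Dwell is
multiplicative in sequence context over a window of offsets relative to the
last incorporated nucleotide (offset 0):

    log dwell(i) = Σ_{o ∈ W} log w(base at i+o) + b·(1 − i/L) [+ noise]

* **Window W** defaults to −9..0 (10 nt), covering a canonical-length RNA:DNA
  hybrid plus the incorporation site; configurable.
* **w(base)** are per-strain positive weights; missing bases default to 1.
* **b** (`five_prime_bias`) is the total log-range of a 5′→3′ tilt; 0 = flat.
* Optional lognormal positional jitter (`noise_sd`, default 0) requires a
  seed.
* Dwell is rescaled to mean 1, so a strain's global slow-down factor
  (`slowdown`) cancels out of dwell and of CPM-normalized occupancy; it is
  retained on the parameters because it scales steady-state polymerase
  *density* (slower transcription at equal initiation ⇒ proportionally more
  engaged complexes), which the CLI uses for Miller-spread simulation.

This is deliberately not a kinetic elongation model: no cooperative pushing,
torsional stress, or co-transcriptional folding. Exclusion between polymerases
is modeled only for Miller snapshots, not for NET-Seq reads (reads from
different rDNA copies are effectively independent).

### Strain scenario defaults

`make_strain_pair_scenario` returns documented strong-effect presets: WT
weights A 0.75, C 1.55, G 0.80, T 1.35; mutant the mirror image (A 1.55,
C 0.75, G 1.35, T 0.80), both over the −9..0 window; mutant slowdown 2.5× and
5′ tilt b = 2.0 (5′ dwell ≈ e² × 3′ dwell), reflecting a mutant that pauses on
A/G-rich hybrids and accumulates promoter-proximally with depleted 3′
occupancy. With a ~2× per-base weight ratio compounded over 10 window
positions, the strain contrast redistributes well over 30% of occupancy mass
(total variation distance ≈ 0.7 between the two dwell distributions), so at
the depths used throughout (≥10⁵ reads/library) strain identity — not
replicate sampling noise — dominates every downstream comparison. No
quantitative pause-strength values exist for either real strain; these numbers
are synthetic by construction and labeled as such.

## Synthetic libraries

A library of depth *D* contains exactly round(contamination_frac · D)
contaminant reads (deterministic split — removes binomial noise from
read-conservation checks) with 3′ ends uniform over mature-region positions
only, modeling mature-rRNA carry-over that cannot reach the spacers; the rest
are nascent reads drawn from the dwell distribution. Each read is the template
substring of `read_len` (default 40) nt ending at its 3′ end, truncated at the
TSS when necessary, never padded. The FASTQ layout is
`[8-nt UMI][insert][3′ adaptor]` with constant quality "I"; the exact linker
chemistry of real protocols differs and can be declared in config. Record
headers carry the ground truth for validation; the processing pipeline never
reads them.

What the generator does **not** emulate: PCR duplication families (UMI
collisions are the only duplicate source), sequencing errors, ligation bias,
variable read quality, partial adaptors from short inserts, and any
non-rDNA genomic background. Consequently, passing tests demonstrate that the
*analysis* recovers planted signal under the stated statistical structure —
not that the pipeline is robust to real-data artifacts such as error-tolerant
alignment; real alignments can be imported as per-position count tables.

## Read processing

Order mirrors standard NET-Seq preprocessing: deduplicate → trim → map →
normalize, with a full accounting identity
(`input = duplicates + no_adaptor + unmapped + ambiguous + mapped`).

* **Dedup key** = (UMI, full insert sequence), pre-trimming; first occurrence
  survives; idempotent.
* **Trimming** removes the longest read suffix that exactly matches a prefix
  of the adaptor (≥ `min_overlap`, default 5); reads without any such suffix
  are discarded and counted.
* **Mapping** is exact and single-locus: the 3′-terminal `min_match`-mer
  (default 18, floor 12) is looked up in a template k-mer index and the full
  insert must extend to an exact match. Unique hit → the 3′-end position is
  counted; none → unmapped; several → ambiguous, discarded. Zero mismatch
  tolerance keeps the mapper verifiable against a sliding-window oracle; it
  is *not* a substitute for genome-scale alignment of real reads.
* **Normalization** = counts per million template-mapped reads (CPM). This is
  the minimal scheme making depths comparable; whether mature-region
  (contaminated) counts should be excluded from the denominator is a judgment
  call — here they are included, documented, and the spacer-restricted
  analyses are insensitive to it because CPM is a single global scale factor
  and all spacer statistics are either rank-based, distribution-normalized, or
  two-sample comparisons under the same convention.

## Occupancy statistics

* **Per-position test**: two-sided Welch (unequal-variance) *t* test on
  normalized replicate values, n = 3 per strain typically. No multiple-testing
  correction by default (each position colored at its own p < 0.05; an
  optional Benjamini–Hochberg flag exists). Positions with zero variance in
  both strains and equal means get p = 1 / no-change rather than NaN.
  Classification is by median direction; equal medians are never called
  changed.
* **Region KS**: each strain's positional distribution within a region is its
  normalized counts rescaled to sum 1; D = max |ΔECDF| over positions. The
  p-value uses the asymptotic Kolmogorov tail with Stephens' correction at
  effective sample sizes equal to region-mapped read counts, capped at 10,000
  per strain — read-level n at NET-Seq depths would otherwise force p ≈ 0 for
  trivially small D. The cap is configurable and its value is a reporting
  choice, not a discovery threshold.
* **Moving average**: centered, odd window, truncated (not padded) edges.
* **Spearman matrix**: average-rank ties; constant profiles reported as NaN.
* **PCA**: libraries × positions CPM matrix, column-centered, SVD; variance
  fractions sum to 1. With 3+3 replicates of a strong strain contrast, PC1
  carries the strain axis.

## Pause sites and differential logos

Pause sites are the top q% (default 2.5) positions by replicate-median CPM
within the spacer regions only (mature regions are contaminated and excluded);
ties break toward the lower coordinate; the site count is ⌈q/100 · n⌉ of the
1,690 spacer positions (43 sites at default). Contexts use window −10..+5 (16
nt: hybrid + downstream DNA); positions whose window leaves the template are
dropped and counted. PWMs use pseudocount 0.5 per letter (avoids log 0 on
small context sets). Per offset, the divergence between strains is the
Jensen–Shannon divergence in bits (symmetric, ≤ 1); signed per-letter
contributions are probs(mutant) − probs(WT), so positive values mean
mutant-enriched (conventionally drawn below the axis; the JSD itself stays
non-negative and the sign convention lives entirely in the deltas).
Significance per offset: pooled-label permutation of context-set membership
with set sizes preserved, p = (1 + #{permuted JSD ≥ observed})/(n_perm + 1),
default n_perm 999 (minimum attainable p = 1/1000). No across-offset
correction by default, matching per-position significance marking; the
permutation machinery supports a max-statistic correction if desired.

## Miller-spread gaps

Each simulated gene receives Poisson(target_density) polymerases (default 50,
the canonical packing of an active 35S gene), placed sequentially by
dwell-weighted sampling with hard-core exclusion: a draw landing within one
footprint (default 40 nt) of an accepted position is rejected and redrawn, up
to 200 attempts per polymerase. Retrying (rather than discarding) colliding
draws keeps the realized mean at the Poisson target; with the default cap,
placement failures are negligible at feasible densities.

Gap analysis is purely geometric: polymerase-free intervals are the complement
of the footprints (each polymerase blocks ± footprint/2 around its active
site, clipped to the gene); a gene with zero polymerases is one whole-gene gap
starting at 0. "Large" gaps are strictly longer than 25% of the gene by
default — room for ~40 packed polymerases — with the >23% variant exposed as
an alternative preset rather than silently privileged. Start sites
(promoter-proximal edges) are binned in 10%-of-gene bins reported at bin
midpoints; a gap longer than fraction t cannot start beyond 1 − t of the gene,
so the 3′-most bins are structurally empty. Gene-level frequency counts genes
with ≥ 1 large gap (a gene counts once regardless of how many large gaps it
carries); bin frequencies are normalized per gene scored.

Under a flat dwell at ~50 polymerases/gene, whole-quarter gaps are essentially
impossible; in simulation, elevated large-gap frequency emerges from spatial
dwell structure (e.g. the mutant's 5′ tilt depleting 3′ occupancy), and the
tests assert the mutant-vs-WT *direction* of the effect, not any absolute
frequency — absolute gap frequencies in micrographs also reflect gene-to-gene
activity heterogeneity that the Poisson-per-gene model does not include.

## Numerical and degenerate-input choices

* JSD is clipped to [0, 1] against floating-point negatives; inputs must sum
  to 1 within 1e−6.
* All-zero profiles cannot be normalized (error), empty regions cannot be
  KS-tested (error), constant profiles yield NaN correlations (reported as
  missing).
* Ties in pause-site calling break deterministically toward the 5′ coordinate.
* Every stochastic routine takes an explicit seed; CLI outputs embed the
  resolved-config SHA-256 and seed, and reruns are byte-identical.

## Problem sizes used in the shipped analyses

The packaged test-and-reproduction runs use the default 6,700-nt template,
libraries of 5×10⁵ reads (10⁵ for calibration checks), 3 replicates per
strain, contamination 0.1, 999-permutation logos, and Miller simulations of a
few hundred to 2,000 genes — sizes at which every stochastic assertion has
comfortable margin while the full suite completes in a few minutes on one CPU.

## Known limitations

* Exact-match mapping and single-record references only; no mismatch/indel
  tolerance, no multi-locus genomes, no spike-in normalization.
* The dwell model is positionally independent given the window (no k-mer
  coupling beyond the multiplicative window, no RNA secondary structure).
* KS effective-n capping makes region p-values a calibrated summary rather
  than an exact sampling distribution.
* Miller simulation draws per-gene loads from a single Poisson rate; real
  spreads mix gene activity states.
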