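# poliseq

In vivo transcription-elongation analysis for RNA polymerase I (Pol I) on the
ribosomal DNA, built around NET-Seq (native elongating transcript sequencing)
occupancy profiles and electron-microscopy Miller chromatin spreads.

Pol I transcribes the yeast 35S rRNA gene — a single ~6.7 kb unit present in
~200 tandem repeats — and processing of the transcript begins while the
polymerase is still elongating. Mutations that perturb elongation (such as
trigger-loop point mutants) change where the polymerase pauses, and aberrant
pausing disrupts co-transcriptional rRNA processing and ribosome assembly.
`poliseq` provides the quantitative toolbox for characterizing such pausing
phenotypes:

* **Template model** — the 35S unit with its spacer (ETS1, ITS1, ITS2, ETS2)
  and mature (18S, 5.8S, 25S) regions; spacers matter because they are free of
  mature-rRNA contamination and report nascent transcription only.
* **Read processing** — UMI deduplication, 3′-adaptor trimming, and exact
  single-locus mapping of each read's 3′ end (the polymerase's last
  incorporated nucleotide) to single-nucleotide occupancy profiles, normalized
  to counts per million mapped reads (CPM).
* **Occupancy statistics** — per-position Welch *t* tests between strains with
  increased/decreased/no-change classification, two-sample Kolmogorov–Smirnov
  comparisons of positional distributions per spacer region, moving-average
  and ECDF summaries, replicate Spearman correlation matrices, and PCA of
  libraries × positions.
* **Pause-site sequence logos** — the top 2.5% occupied spacer positions per
  strain, position weight matrices over a window anchored at the last
  incorporated nucleotide (offsets −10..+5; offsets ≤ 0 cover the RNA:DNA
  hybrid), per-offset Jensen–Shannon divergence between strains in bits with
  signed per-letter contributions, and pooled-label permutation *p*-values.
* **Miller-spread gap statistics** — polymerase-free intervals from per-gene
  position lists, "large gap" calling (> 25% of the gene, enough room for ~40
  packed polymerases), start-site binning in 10%-of-gene bins, and per-strain
  gap frequencies.
* **Synthetic-data generator** — sequence-context dwell models (occupancy ∝
  dwell), strain scenarios with opposite nucleotide preferences (WT-like C/T
  vs mutant-like A/G in the hybrid window), mature-region-only contamination,
  and dense-packing Miller snapshots, so the entire pipeline is testable
  without external data.

## The model in brief

A pause model assigns each template position *i* a dwell weight

```
dwell(i) ∝ Π_o  w(base at i+o),   o ∈ {−9,…,0}
```

optionally times a 5′→3′ log-linear tilt, rescaled to mean 1. NET-Seq read 3′
ends are drawn with probability dwell(i)/Σ dwell, plus a fixed fraction of
contaminant reads uniform over mature regions. Differential sequence
preferences between strains are summarized per window offset by

```
JSD(P, Q) = H((P+Q)/2) − (H(P) + H(Q))/2        (log base 2, ≤ 1 bit)
```

between the two strains' pause-context base distributions, with significance
from permutation of context-set membership.

## Worked example

```python
import numpy as np
import poliseq as pq

template = pq.make_default_template()                       # 6,700-nt synthetic 35S
wt_params, mut_params = pq.make_strain_pair_scenario(template)
wt = pq.build_pause_model(template, wt_params)
mut = pq.build_pause_model(template, mut_params)

def library(model, seed):
    lib = pq.simulate_netseq_library(model, depth=100_000,
                                     contamination_frac=0.1, seed=seed)
    return pq.process_library(lib.full_sequences(), template,
                              adaptor=lib.adaptor, umi_len=lib.umi_len,
                              library_id=f"{model.strain_label}-{seed}",
                              strain=model.strain_label)

wt_reps = [library(wt, s) for s in (1, 2, 3)]
mut_reps = [library(mut, s) for s in (4, 5, 6)]

print("mapping stats, first WT replicate:", wt_reps[0].stats)
rho = pq.spearman_matrix(wt_reps).iloc[0, 1]
print(f"WT replicate Spearman rho: {rho:.3f}")

ets1 = template.region_by_name("ETS1")
D, p = pq.region_ks_test(wt_reps[0], mut_reps[0], ets1)
print(f"ETS1 KS: D = {D:.3f}, p = {p:.2e}")

med_wt = pq.median_occupancy(wt_reps)
med_mut = pq.median_occupancy(mut_reps)
result = pq.compare_pause_contexts(template, med_wt, med_mut,
                                   q=2.5, n_perm=999, seed=0)
i0 = result.offsets.index(0)
print(f"offset 0: JSD = {result.jsd[i0]:.3f} bits, "
      f"deltas A/C/G/T = {np.round(result.letter_deltas[i0], 2)}, "
      f"p_perm = {result.p_perm[i0]:.3f}")
```

Output:

```
mapping stats, first WT replicate: {'mapped': 99793, 'unmapped': 181, 'ambiguous': 0, 'input_reads': 100000, 'duplicates_removed': 26, 'discarded_no_adaptor': 0}
WT replicate Spearman rho: 0.855
ETS1 KS: D = 0.176, p = 1.56e-116
offset 0: JSD = 0.222 bits, deltas A/C/G/T = [ 0.38 -0.2   0.16 -0.33], p_perm = 0.001
```

Reading the numbers: 99.8% of reads map uniquely back to the template (the
unmapped remainder are TSS-truncated reads shorter than the 18-nt match seed);
replicate rank correlation is 0.855 at this modest depth of 1e5 reads and
exceeds 0.9 at 5e5; the KS test rejects identical positional distributions in
ETS1; and at the last incorporated nucleotide the mutant's pause contexts are
strongly enriched for A (+0.38) and G (+0.16) at the expense of C/T, with the
minimum attainable permutation *p* of 0.001 — the mutant pauses on A/G
contexts where the WT prefers C/T.

The same scenario is available from the shell:

```
poliseq demo --outdir results/demo            # simulate → process → stats → logo → gaps
```

which writes FASTQ libraries plus truth tables, per-library occupancy tables
and bedGraphs, the per-position *t*-test map, per-region KS table, Spearman
matrix, PCA fractions, the differential-logo table, pause-site BEDs, and
per-strain gap summaries, each stamped with the config hash and seed.

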