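# cswitch

Analysis toolkit for a recurring question in regulatory genomics: **how a
chromatin co-factor redirects a signalling transcription-factor complex
across the genome.** The motivating biology is the BMP pathway, where the
SMAD4/pSMAD1/5/8 complex binds DNA weakly and depends on co-factors such
as PRDM16 to choose between repressive and activating regulatory elements.
When the co-factor is absent, SMAD occupancy drops at formerly co-bound
sites and the complex relocates to nearby ("ectopic") sites — an
*enhancer switch*. `cswitch` implements the complete computational side of
such a study as a tested, reusable pipeline, exercisable end-to-end on
synthetic data with planted ground truth.

Intended users: computational biologists analysing CUT&TAG / ChIP-seq
style sparse coverage for two factors across two genotypes, plus
promoter-activity profiling (e.g. H3K4me3) and per-cell transcript dot
counts from multiplexed in situ experiments.

## What it computes

* **Interval algebra** (`cswitch.intervals`) — BED parsing, strict
  direct-overlap merging (book-ended intervals never merge), replicate
  consensus (peaks supported by *every* replicate), two-set Venn
  bookkeeping of lost/common/gained peak loci, and peak-to-promoter
  assignment over `[TSS − 500, TSS + 500)` windows.
* **Coverage** (`cswitch.coverage`) — bedGraph tracks as run-length
  signal, reads-per-million (RPM) normalization, per-base input
  normalization `(chip + c)/(control + c)`, summit finding and
  summit-centred metaplot matrices.
* **Peak calling** (`cswitch.peakcall`) — sparse-enrichment calling for
  CUT&TAG-like data: candidate blocks of contiguous signal scored by total
  signal, thresholded at an empirical false-discovery proportion against a
  control (IgG/input) track, FDR 0.1 by default.
* **Motif scanning** (`cswitch.motifscan`) — IUPAC degenerate matching on
  both strands with correct handling of self-reverse-complement patterns.
  Built-in catalogue: the SMAD palindrome `GTCTAGAC`, the GTCT direct
  repeat `GTCTGTCTGTCT`, two GC-rich SMAD-binding elements
  (`GGCGCCANNNNGNCV`, `GRCGNCNNNNNGTCT`) and an AP1 site (`TGASTCA`);
  per-peak occurrence frequencies across score-quantile bins, stratified
  by co-factor co-binding.
* **Co-binding & relocation** (`cswitch.cobind_switch`) — the core
  inference. Sites are *co-bound* iff they overlap a co-factor peak by
  ≥ 1 bp. Co-factor dependence: paired-by-site two-tailed t test of
  per-site window signal between genotypes, per stratum. Relocation:
  non-co-bound sites within 200 kb of a co-bound summit are tested for
  differential occupancy with a moderated t statistic (per-site variance
  shrunk toward the across-site mean, prior weight d0 = 4) and
  Benjamini–Hochberg control at q < 0.1.
* **Promoter activity** (`cswitch.promoter_activity`) — TSS ± 500 bp
  signal, the same moderated differential statistic at p < 0.01,
  repressed-gene set intersection logic, and Fisher's exact test of
  binding enrichment between gene groups.
* **Cell statistics** (`cswitch.cellstats`) — per-gene genotype
  comparisons of dot counts via the rank-sum ROC AUC (half-credit ties),
  Pearson correlation matrices and multi-gene least-squares fits.
* **Synthetic data** (`cswitch.synthetic_data`) — a generator that plants
  every effect the pipeline is meant to recover (co-binding classes,
  occupancy attenuation 2^−δ, ectopic relocation within a bounded offset,
  class-specific motifs written into the genome, repressed promoter sets,
  per-cell genotype effects with a correlated gene pair) and emits the
  truth tables to check recovery against.

## Worked example

One command simulates a dataset and runs every stage:

```
cswitch pipeline --out run --seed 3
```

Stage summary printed at the end (abridged):

```
"callpeaks": {"n_consensus": {"smad_wt": 329, "smad_ko": 379,
                              "cofactor_wt": 100, "cofactor_ko": 0}},
"venn":      {"lost": 0, "common": 329, "gained": 50},
"cobind":    {"n_sites": 379, "n_cobound": 100},
"relocate":  {"summary": {"cobound": -0.94, "flanking": 4.5273}},
"promdiff":  {"bmp_repressed": 50, "cofactor_repressed": 50},
"setlogic":  {"co_repressed": 20, "fisher_one_sided_p": 0.0201},
"cellstats": {"mki67_axin2_r": 0.826, "fit_r_squared": 0.702}
```

Reading it: the simulation planted 100 co-bound, 100 solo and (at this
seed) 129 promoter-bound SMAD sites; replicate consensus recovered 329 of
them in the co-factor-present genotype and 100 co-factor peaks. The null
genotype gains exactly the 50 planted ectopic loci (`venn.gained`).
Co-bound sites lose occupancy (mean log2 fold change −0.94, planted −1.0)
while flanking sites within 200 kb gain strongly (+4.5). Both planted
50-gene repressed sets are recovered with their 20-gene overlap, and in
the cell table the proliferation marker correlates with the Wnt activity
readout (r = 0.83) as planted through the shared latent factor.

Every stage is also a standalone command over standard files
(`cswitch callpeaks|consensus|venn|metaplot|motifbin|relocate|promdiff|setlogic|fisher|cellstats`),
e.g. the binding-enrichment test from published counts:

```
$ cswitch fisher --g1 24 31 --g2 84 153
odds_ratio      2.816
p_one_sided     0.01511
p_two_sided     0.02689
```

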