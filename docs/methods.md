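# Methods

This note documents the models, defaults and numerical choices behind
`cswitch`, in the order data flows through the pipeline.

## Coordinate and signal conventions

All intervals are 0-based half-open (BED convention); bedGraph shares it.
"Direct overlap" always means ≥ 1 shared base: book-ended intervals do not
merge, a peak binds a promoter only if it overlaps the window by ≥ 1 bp.
Signal tracks are run-length lists per chromosome; uncovered bases read as
zero. RPM normalization multiplies raw per-base counts by 10⁶ / library
size, where the library size of a raw track is its own total count.
A pseudocount of **0.1 RPM** is added before every ratio and log2 fold
change. The value is a compromise: it must be large enough to stabilise
zero-coverage windows, but any pseudocount compresses fold changes by
roughly `log2((x/2+c)/(x+c))` versus the true −1 at typical per-site
signal `x`; at the few-RPM window means this data regime produces, 0.1
keeps that compression under 0.05 log2 units while 0.5 would flatten a
planted −1.0 to ≈ −0.85.

## Synthetic data model

The generator emulates a two-factor × two-genotype chromatin profiling
study plus a promoter-activity factor and a per-cell count table. It is
the fixture for everything else, so its defaults *are* the study
conditions:

| parameter | default | meaning |
|---|---|---|
| `n_smad_sites` | 200 | distal SMAD-type sites (split by `cobound_fraction`) |
| `cobound_fraction` | 0.5 | fraction of distal sites co-bound by the co-factor |
| `dependence_effect_delta` | 1.0 | log2 drop of SMAD signal at co-bound sites in the null genotype |
| `relocation_fraction_rho` | 0.5 | fraction of co-bound sites gaining an ectopic partner in the null genotype |
| `relocation_distance` | 200 000 bp | maximum co-bound-to-ectopic distance |
| `ectopic_offset_range` | 4–11 kb | realised offsets (well inside the window; peaks stay ≥ 3 kb apart) |
| `n_replicates` | 3 | per factor × condition |
| `library_size` | 10⁶ reads | expected total per replicate track |
| `peak_width` | 1 000 bp | triangular kernel width |
| `background_rate` | 0.02 reads/bp | genome-wide background |
| `n_genes` | 500 | genes at 3 kb spacing on their own chromosome |
| `repressed_set_sizes` | (50, 50, 20) | BMP-repressed, co-factor-repressed, overlap |
| `promoter_effect` | 1.0 | log2 elevation of repressed promoters in the perturbed condition |

Layout: chromosome 1 carries the co-bound sites at 25 kb spacing together
with their ectopic partners; chromosome 2 carries solo sites; chromosome 3
carries genes. Keeping solo sites on a separate chromosome makes the
planted flanking set of the co-bound sites exactly the ectopic class,
which is what parameter-recovery checks need. Genes drawn as "bound" (with
class-dependent probability: 0.8 for co-repressed, 0.5 for singly
repressed, 0.2 otherwise) receive a real SMAD promoter peak, so the
peak-to-promoter and Fisher stages run on called peaks, not annotations.

Coverage is a flat background plus a unit-mass triangular kernel of width
`peak_width` per site, Poisson-sampled per base. Sampling is implemented
as a Poisson total split into uniform background reads and
profile-positioned peak reads — by Poisson thinning this is exactly
per-base Poisson sampling, just faster. There is no read-length/fragment
model and no mappability or GC bias; coverage-level emulation is all the
downstream stages consume.

**Composition balance.** Every condition with planted enrichment keeps the
same expected total (`library_size`); the background rate absorbs the
planted excess, and amplitudes are sized against the most-loaded
condition. Without this, library normalization converts the planted
elevation at 50 promoters into a spurious ≈ 0.1 log2 shift at all 450
unperturbed ones — a real artefact of global normalization that would
dominate the false-call statistics of a generator that ignores it.
Knocked-out-factor and IgG tracks keep the nominal background rate; their
small libraries are what a depleted immunoprecipitation produces.

Motifs are written into the random genome at site centres: the palindrome
at co-bound sites (rate 0.8), a GC-rich element at solo sites (0.6), the
AP1 site at ectopic sites (0.8); degenerate positions are instantiated
randomly and the exact planted coordinates recorded in the truth table.
Because planting is Bernoulli, the *realised* planted fraction of a given
dataset (recorded in `truth.tsv`) is the reference for recovery checks,
not the configured rate.

The cell table models two regions (CH, ChP) × two genotypes × 110 cells ×
3 replicates over ten marker genes with Poisson counts; the mutant-ChP
effect is a per-gene log2 shift, and one gene pair (proliferation marker
and Wnt-activity readout) shares a log-normal latent factor (σ = 0.6)
that plants their correlation.

Determinism: every random stream derives from the master seed with fixed
integer tags (genome, layout, motifs, one stream per factor × condition ×
replicate, cells), so identical configs give byte-identical outputs and
adding replicates does not perturb earlier streams.

What passing on this generator does **not** show about real data:
fragment-level artefacts (duplicates, size selection), mappability and GC
structure, peak-shape heterogeneity, antibody efficiency differences
between factors, and overdispersion beyond Poisson are all absent. The
pipeline's statistical calibration on real data therefore rests on the
moderated test's robustness, not on these simulations.

## Peak calling

Candidate blocks are maximal runs of covered bases, bridging uncovered
gaps of ≤ 10 bp. The bridge is needed because at Poisson-sampled depth the
flanks of a genuine peak drop to zero repeatedly; without it each site
fragments into several blocks and every count downstream doubles. Ten
bases is far below the typical background read spacing (1/0.02 = 50 bp),
so background does not chain.

Each block is scored by its **total signal**. The retention threshold is
the smallest observed block total `t` at which the empirical
false-discovery proportion

```
FDR(t) = frac(control blocks ≥ t) / frac(signal blocks ≥ t)
```

drops to the requested level (default 0.1, "FDR < 10%"). When no
threshold achieves it — e.g. the control is as enriched as the signal —
the caller falls back to the (1 − fdr) quantile of the control block
totals and flags the run; under a null where control and signal are
draws from the same distribution this retains ≈ the nominal fraction of
blocks. This is a transparent re-implementation in the spirit of
sparse-enrichment callers for CUT&TAG-style data; equivalence with any
published implementation is a non-goal, and only a total-signal
("non-stringent"-style) mode is provided.

## Consensus, Venn and co-binding

Replicate consensus keeps merged loci supported by ≥ 1 peak from *every*
replicate. The Venn counts jointly merged loci once each (a locus with
members from both sets is one "common" locus); for bookkeeping from
published set totals, `VennCounts.from_totals` completes the diagram
arithmetically (`common = |A| − lost`, `gained = |B| − common`). A single
locus spanning several peaks of the other set is counted once; the
per-set totals can therefore differ slightly from counting within each
set separately.

Co-binding is a ≥ 1 bp overlap between a SMAD-type site and a co-factor
peak. Per-site signal for all occupancy statistics is the mean normalized
coverage in a ± 500 bp window around the summit (configurable), which is
comparable across sites of different widths.

## Differential statistics

Both differential binding and differential promoter activity use the same
moderated two-sample t statistic on log2(signal + 0.1): the per-feature
pooled variance is shrunk toward the across-feature mean with a fixed
prior weight d0 = 4, and the null is t with d0 + nA + nB − 2 degrees of
freedom. A fixed-prior shrinkage was chosen over a fitted empirical-Bayes
prior because it is transparent, easily oracle-checked, and calibrated on
this data regime (observed null type-I fraction 0.032–0.05 at nominal
0.05 over 500 features). The dependence test is instead paired by site
across strata means, two-tailed; with identical inputs the difference is
exactly zero and p is reported as 1.

Multiple testing uses Benjamini–Hochberg, applied jointly across all
tested sites (co-bound + flanking) in the relocation analysis;
significance is q < 0.1 there and unadjusted p < 0.01 for promoter calls
(matching the conventions of the respective analyses). Sites or genes
with zero signal in every replicate of both conditions are dropped with a
warning.

Fisher's exact test reports both sidednesses; the one-sided (enrichment)
value is the headline, which is the reading consistent with published
values for this table shape. Degenerate tables (a zero margin) return
p = 1 with an undefined odds ratio, flagged.

## Motif statistics

IUPAC patterns compile to character classes and are scanned with
overlapping matches on both strands; a pattern equal to its own reverse
complement (the palindrome, and also `TGASTCA`) would otherwise report
every hit twice, so such hits are reported once with strand ".".
Binned frequencies rank peaks by score within each co-binding stratum and
cut them into five equal-count bins (ties broken by rank order); the
primary statistic is presence (fraction of peaks with ≥ 1 match), robust
to peak-width differences, with matches-per-kb emitted alongside. The
reading of the GC-rich element "GGCGCC-AN4-GNCV" as `GGCGCC + A + NNNN +
GNCV` is one of two possible parses; the pattern table is replaceable via
a TSV for the alternative.

## Cell statistics

Group comparisons use the ROC AUC with half-credit ties — appropriate for
small integer dot counts — with the Wilcoxon rank-sum null for p values.
Cells are pooled across replicates for the primary statistics, with
per-replicate means emitted alongside; no mixed-effects modelling.
Correlations are product-moment with two-sided p; zero-variance genes
yield flagged NaNs. Multi-gene fits are ordinary least squares with an
intercept; exactly collinear predictors raise an error naming a pair.

## Problem sizes

The default configuration (≈ 6.5 Mb genome, 23 tracks, 1 320 cells) was
chosen so a full pipeline run completes in well under two minutes on one
CPU; calibration uses 500 sites and 1 000 genes at the same depth. These
sizes put the planted effects at signal-to-noise comparable to a
well-powered real experiment (per-site window counts of a few thousand
reads across three replicates).

## Known limitations

* The peak caller is intentionally minimal: no fragment model, no
  duplicate handling, one scoring mode.
* The moderated test assumes roughly exchangeable per-feature variances;
  strongly heteroskedastic real data would want a fitted prior
  (limma-style) instead of the fixed d0.
* The Venn's per-set totals are defined on jointly merged loci (see
  above) — exact agreement with tools that count within-set loci is not
  guaranteed when peaks of one set straddle several of the other.
* Genome-scale results from the motivating study (thousands of peaks,
  specific gene counts) require the original sequencing data and are out
  of scope; the package reproduces the *procedures* and their printed
  worked examples, and validates recovery on planted truth.
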