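# Methods

This note documents the models behind `arrayqc`: what the synthetic-data
generator emulates (and what it does not), the QC statistics and their
conventions, the wave-correction and segmentation models, and the numerical
and design choices that were genuinely open.

## The synthetic study

The generator produces an Infinium-style genotyping study end to end:
a probe manifest, a cohort with blinded replicate structure, a per-call
table (genotype, confidence score, raw intensities, LRR, BAF), Identifiler-
style STR profiles, and truth tables for every injected artifact. A single
integer seed drives independent named streams, so identical (seed, config)
pairs yield byte-identical output files.

### Allele-frequency spectrum and heterozygosity

High-density exome-augmented arrays are rare-variant heavy. Per-locus MAF is
drawn as `0.5 · X` with `X` from the mixture
`0.744 · Beta(0.35, 6) + 0.256 · Beta(1.8, 1.2)`; genotypes follow
Hardy–Weinberg with no linkage disequilibrium (none of the QC metrics uses
LD). The mixture weight was solved analytically so the expected
heterozygous fraction `E[2m(1−m)] = 0.137`, the cohort median the pipeline
should recover; the rare component puts ≈ 60% of loci at MAF ≤ 5%.

### Sample quality and no-calls

Each sample carries a latent quality score `q ∈ [0, 1]`, drawn from a
clipped normal whose mean depends on (input type × source material):

| stratum | mean q (sd 0.15) |
|---|---|
| gDNA blood / buccal / Oragene | 0.772 / 0.760 / 0.763 |
| wgaDNA blood / buccal / Oragene | 0.701 / 0.604 / 0.723 |

The per-call no-call probability is `0.10 · (1 − q)`, so a sample fails the
95% call-rate threshold exactly when `q < 0.5`, and the stratum means above
were obtained by inverting the target stratum failure rates (gDNA uniformly
≈ 4%; wgaDNA buccal ≫ blood > Oragene) under that mapping. Confidence
scores are drawn so that the 0.25 no-call rule holds by construction:
failing calls get `U(0, 0.25)`, passing calls `0.25 + 0.75·Beta(5, 1.5)`.
The rule itself is applied downstream by the reader, not baked into the
analysis code.

Chip failures (probability 0.005 per chip) and plate failures (0.01) are
modelled by capping `q` for every co-located sample, which both drives all
four chip mates below the threshold and leaves the conservation invariant
intact: the number of NC calls in the table equals the injected mask count
exactly.

### Allele drop-out (the pair-type gradient)

Replicate concordance in mixed-input studies shows the ordering
gg ≥ ww ≥ gw. Drop-out that strikes each wgaDNA sample independently cannot
produce this — two independently corrupted copies would agree with each
other *less* than with the clean gDNA. Drop-out is therefore modelled at
the locus level: per (individual, locus), a site is "vulnerable" with
probability `0.0143 · (1 − q_ind)` and has a fixed surviving allele; each
wgaDNA sample of that individual then drops the other allele with
conditional probability 0.8. Both wgaDNA replicates tend to fail at the
same sites in the same direction and stay mutually concordant. The marginal
drop-out rate is `D(q) = 0.0114 · (1 − q)`, giving an expected gDNA–wgaDNA
concordance of `1 − h·D` (h = het fraction) and a wgaDNA–wgaDNA deficit
smaller by the factor `2·(1 − 0.8)`. With genotype error rate 5·10⁻⁵ the
defaults reproduce the gradient 99.99 / 99.97 / 99.94 in expectation.

### Positional artifacts

Each chromosome end is independently "under-amplified" with probability
0.5; loci inside the terminal three 50-kb windows of an affected end fail
*all* wgaDNA samples with probability 0.8 (the per-locus magnitude of
under-amplification is not separately parameterised — failure is all or
nothing, which is what a windowed failure map can detect). A fraction
0.0019 of probes fails everything regardless of input. GC waves enter LRR
as `amplitude · (gc − mean gc) + cpg_amplitude · (cpg − mean cpg)` scaled by
a per-sample factor `N(1, 0.2)`, plus a per-chip offset `N(0, 0.05)` and
per-call noise whose sd grows for wgaDNA as `0.12 · (1 + 1.2·(1 − q))` with
lognormal per-sample jitter — so a tail of wgaDNA samples exceeds the 0.30
sd gate and is excluded from CNV calling, the observed failure mode.

### CNV truth and BAF

Injected events use canonical signatures: gain ΔLRR +0.32 with het BAF at
1/3 and 2/3; loss ΔLRR −0.45 with het BAF at 0/1; CN-LOH ΔLRR 0 with het
BAF at 0/1; mosaic CN-LOH ΔLRR 0 with het BAF at `0.5 ± m/2` for cell
fraction `m`, the side chosen per locus (haplotype-like). Carriers are
drawn preferentially from individuals with both input types so matched-pair
concordance is exercised; events are germline (present in every sample of
the carrier). Genotype *calls* are not altered inside event regions — a
simplification that keeps the genotype-level metrics orthogonal to the
copy-number channel; real callers would miscall hets inside losses.

### What the generator does not emulate

Raw two-colour images and idat-level chemistry, dye bias, LD, pedigrees,
population structure, batch-specific cluster drift, and genotype-calling
errors correlated with intensity. Passing tests therefore demonstrate that
the *analysis* is correct under the stated artifact model, not that the
model captures every failure mode of real amplified DNA.

## QC conventions

* **Denominators.** gDNA: all probes minus complete failures; wgaDNA:
  additionally minus probes failing every wgaDNA sample.
* **Pass boundary.** A call rate of exactly 0.95 passes ("less than 95%"
  fails). The alternative "≤ 95%" reading that appears in copy-number
  contexts is treated as imprecise wording, not a second threshold.
* **Heterozygosity** is computed over autosomes only by default (sex
  chromosomes would depress male rates); outliers use Tukey fences with
  k = 3 — no canonical fence exists for this statistic, so k is exposed.
* **Concordance** is class-level (AA/AB/BB); an NC in either member removes
  the probe from the pair's denominator. Duplicate-locus concordance
  aggregates *within sample first*: a sample counts as concordant at a
  locus only if all its duplicate probes agree, and the locus concordance
  is the fraction of such samples; the per-input-type split at 99%
  yields the four classes. MAF uses one sample per individual (gDNA
  preferred, then highest call rate) and each locus's first probe.
* **Windows** are genome-anchored, 1-based half-open `[start, start+50000)`;
  BED output converts to 0-based. "Subtelomeric" means the terminal k
  covered windows at each chromosome end (k = 3 default) — coverage-based,
  because annotation of true telomere position is out of scope.

## Wave correction

LRR/BAF derive from cluster positions: normalized angle
`theta = (2/π)·atan2(y, x)`, `R = x + y`, expected R linearly interpolated
between the flanking genotype centroids, `LRR = log2(R/R_expected)`, BAF by
piecewise-linear interpolation of theta (clamped to [0, 1]); `x = y = 0` is
undefined and emitted as missing.

The correction model is deliberately fully specified rather than a
reimplementation of any particular toolchain: (1) quantile normalization
maps a sample's intensity vector onto a cohort reference distribution, with
ties receiving the mean of the tied reference positions (making the map
idempotent); (2) per-sample ordinary least squares of LRR on centred
`gc, gc², cpg, cpg²` (degree 2 default, configurable — the right degree is
an open choice; degree 2 suffices for the smooth waves modelled here);
(3) a per-chip multiplicative rescaling factor `2^(chip mean intercept)`,
which absorbs constant chip-wide intensity offsets exactly. Subtracting the
fitted term centres each sample at zero and can only reduce per-sample
variance (least-squares identity). A rank-deficient design (constant GC)
falls back to a lower degree with a warning. BAF is not wave-corrected:
correction demonstrably barely moves genotype-conditional BAF dispersion,
which is also why the sd report computes BAF sd against the 0/0.5/1 cluster
centres rather than the raw mean. Genotypes are never touched.

## Segmentation and classification

CBS searches every arc of a segment for the maximal |t| of arc vs
complement (enumerating contiguous arcs covers circular ones by
complementarity) and accepts a split when a permutation test gives
`p = (1+exceedances)/(1+N) < α` (α = 0.01, N = 1000 default, seeded; the
permutation generator is keyed by (seed, segment start, segment end) so
results are independent of recursion order, and drawing stops early once
significance is unreachable). Segments shorter than `min_probes` (20) are
dissolved into their neighbours — both boundaries removed — so a
sub-minimum event disappears instead of leaving a residual breakpoint.

Classification takes the union of breakpoints from the LRR and mirrored-BAF
segmentations and recomputes each atomic interval's mean LRR and mean mBAF
directly from the raw series, which stays robust when only one track saw
the event (mosaic events are LRR-silent; short gains contain too few hets
for the mBAF track to split). Default thresholds: gain `LRR ≥ +0.10` with
mBAF elevated (≥ 0.55); loss `LRR ≤ −0.15` with mBAF ≥ 0.90; CN-LOH
`|LRR| < 0.05` with mBAF ≥ 0.95; mosaic CN-LOH `|LRR| < 0.05` with
0.55 ≤ mBAF < 0.95 and cell fraction `2·(mBAF − 0.5)` (exact for
copy-neutral events only; gains/losses report no fraction). Conflicting
evidence is emitted flagged for manual review rather than dropped.
Informative probes for mBAF are heterozygous calls plus probes with BAF in
(0.15, 0.85), retaining mosaic hets the caller already homozygosed.

Matched-pair concordance uses optimal one-to-one assignment (maximum
matches, then maximum summed overlap) over candidate pairs with the same
chromosome and class and reciprocal overlap ≥ 0.5 — optimal rather than
greedy so that swapping reference and test exactly swaps FN and FP.

## STR screen

Per marker: fully concordant (equal allele sets), drop-out (strict
non-empty subset), failure (empty), or otherwise discordant; the accounting
always sums to 16. Contamination requires > 2 alleles at ≥ 2 autosomal
markers; amelogenin is checked against reported sex. Category cutpoints
(high: ≥ 15 concordant and no failures; poor: ≥ 3 drop-outs or ≥ 2 failures
or contamination; else intermediate) are invented operating points — no
standard exists — and are exposed in configuration. Peak-height
thresholding is upstream wet-lab; profiles arrive pre-thresholded and the
generator models drop-out directly.

## Problem sizes and numerical notes

Cohort-level checks run at 25k–50k probes and 200–600 samples (e.g. median
heterozygosity stabilises to ±0.01 well below 50k loci; replicate
concordance to ±0.01 percentage points with ~300 pairs at 25k probes);
segmentation suites use chromosomes of 400–1600 probes with 200
permutations, which keeps the permutation floor (1/201) below α while the
benchmark suites stay minutes-scale. These sizes are the package's chosen
operating points for validation, scaled from the full-array setting where
the same statistics are sums over ~100× more calls.

Tie-breaks: the CBS arc search takes the first maximum in (arc length,
start) order; exact ties have measure zero for continuous data. Degenerate
inputs: constant series return one segment; zero-variance windows make the
GC association explicitly undefined instead of NaN; empty wgaDNA profiles
count as marker failures, not drop-outs.

## Known limitations

Locus-consistent drop-out uses a single conditional-drop parameter rather
than a per-locus severity distribution; under-amplification is binary at
locus level; CNV events do not perturb genotype calls; the mBAF δ-window
cannot recover mosaic fractions above `1 − 2δ = 0.7` from homozygosed
calls; and the STR allele model ignores stutter and relative peak heights.
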