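# Methods

This note documents the models, estimators and design choices behind the
package, in the order data flows through an analysis.

## Coordinates and formats

All coordinates are 0-based, half-open (BED convention), everywhere.
Fragments are read from BED (≥ 3 columns) or from BAM/SAM proper pairs
(one template per pair, reconstructed from the leftmost mate; unpaired
records are skipped with a logged count). Coverage is written as
bedGraph (zero runs omitted, equal-value runs merged) or bigWig; both
round-trip exactly.

## Dyad-density vectors

Mononucleosomal templates are size-selected to lengths of 121–199 bp
inclusive (i.e. > 120 and < 200). Each fragment is reduced to a 50 bp
window centred on its midpoint: centre *c* = ⌊(start + end)/2⌋, window
[*c* − 25, *c* + 25), clipped at chromosome bounds. For even-length
fragments the floor picks the left-of-centre base; the resulting ≤ 1 bp
systematic shift is common to all fragments and cannot move
autocorrelation peak spacing. Strand is ignored (templates are
strandless). Coverage is accumulated at 1 bp resolution via a
difference-array (O(fragments + genome) time), so total mass equals
50 × fragments minus clipped overhang.

## Autocorrelation and repeat length

The regularity statistic is the biased, lag-0-normalised autocovariance
with the global mean:

    r[k] = Σ_t (x_t − μ)(x_{t+k} − μ) / Σ_t (x_t − μ)²,  k = 0 … 1000 bp.

This is the conventional default of mainstream statistics packages; the
per-lag Pearson variant differs by O(lag/n), negligible at genome scale,
and is deliberately not offered. The implementation is FFT-based
(linear, zero-padded to avoid circular wrap) and is checked in the test
suite against a direct-summation oracle to 10⁻⁹. r[0] is set to exactly
1; constant vectors are rejected ("zero variance").

State-conditioned analysis concatenates the coverage slices of one
state's domains head-to-tail in (chromosome, start) order. Junction
artifacts are accepted as-is: with domains of ~100 kb and lags ≤ 1 kb
fewer than 1% of lagged products straddle a junction.

Peak calling returns the two smallest lags ≥ `min_lag` (default 100 bp —
safely below the ~147 bp physical lower bound of nucleosome spacing,
above the lag-0 shoulder) that are strict local maxima; flat-top
plateaus are reported at their smallest lag. Two numerical guards
matter in practice:

* a rise smaller than `atol` = 10⁻⁹ does not count as a peak. On
  noise-free simulated combs the inter-peak trough is analytically
  constant, and FFT round-off otherwise produces float-level "maxima"
  there;
* an optional centred moving average (`smooth_window`, default off, must
  be < 50 bp to avoid peak displacement) for shallow libraries whose
  sampling ripple produces spurious early maxima.

The repeat length is the zero-intercept least-squares slope of the peak
positions (p₁, p₂) on peak index (1, 2): NRL = (p₁ + 2 p₂)/5. Estimates
are made on integer lags (no sub-bp interpolation; with peaks near
190/380 bp the induced error is ≲ 0.3 bp). Replicates are aggregated as
arithmetic mean ± SEM (sample SD/√n; undefined, reported as NaN, for
n = 1). The regularity amplitude is r at the first peak.

## Chromatin domains and genes

Domains are BED4 with states BLACK, BLUE, YELLOW, RED, GREEN (GRAY is
the synthesized complement); same-chromosome overlaps are rejected.
Gene-to-domain assignment is nearest-interval with explicit tie rules:
distance is gap length (0 if touching/overlapping); a gene overlapping
several states takes the largest overlap; remaining ties take the
domain with the smaller start. Genes on unannotated chromosomes fall
back to GRAY with a warning. The assignment uses the gene body, not the
TSS. The implementation is an all-pairs scan per chromosome, verified
against an independent oracle in the tests; the data sizes involved
(thousands of genes × hundreds of domains) do not warrant an interval
index.

Histone-mark levels are length-weighted means of windowed signal over
the gene body (NaN if uncovered). High/low classification finds the
cutoff at the deepest local minimum of a Gaussian KDE (Silverman
bandwidth, 512-point grid spanning the data ± 3 bandwidths) between the
two largest modes; unimodal densities raise "no bimodality detected".
By default each mark is cut on its own distribution — the only
scale-coherent choice when marks have different dynamic ranges — but
passing the H3K36me3 levels as `reference_values` applies one reference
cutoff to all marks. Genes are "marked" iff high in all four of
H3K27me3, H3K36me3, H3K9me3, H3K4me3. Note that Silverman's bandwidth
depends on n, so duplicating a sample moves the cutoff slightly;
high/low membership is stable, and tests assert exactly that.

## Reporter (TRIP) analysis

Normalized expression per condition is the double ratio
(cDNA/cDNA-total)/(gDNA/gDNA-total) per replicate, averaged across
replicates on the linear scale — matching "mean log₂ expression" axes
computed from averaged expression. Reporters with zero normalized
expression in any condition are discarded before fold-changes, so no
pseudocounts are needed; reporters with zero gDNA in a replicate are
unmeasurable there and treated as zero (hence filtered). Expression
dependence is ordinary least squares of log₂FC on log₂ mean normalized
expression with a two-sided t-test on the slope; slope differences
between datasets use a pooled OLS with a group × expression interaction
term.

## Expression stratification

Genes with zero counts in at least half the samples (#zeros ≥ n/2) are
dropped. Size factors are median-of-ratios: for genes positive in all
samples, the median over genes of count/geometric-mean. Per-gene
log₂FC = log₂((mutant mean + 0.5)/(wt mean + 0.5)) of normalized
counts — deliberately a ratio summary rather than a negative-binomial
GLM, which is out of scope here; the stratification readouts (medians
by state, quartile, marked status) only need a per-gene effect size,
and the ratio's small-count attenuation is noted below. Quartiles are
cut at linear-interpolation (type-7) percentiles of mean expression,
boundary ties to the lower quartile. The loess trend is a
tricube-weighted local-linear fit (span 0.75, no robustness
iterations) evaluated on a 100-point grid. The PCA gene selection
keeps variances strictly above the 85th and at/below the 99th
percentile; the PCA itself is a thin scikit-learn wrapper.

## Synthetic data: what it emulates, and what not

The generators plant known truth at the study's own values wherever the
study states one: genome repeat lengths 188.4 (wild type) and 195.3 bp
(mutant); state-conditioned repeat lengths 192.6/192.2/182.0 (wild
type) and 206.0/201.0/184.0 bp (mutant) for BLACK/BLUE/YELLOW; a
492-reporter library with state composition 197/102/94/70/12/17 and
per-state median effects −1.83/−1.45/−0.39/−0.70/−0.97 (GRAY uses the
library-wide −1.24 as a stand-in, since no per-state GRAY median is
reported); two reporter replicates; six RNA-seq replicates per
genotype and stage.

**Nucleosome arrays.** Nucleosome k of a domain sits at
start + k·NRL + ε, ε ~ N(0, jitter_sd), independent per nucleosome
(phased-array model), present with probability `occupancy`
(default 0.85). Independent jitter keeps the planted NRL equal to the
mean spacing and makes recovery tolerances analyzable; a
cumulative-jitter mode exists for liquid-like arrays. Each domain is its
own phase; phases break at domain boundaries. Fragments are truncated
normal in length (default mean 165, sd 20, bounds 121/199 bp), centred
exactly on their dyad — there is no MNase positional or sequence bias,
no GC bias, no read errors. Genome-scale simulation draws fragments
uniformly over dyads and drops chromosome-end overhangs (clipping would
displace centres off the dyad comb). Domain annotations tile each
chromosome with exponential-length domains whose states are drawn
proportionally to remaining target coverage, keeping realised per-state
fractions within a few domain lengths of target.

**Reporter libraries.** Each reporter draws a state, a baseline log₂
expression from the state's normal (defaults: active states high,
inactive low, sd 1), and a tethering effect
state-effect + slope·(log₂expr − state mean), so the planted per-state
median equals the state effect while expression dependence is present
(default slope +0.3 log₂FC per log₂ expression: repression attenuates
with expression). Counts are negative binomial (overdispersion 0.05)
with lognormal per-library depth; 2% of reporters are zeroed in one
condition to exercise the filter. The emitted library totals are
depth-calibrated nominal sizes rather than barcode column sums:
fold-changes are identifiable only up to a library-composition
constant, and calibrated totals pin that constant so planted medians
are recoverable as absolute values. With raw column-sum totals a
uniform planted effect would, by construction, be measured as exactly
zero.

**Count matrices.** Gene baselines are lognormal (median 100, log-sd
1.2 — deeply sequenced single-embryo libraries), counts negative
binomial (dispersion 0.05) with lognormal sample depths (log-sd 0.15)
so size-factor normalisation is exercised. Genes below the 25th
expression percentile ("low expression", mirroring the
quartile-restricted derepression signature) in BLACK/BLUE receive
+0.5/+0.4 log₂ in the mutant. Two known, accepted biases shape
recovery: the +0.5 pseudocount attenuates fold-changes of very low
genes, and median-of-ratios factors absorb part of any asymmetric
planted effect (fold-changes are identified only up to the
normalisation constant), so a planted +0.5 is measured as ≈ +0.45;
uniform planted effects are therefore best recovered as contrasts
between affected and unaffected gene groups, and one test does exactly
that.

Because the generators contain none of the biases of real chromatin
(MNase preference, mappability, barcode PCR jackpots, maternal
transcript decay), passing recovery tests demonstrates correctness of
the estimators under the stated generative model, not robustness to
real-data artifacts.

## Problem sizes and determinism

Simulation scales were chosen so recovery is sharp but runs stay light:
genome-wide NRL on 10 Mb with 2×10⁶ fragments per replicate;
state-conditioned NRL on 6 Mb (three equal states, 100 kb mean domain
length) with 1.2×10⁶ fragments; amplitude-versus-jitter on 1 Mb with
1.3×10⁵ fragments; reporter recovery at 5,000 reporters (medians) and
492 (slope sign, 100 seeded libraries); stratification at 5,000 genes,
20 seeded runs. Every stochastic routine takes one explicit integer
seed and uses a local `numpy` Generator; identical seeds give
bit-identical outputs, and no global random state is touched.

## Known limitations

* Integer-lag peaks quantise NRL estimates to 0.2 bp steps.
* The ratio-based RNA-seq log₂FC is not a GLM estimate; shrinkage-based
  values from count models will differ for low-count genes.
* The first-two-peaks rule needs a profile whose first two maxima are
  genuine; heavily damped profiles (very irregular chromatin) may
  require smoothing or fail with "insufficient periodicity" rather than
  return a misleading estimate.
* Gene assignment ties and the high/low cutoff procedure are exact to
  this package's declared rules; other tools' nearest/valley
  conventions may differ at boundary cases.
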