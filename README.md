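# nucspacing

Nucleosome-array regularity from MNase-seq dyad autocorrelation, with
chromatin-state-conditioned repeat-length estimation, TRIP-style
barcoded-reporter repression analysis, and expression stratification of
RNA-seq fold-changes — plus a synthetic-data generator with known ground
truth for every analysis.

## The scientific problem

ISWI-family remodelers such as CHRAC/ACF slide nucleosomes into evenly
spaced arrays. Losing that spacing activity leaves chromatin irregular and
derepresses genes — but only in particular chromatin contexts: inactive
(BLACK) and Polycomb (BLUE) domains of the *Drosophila* five-state
chromatin model, and preferentially at lowly expressed genes. Testing this
requires three quantitative readouts:

1. **Array regularity and spacing** from MNase-seq. Mononucleosomal
   fragments (length > 120 and < 200 bp) are resized to 50 bp windows at
   their centres, giving a per-base dyad-density vector *x*. Its
   autocorrelation

   *r*(*k*) = Σₜ (*x*ₜ − μ)(*x*ₜ₊ₖ − μ) / Σₜ (*x*ₜ − μ)², 0 ≤ *k* ≤ 1000 bp,

   oscillates with lag *k* when arrays are regular; the amplitude measures
   regularity and the peak positions measure spacing. The **nucleosome
   repeat length (NRL)** is the slope of the zero-intercept regression of
   the first two peak lags (*p*₁, *p*₂) on peak index:
   NRL = (*p*₁ + 2 *p*₂)/5. State-conditioned profiles use head-to-tail
   concatenation of the coverage over a state's domains; biological
   replicates are summarised as mean ± SEM.

2. **Context-dependent repression** from a barcoded reporter library
   (TRIP): normalized expression per condition is
   (cDNA/cDNA-total)/(gDNA/gDNA-total) averaged over replicates;
   reporters with a zero normalized count in any condition are discarded;
   log₂ fold-changes versus control are stratified by integration state
   and regressed on mean log₂ expression.

3. **Expression stratification** of mutant-versus-wild-type RNA-seq:
   genes with zero counts in at least half the samples are dropped,
   counts are normalized by median-of-ratios size factors, per-gene
   log₂FC = log₂((mutant mean + 0.5)/(wt mean + 0.5)) is stratified by
   chromatin state and expression quartile, with loess trends and
   histone-mark (marked/unmarked) classification.

The package is aimed at chromatin biologists and computational
genomicists who want these estimators as tested, composable functions
rather than one-off scripts.

## Worked example

Simulate three replicate MNase-seq experiments over a 2 Mb genome with a
planted repeat length of 188.4 bp and 15 bp positional jitter, then run
the full estimation pipeline:

```python
import pandas as pd
import nucspacing as ns
from nucspacing import synthetic as syn, regularity as reg

chrom_sizes = {"chr2L": 2_000_000}
domains = pd.DataFrame([("chr2L", 0, 2_000_000, "GRAY")],
                       columns=["chrom", "start", "end", "state"])
values = []
for seed in (1, 2, 3):
    frags = syn.simulate_mnase_experiment(
        chrom_sizes, domains, {}, jitter_sd=15,
        n_fragments=400_000, seed=seed, default_nrl=188.4)
    frags = ns.filter_fragments_by_length(frags)
    coverage = ns.fragments_to_dyad_coverage(frags, chrom_sizes)
    est = reg.estimate_nrl_from_vector(coverage["chr2L"])
    values.append(est.nrl)
    print(f"replicate {seed}: peaks ({est.peak1}, {est.peak2}) bp "
          f"-> NRL {est.nrl:.1f} bp")
mean, sem = reg.aggregate_replicates(values)
print(f"NRL = {mean:.1f} +/- {sem:.1f} bp (n = 3)")
```

```
replicate 1: peaks (189, 377) bp -> NRL 188.6 bp
replicate 2: peaks (188, 377) bp -> NRL 188.4 bp
replicate 3: peaks (189, 377) bp -> NRL 188.6 bp
NRL = 188.5 +/- 0.1 bp (n = 3)
```

The first and second autocorrelation peaks sit at one and two repeat
lengths; the zero-intercept regression recovers the planted 188.4 bp
spacing to within rounding of the integer lag grid.

A 492-reporter tethering library with the default planted per-state
effects, analysed end to end:

```python
from nucspacing import tethering as trip

library = syn.simulate_reporter_library(n=492, seed=4)
kept = trip.filter_reporters(trip.normalize_reporter_counts(library))
fc = trip.reporter_log2fc(kept, "tethered", "control")
print(trip.median_fc_by_state(fc, kept["state"]).round(2))
```

```
        median    n
state
BLACK    -1.87  174
BLUE     -1.42   93
GRAY     -1.45   16
GREEN    -0.72   14
RED      -0.84   83
YELLOW   -0.35  102
```

Reporters in inactive BLACK/BLUE chromatin are strongly repressed;
reporters in active YELLOW chromatin barely respond — the
context-dependence signature, with medians near the planted per-state
effects (the small GREEN/GRAY groups are noisy at this library size).

A CLI mirrors the main stages
(`nucspacing simulate|dyads|acf|nrl|trip|stratify`); run
`nucspacing --help` for details.

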