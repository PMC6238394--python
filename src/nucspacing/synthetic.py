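"""Synthetic inputs with known ground truth.

Generators for every input the analysis consumes: phased nucleosome
arrays with state-specific repeat length and positional jitter,
MNase-like fragments with truncated-normal lengths, five-state domain
annotations, barcoded (TRIP-style) reporter count tables with
state-specific and expression-dependent repression, and
negative-binomial gene count matrices with replicate structure.

Planted parameters are the study's own where they are stated: a
wild-type genome repeat length of 188.4 bp (mutant 195.3; BLACK 206.0,
BLUE 201.0, YELLOW 184.0 in the mutant), a 492-reporter library with the
observed per-state composition and median log2 fold-changes
(BLACK −1.83, BLUE −1.45, YELLOW −0.39, RED −0.70, GREEN −0.97), two
reporter replicates and six RNA-seq replicates per genotype and stage.
Distributional choices the study does not state (fragment-length model,
count depths, overdispersion) are configurable stand-ins.

Jitter is independent per nucleosome (phased-array model) by default, so
the planted repeat length equals the mean spacing; a cumulative-jitter
mode is available. Every generator takes one explicit integer seed; no
global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import CHROMATIN_STATES, FRAGMENT_COLUMNS, GenomicInterval
from .domains import DOMAIN_COLUMNS

# Repeat lengths measured by the autocorrelation analysis on the real
# embryo nucleosome maps; used as planted ground truth.
WT_GENOME_NRL = 188.4
MUTANT_GENOME_NRL = 195.3
WT_STATE_NRL = {"BLACK": 192.6, "BLUE": 192.2, "YELLOW": 182.0}
MUTANT_STATE_NRL = {"BLACK": 206.0, "BLUE": 201.0, "YELLOW": 184.0}

#: Reporter-library composition observed in the Kc167 TRIP library
#: (N = 492: BLACK 197, BLUE 102, YELLOW 94, RED 70, GREEN 12, GRAY 17).
REPORTER_STATE_PROPORTIONS = {
    "BLACK": 197 / 492, "BLUE": 102 / 492, "YELLOW": 94 / 492,
    "RED": 70 / 492, "GREEN": 12 / 492, "GRAY": 17 / 492,
}

#: Median log2 fold-changes upon tethering, by integration state. The
#: GRAY value is a stand-in (the library-wide median); the per-state
#: GRAY median is not reported.
REPORTER_STATE_EFFECTS = {
    "BLACK": -1.83, "BLUE": -1.45, "YELLOW": -0.39,
    "RED": -0.70, "GREEN": -0.97, "GRAY": -1.24,
}


@dataclass(frozen=True)
class ArraySpec:
    """A phased nucleosome array on one interval.

    nrl is the target centre-to-centre spacing (> 146 bp, the nucleosome
    footprint), jitter_sd the per-nucleosome positional noise, occupancy
    the probability each nucleosome is present.
    """

    interval: GenomicInterval
    nrl: float
    jitter_sd: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.nrl <= 146:
            raise ValueError(f"nrl must exceed 146 bp, got {self.nrl}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy must be in [0, 1]")


@dataclass(frozen=True)
class FragmentLengthModel:
    """Truncated-normal MNase fragment-length distribution."""

    mean: float = 165.0
    sd: float = 20.0
    min: int = 121
    max: int = 199

    def __post_init__(self) -> None:
        if self.min >= self.max:
            raise ValueError("min must be < max")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, int(round(self.mean)))
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        vals = truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                             size=n, random_state=rng)
        return np.clip(np.rint(vals).astype(int), self.min, self.max)


@dataclass(frozen=True)
class ReporterEffectModel:
    """Per-state reporter expression and repression model.

    baseline_mean/baseline_sd give each state's log2 normalized
    expression distribution; effects are per-state median log2
    fold-changes upon tethering; expression_slope adds
    ``slope * (log2 expression - state mean)`` to the effect, planting an
    expression dependence without moving the state median; overdispersion
    is the negative-binomial alpha (variance = m + alpha * m^2).
    """

    baseline_mean: dict = field(default_factory=lambda: {
        "YELLOW": 3.0, "RED": 2.5, "GREEN": 1.0,
        "GRAY": 2.0, "BLUE": 1.0, "BLACK": 0.5,
    })
    baseline_sd: float = 1.0
    effects: dict = field(
        default_factory=lambda: dict(REPORTER_STATE_EFFECTS))
    expression_slope: float = 0.3
    overdispersion: float = 0.05

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       alpha: float) -> np.ndarray:
    """NB draws with variance mean + alpha * mean^2 (Poisson at alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha == 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_dyad_positions(
    spec: ArraySpec, seed: int, cumulative_jitter: bool = False
) -> np.ndarray:
    """Dyad (nucleosome-centre) positions of one phased array.

    Nucleosome k sits at ``start + k * nrl + eps_k`` with
    ``eps_k ~ Normal(0, jitter_sd)`` (independent per nucleosome; with
    ``cumulative_jitter`` the noise accumulates along the array), is
    retained with probability ``occupancy``, and is clipped to the
    interval. Returns sorted integer positions.
    """
    iv = spec.interval
    length = len(iv)
    if length < spec.nrl:
        raise ValueError(
            f"interval too short: {length} bp < one repeat ({spec.nrl} bp)"
        )
    rng = np.random.default_rng(seed)
    k = np.arange(int(np.ceil(length / spec.nrl)))
    grid = iv.start + k * spec.nrl
    grid = grid[grid < iv.end]
    if spec.jitter_sd > 0:
        eps = rng.normal(0.0, spec.jitter_sd, size=grid.size)
        if cumulative_jitter:
            eps = np.cumsum(eps)
        pos = grid + eps
    else:
        pos = grid.astype(float)
    if spec.occupancy < 1:
        pos = pos[rng.random(pos.size) < spec.occupancy]
    pos = np.clip(np.rint(pos).astype(np.int64), iv.start, iv.end - 1)
    return np.sort(pos)


def simulate_fragments(
    dyads: np.ndarray,
    model: FragmentLengthModel,
    depth: int,
    seed: int,
    chrom: str = "chr2L",
) -> pd.DataFrame:
    """``depth`` MNase-like fragments per dyad, centred on their dyad.

    Fragment centre ``floor((start + end)/2)`` equals the source dyad
    exactly; lengths come from the truncated normal. Output is sorted by
    (chrom, start). An empty dyad list yields an empty table.
    """
    if depth <= 0:
        raise ValueError(f"depth must be > 0, got {depth}")
    dyads = np.asarray(dyads, dtype=np.int64)
    rng = np.random.default_rng(seed)
    centers = np.repeat(dyads, depth)
    lengths = model.draw(centers.size, rng)
    starts = centers - lengths // 2
    frags = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + lengths}
    )
    return frags.sort_values(["chrom", "start"],
                             kind="stable").reset_index(drop=True)


def simulate_domain_annotation(
    chrom_sizes: dict[str, int],
    state_fractions: dict[str, float],
    mean_domain_len: float,
    seed: int,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping state domains.

    Domain lengths are exponential with the given mean; states are drawn
    with probability proportional to each state's remaining target
    coverage (fraction × chromosome length), which keeps realised
    per-state coverage within a few domain lengths of target. The
    residual fraction is emitted as GRAY; fractions summing above 1 are
    rejected. Adjacent same-state domains are merged.
    """
    bad = set(state_fractions) - set(CHROMATIN_STATES)
    if bad:
        raise ValueError(f"unknown chromatin state(s): {sorted(bad)}")
    total = float(sum(state_fractions.values()))
    if total > 1 + 1e-9:
        raise ValueError(f"state fractions sum to {total} > 1")
    rng = np.random.default_rng(seed)
    fractions = dict(state_fractions)
    gray = 1.0 - total
    if "GRAY" not in fractions and gray > 1e-9:
        fractions["GRAY"] = gray
    states = list(fractions)
    rows = []
    for chrom, size in chrom_sizes.items():
        remaining = np.array([fractions[s] * size for s in states])
        pos = 0
        while pos < size:
            length = max(int(round(rng.exponential(mean_domain_len))), 200)
            length = min(length, size - pos)
            weights = np.clip(remaining, 0.0, None)
            if weights.sum() == 0:
                weights = np.array(
                    [fractions[s] * size for s in states], dtype=float)
            i = rng.choice(len(states), p=weights / weights.sum())
            rows.append((chrom, pos, pos + length, states[i]))
            remaining[i] -= length
            pos += length
    domains = pd.DataFrame(rows, columns=DOMAIN_COLUMNS)
    return _merge_adjacent(domains)


def _merge_adjacent(domains: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for row in domains.itertuples(index=False):
        if (rows and rows[-1][0] == row.chrom and rows[-1][3] == row.state
                and rows[-1][2] == row.start):
            rows[-1][2] = row.end
        else:
            rows.append([row.chrom, row.start, row.end, row.state])
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def simulate_mnase_experiment(
    chrom_sizes: dict[str, int],
    domains: pd.DataFrame,
    nrl_by_state: dict[str, float],
    jitter_sd: float,
    n_fragments: int,
    model: FragmentLengthModel | None = None,
    occupancy: float = 0.85,
    seed: int = 0,
    default_nrl: float = WT_GENOME_NRL,
) -> pd.DataFrame:
    """One replicate of an MNase-seq experiment over an annotated genome.

    Each domain carries its own phased array at the state's repeat length
    (``default_nrl`` for states not listed); ``n_fragments`` fragments are
    drawn uniformly over all dyads. Returns a sorted fragment table.
    """
    if model is None:
        model = FragmentLengthModel()
    rng = np.random.default_rng(seed)
    dyads_by_chrom: dict[str, list[np.ndarray]] = {}
    for i, row in enumerate(domains.itertuples(index=False)):
        nrl = nrl_by_state.get(row.state, default_nrl)
        spec = ArraySpec(
            GenomicInterval(row.chrom, row.start, row.end),
            nrl=nrl, jitter_sd=jitter_sd, occupancy=occupancy,
        )
        if len(spec.interval) < nrl:
            continue
        sub_seed = int(rng.integers(2**31))
        dyads_by_chrom.setdefault(row.chrom, []).append(
            simulate_dyad_positions(spec, seed=sub_seed))
    frames = []
    all_dyads = [
        (chrom, np.concatenate(parts))
        for chrom, parts in dyads_by_chrom.items()
    ]
    total = sum(d.size for _, d in all_dyads)
    for chrom, dyads in all_dyads:
        n_chrom = int(round(n_fragments * dyads.size / total))
        centers = rng.choice(dyads, size=n_chrom, replace=True)
        lengths = model.draw(n_chrom, rng)
        starts = centers - lengths // 2
        ends = starts + lengths
        size = chrom_sizes[chrom]
        # drop chromosome-end overhangs: clipping would displace the
        # fragment centre off its source dyad
        keep = (starts >= 0) & (ends <= size)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "start": starts[keep], "end": ends[keep]}))
    frags = pd.concat(frames, ignore_index=True)[FRAGMENT_COLUMNS]
    return frags.sort_values(["chrom", "start"],
                             kind="stable").reset_index(drop=True)


def simulate_reporter_library(
    n: int = 492,
    state_proportions: dict[str, float] | None = None,
    effects: ReporterEffectModel | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    conditions: tuple[str, str] = ("control", "tethered"),
    zero_fraction: float = 0.02,
    gdna_mean: float = 200.0,
    cdna_scale: float = 100.0,
    depth_log_sd: float = 0.1,
) -> pd.DataFrame:
    """Raw gDNA/cDNA counts for a barcoded reporter library.

    Each reporter gets an integration state, a baseline log2 expression
    from the state's distribution, and (second condition only) a log2
    effect of ``effects.effects[state] + expression_slope * (log2expr -
    state mean)``, so the planted per-state median log2FC equals the
    state effect. Counts are negative binomial with a lognormal
    per-library sequencing-depth factor. The emitted cdna_total /
    gdna_total columns are the depth-calibrated nominal library sizes
    (depth factor × a fixed constant), not the barcode column sums:
    fold-changes are only identifiable up to a library-composition
    constant, and calibrated totals pin that constant so the planted
    per-state medians are recoverable as absolute values. A
    ``zero_fraction`` of reporters is zeroed in one random condition to
    exercise the zero filter.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    props = state_proportions or REPORTER_STATE_PROPORTIONS
    psum = float(sum(props.values()))
    if abs(psum - 1.0) > 1e-8:
        raise ValueError(f"state proportions sum to {psum}, expected 1")
    model = effects or ReporterEffectModel()
    rng = np.random.default_rng(seed)
    states = rng.choice(list(props), size=n, p=list(props.values()))
    mu = np.array([model.baseline_mean.get(s, 1.0) for s in states])
    log2expr = rng.normal(mu, model.baseline_sd)
    effect = np.array([model.effects.get(s, 0.0) for s in states])
    effect = effect + model.expression_slope * (log2expr - mu)
    expr = {conditions[0]: 2.0 ** log2expr,
            conditions[1]: 2.0 ** (log2expr + effect)}
    barcodes = np.array([f"bc{i:05d}" for i in range(n)])
    n_zero = int(round(zero_fraction * n))
    zero_idx = rng.choice(n, size=n_zero, replace=False)
    zero_cond = rng.choice(len(conditions), size=n_zero)
    cdna_nominal = n * cdna_scale
    gdna_nominal = n * gdna_mean
    rows = []
    for ci, cond in enumerate(conditions):
        cdna_mean = cdna_scale * expr[cond]
        for rep in range(1, n_replicates + 1):
            depth = rng.lognormal(0.0, depth_log_sd)
            gdna = _negative_binomial(
                rng, np.full(n, gdna_mean * depth), model.overdispersion)
            cdna = _negative_binomial(
                rng, cdna_mean * depth, model.overdispersion)
            cdna[zero_idx[zero_cond == ci]] = 0
            rows.append(pd.DataFrame({
                "barcode": barcodes, "state": states,
                "condition": cond, "replicate": rep,
                "cdna_count": cdna, "gdna_count": gdna,
                "cdna_total": int(round(cdna_nominal * depth)),
                "gdna_total": int(round(gdna_nominal * depth)),
            }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class ExpressionSimulation:
    """Synthetic RNA-seq counts with per-gene ground truth."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_info: pd.DataFrame


def simulate_expression_counts(
    n_genes: int = 5000,
    domain_assignment=None,
    baseline_mean: float = 100.0,
    baseline_log_sd: float = 1.2,
    dispersion: float = 0.05,
    derepression: dict[str, float] | None = None,
    low_expression_quantile: float = 0.25,
    n_replicates: int = 6,
    stage: str = "post-ZGA",
    depth_log_sd: float = 0.15,
    seed: int = 0,
) -> ExpressionSimulation:
    """Negative-binomial gene counts for wild-type and mutant embryos.

    ``domain_assignment`` is either a per-gene state sequence or a
    state → proportion dict (defaults to a genome-like mix). Genes whose
    baseline mean lies below the ``low_expression_quantile`` of the
    baseline distribution (default: the bottom expression quartile,
    mirroring the quartile-restricted derepression signature) receive
    the state's ``derepression`` log2 effect in the mutant (default:
    BLACK +0.5, BLUE +0.4, others 0 — derepression of lowly expressed
    genes in inactive chromatin). Baseline counts emulate deeply
    sequenced single-embryo libraries (lognormal around 100). Samples
    get lognormal depth factors so size-factor normalisation is
    exercised.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if dispersion <= 0:
        raise ValueError("non-positive dispersion")
    rng = np.random.default_rng(seed)
    if domain_assignment is None:
        domain_assignment = {"BLACK": 0.30, "BLUE": 0.12, "YELLOW": 0.25,
                             "RED": 0.15, "GREEN": 0.08, "GRAY": 0.10}
    if isinstance(domain_assignment, dict):
        states = rng.choice(
            list(domain_assignment), size=n_genes,
            p=np.asarray(list(domain_assignment.values()))
            / sum(domain_assignment.values()),
        )
    else:
        states = np.asarray(domain_assignment)
        if states.size != n_genes:
            raise ValueError("domain_assignment length != n_genes")
    if derepression is None:
        derepression = {"BLACK": 0.5, "BLUE": 0.4}
    base = rng.lognormal(np.log(baseline_mean), baseline_log_sd,
                         size=n_genes)
    low = base < np.quantile(base, low_expression_quantile)
    effect = np.where(
        low, [derepression.get(s, 0.0) for s in states], 0.0)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    counts = {}
    meta_rows = []
    for geno, fold in (("wt", np.ones(n_genes)), ("mutant", 2.0 ** effect)):
        for rep in range(1, n_replicates + 1):
            sample = f"{geno}_{rep}"
            depth = rng.lognormal(0.0, depth_log_sd)
            counts[sample] = _negative_binomial(
                rng, base * fold * depth, dispersion)
            meta_rows.append((sample, geno, stage, rep))
    counts_df = pd.DataFrame(counts, index=genes)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "genotype", "stage", "replicate"]
    ).set_index("sample")
    gene_info = pd.DataFrame(
        {"state": states, "base_mean": base, "low_expression": low,
         "effect_log2": effect}, index=genes,
    )
    return ExpressionSimulation(counts=counts_df, meta=meta,
                                gene_info=gene_info)
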