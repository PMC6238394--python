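"""Expression stratification of mutant-versus-wild-type fold-changes.

Single-embryo RNA-seq count matrices (genes × samples, with genotype /
stage / replicate metadata) are filtered, normalised by median-of-ratios
size factors, summarised as per-gene log2 fold-changes (normalized-mean
ratio with a 0.5 pseudocount — deliberately a ratio summary, not a
negative-binomial GLM), and stratified by chromatin state, expression
quartile, or marked/unmarked status. A tricube local-linear (loess) trend
supports MA-plot visualisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

LOG2FC_PSEUDOCOUNT = 0.5


def read_counts(path) -> pd.DataFrame:
    """Genes × samples TSV with a header of sample ids, gene ids in col 1."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample, genotype, stage, replicate."""
    meta = pd.read_csv(path, sep="\t")
    for col in ("sample", "genotype", "stage"):
        if col not in meta.columns:
            raise ValueError(f"sample metadata missing column {col!r}")
    return meta.set_index("sample")


def filter_genes_by_zero_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with a zero count in at least half of the samples."""
    n = counts.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    zeros = (counts == 0).sum(axis=1)
    return counts.loc[zeros < n / 2].copy()


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For genes with nonzero counts in every sample, each count is divided
    by the gene's geometric mean across samples; a sample's factor is the
    median of those ratios.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene with nonzero counts in all samples; cannot compute "
            "size factors"
        )
    sub = mat[allpos]
    log_geo = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


def normalize_counts(counts: pd.DataFrame,
                     size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(counts)
    return counts / size_factors


def log2fc_by_genotype(
    normalized: pd.DataFrame,
    meta: pd.DataFrame,
    stage: str,
    mutant: str = "mutant",
    wildtype: str = "wt",
    eps: float = LOG2FC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene log2FC (mutant vs wild type) and mean expression at a stage.

    log2fc = log2((mean normalized mutant + eps) / (mean normalized wt +
    eps)); mean_expression is the across-sample mean of normalized counts
    over both genotypes at the stage. Requires >= 2 replicates per
    genotype.
    """
    at_stage = meta[meta["stage"] == stage]
    groups = {}
    for name, geno in (("mut", mutant), ("wt", wildtype)):
        samples = at_stage.index[at_stage["genotype"] == geno]
        samples = [s for s in samples if s in normalized.columns]
        if len(samples) < 2:
            raise ValueError(
                f"need >= 2 replicates for genotype {geno!r} at stage "
                f"{stage!r}, found {len(samples)}"
            )
        groups[name] = normalized[samples]
    mut_mean = groups["mut"].mean(axis=1)
    wt_mean = groups["wt"].mean(axis=1)
    log2fc = np.log2((mut_mean + eps) / (wt_mean + eps))
    all_samples = pd.concat([groups["mut"], groups["wt"]], axis=1)
    return pd.DataFrame({
        "log2fc": log2fc,
        "mean_expression": all_samples.mean(axis=1),
    })


def _summarize(df: pd.DataFrame, by: str) -> pd.DataFrame:
    out = df.groupby(by, observed=True)["log2fc"].agg(
        n="size", median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
    )
    out["n"] = out["n"].astype(int)
    return out


def stratify_by_state(log2fc: pd.Series, states: pd.Series) -> pd.DataFrame:
    """Per-chromatin-state summary (n, median, quartiles) of log2FC."""
    df = pd.DataFrame({"log2fc": log2fc, "state": states}).dropna()
    return _summarize(df, "state")


def stratify_by_quartile(log2fc: pd.Series,
                         mean_expression: pd.Series) -> pd.DataFrame:
    """log2FC summaries per expression quartile (Q1 lowest).

    Genes are split at the 25/50/75th percentiles of mean expression
    (linear-interpolation percentiles); genes exactly on a boundary go to
    the lower quartile.
    """
    df = pd.DataFrame(
        {"log2fc": log2fc, "expr": mean_expression}
    ).dropna()
    if len(df) < 4:
        raise ValueError("need at least 4 genes for quartile stratification")
    cuts = np.percentile(df["expr"], [25, 50, 75])
    # right=True puts boundary ties into the lower quartile
    idx = np.digitize(df["expr"], cuts, right=True)
    df["quartile"] = pd.Categorical(
        [f"Q{i + 1}" for i in idx], categories=["Q1", "Q2", "Q3", "Q4"]
    )
    return _summarize(df, "quartile")


def quartile_assignment(mean_expression: pd.Series) -> pd.Series:
    """Quartile label (Q1 lowest expression … Q4) per gene."""
    expr = pd.Series(mean_expression, dtype=float)
    cuts = np.percentile(expr, [25, 50, 75])
    idx = np.digitize(expr, cuts, right=True)
    return pd.Series([f"Q{i + 1}" for i in idx], index=expr.index)


def loess_trend(x, y, span: float = 0.75,
                grid_points: int = 100) -> pd.DataFrame:
    """Tricube-weighted local-linear (loess) trend on a regular grid.

    Fitted at ``grid_points`` points spanning the range of ``x``.
    Returns a frame with columns ``x`` and ``fitted``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a loess trend")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    grid = np.linspace(x.min(), x.max(), grid_points)
    fitted = lowess(y, x, frac=span, it=0, xvals=grid)
    return pd.DataFrame({"x": grid, "fitted": fitted})


def select_variance_window_genes(
    counts: pd.DataFrame, lower_pct: float = 85.0, upper_pct: float = 99.0
) -> pd.Index:
    """Genes whose across-sample variance lies in the (85th, 99th] window.

    Percentiles use linear interpolation; genes strictly above the lower
    and at/below the upper percentile are kept.
    """
    if counts.shape[0] < 100:
        raise ValueError("need at least 100 genes")
    var = counts.var(axis=1, ddof=1)
    lo, hi = np.percentile(var, [lower_pct, upper_pct])
    if lo == hi:
        raise ValueError("degenerate variance distribution")
    return counts.index[(var > lo) & (var <= hi)]


def pca_on_selected_genes(counts: pd.DataFrame, n_components: int = 2):
    """Thin convenience: PCA of samples on variance-window genes.

    Returns a samples × components frame of scores (log2(count+1) input).
    """
    from sklearn.decomposition import PCA

    genes = select_variance_window_genes(counts)
    mat = np.log2(counts.loc[genes].to_numpy(dtype=float).T + 1.0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(mat)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=counts.columns, columns=cols)
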