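"""Barcoded-reporter (TRIP) repression analysis.

Hundreds of barcoded reporters integrated across the genome are read out
by barcode counting in cDNA (expression) and gDNA (copy number) under a
tethering condition versus a control. Per condition, normalized expression
is the double ratio

    (cDNA count / cDNA library total) / (gDNA count / gDNA library total)

averaged over the condition's replicates on the linear scale. Reporters
with a zero normalized count in at least one condition are discarded;
log2 fold-changes versus control are then always defined without
pseudocounts. Repression context is summarised by per-chromatin-state
medians and by ordinary-least-squares fits of log2FC against mean log2
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

REPORTER_COLUMNS = [
    "barcode", "state", "condition", "replicate",
    "cdna_count", "gdna_count",
]


@dataclass
class RegressionFit:
    """OLS fit of log2 fold-change against mean log2 expression."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def read_reporter_counts(path) -> pd.DataFrame:
    """Read the long-form reporter count TSV.

    Expected columns: barcode, state, condition, replicate, cdna_count,
    gdna_count and optionally cdna_total / gdna_total (computed per
    condition × replicate when absent).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REPORTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reporter table missing column(s): {missing}")
    return df


def normalize_reporter_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Normalized expression per reporter × condition.

    Within each condition × replicate library, each reporter's cDNA and
    gDNA counts are divided by the library totals (columns cdna_total /
    gdna_total when present, otherwise the column sums); the cDNA fraction
    over the gDNA fraction is the replicate's normalized expression, and
    replicates are averaged on the linear scale. Reporters with zero gDNA
    in a replicate are unmeasurable there and contribute 0.

    Returns a reporters × conditions frame (index barcode); a "state"
    column is carried through when present.
    """
    df = records.copy()
    group = ["condition", "replicate"]
    if "cdna_total" not in df.columns:
        df["cdna_total"] = df.groupby(group)["cdna_count"].transform("sum")
    if "gdna_total" not in df.columns:
        df["gdna_total"] = df.groupby(group)["gdna_count"].transform("sum")
    if (df["cdna_total"] <= 0).any() or (df["gdna_total"] <= 0).any():
        raise ValueError("zero library total in at least one replicate")
    cdna_frac = df["cdna_count"] / df["cdna_total"]
    gdna_frac = df["gdna_count"] / df["gdna_total"]
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(gdna_frac > 0, cdna_frac / gdna_frac, 0.0)
    df["normalized"] = norm
    wide = (
        df.groupby(["barcode", "condition"])["normalized"]
        .mean()
        .unstack("condition")
    )
    if "state" in df.columns:
        state = df.groupby("barcode")["state"].first()
        wide.insert(0, "state", state)
    return wide


def _condition_columns(norm: pd.DataFrame) -> list[str]:
    return [c for c in norm.columns if c != "state"]


def filter_reporters(norm: pd.DataFrame) -> pd.DataFrame:
    """Discard reporters with normalized expression 0 in any condition."""
    conds = _condition_columns(norm)
    keep = (norm[conds] > 0).all(axis=1)
    return norm.loc[keep].copy()


def reporter_log2fc(norm: pd.DataFrame, condition: str,
                    control: str) -> pd.Series:
    """Per-reporter log2(condition / control) of normalized expression."""
    for col in (condition, control):
        if col not in norm.columns:
            raise ValueError(f"condition {col!r} not in normalized table")
        if (norm[col] <= 0).any():
            raise ValueError(
                "zero normalized expression present: apply "
                "filter_reporters before computing fold-changes"
            )
    return np.log2(norm[condition] / norm[control]).rename("log2fc")


def mean_log2_expression(norm: pd.DataFrame,
                         conditions: list[str] | None = None) -> pd.Series:
    """log2 of the across-condition mean normalized expression."""
    conds = conditions if conditions is not None else _condition_columns(norm)
    return np.log2(norm[conds].mean(axis=1)).rename("mean_log2_expression")


def fit_fc_vs_expression(log2fc: pd.Series,
                         mean_log2_expr: pd.Series) -> RegressionFit:
    """OLS of log2FC on mean log2 expression with a slope t-test.

    The p-value is the two-sided t-test on the slope coefficient.
    """
    y = np.asarray(log2fc, dtype=float)
    x = np.asarray(mean_log2_expr, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 reporters to fit a regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in expression predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(y.size),
    )


def compare_slopes(data_a: pd.DataFrame, data_b: pd.DataFrame) -> float:
    """p-value for a slope difference between two log2FC-vs-expression fits.

    Both inputs need columns ``x`` (mean log2 expression) and ``y``
    (log2FC). A pooled OLS with a group indicator and group × expression
    interaction is fitted; the two-sided t-test p-value on the interaction
    coefficient is returned.
    """
    frames = []
    for g, d in ((0.0, data_a), (1.0, data_b)):
        frames.append(pd.DataFrame(
            {"x": d["x"].to_numpy(dtype=float),
             "y": d["y"].to_numpy(dtype=float), "g": g}))
    pooled = pd.concat(frames, ignore_index=True)
    design = pd.DataFrame({
        "const": 1.0,
        "x": pooled["x"],
        "g": pooled["g"],
        "x_g": pooled["x"] * pooled["g"],
    })
    model = sm.OLS(pooled["y"], design).fit()
    return float(model.pvalues["x_g"])


def median_fc_by_state(log2fc: pd.Series, states: pd.Series) -> pd.DataFrame:
    """Median log2FC and reporter count per chromatin state.

    States with no reporters are omitted. Returns a frame indexed by
    state with columns ``median`` and ``n``.
    """
    df = pd.DataFrame({"log2fc": log2fc, "state": states}).dropna()
    out = df.groupby("state")["log2fc"].agg(median="median", n="size")
    out["n"] = out["n"].astype(int)
    return out
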