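"""Five-state chromatin-domain handling.

The Drosophila genome is segmented into five chromatin states — BLACK
(inactive), BLUE (Polycomb), GREEN (HP1 heterochromatin), RED and YELLOW
(active) — plus GRAY for the unannotated complement. This module reads the
domain annotation, assigns genes to their nearest domain, averages
histone-modification signal over genes and classifies genes into high/low
mark levels via the local minimum of a bimodal kernel density.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core import CHROMATIN_STATES, HISTONE_MARKS

logger = logging.getLogger(__name__)

DOMAIN_COLUMNS = ["chrom", "start", "end", "state"]


def read_domain_bed(path, chrom_sizes: dict[str, int] | None = None,
                    add_gray: bool = False) -> pd.DataFrame:
    """Read a BED4 domain annotation (state name in column 4).

    Unknown state names are rejected; same-chromosome overlaps raise an
    error naming the first offending pair. With ``add_gray=True`` (needs
    ``chrom_sizes``) the unannotated complement is appended as GRAY.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=DOMAIN_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int,
                            "state": str})
    bad = set(df["state"]) - set(CHROMATIN_STATES)
    if bad:
        raise ValueError(f"unknown chromatin state(s): {sorted(bad)}")
    domains = validate_domains(df)
    if add_gray:
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to synthesize GRAY")
        domains = add_gray_complement(domains, chrom_sizes)
    return domains


def validate_domains(domains: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start) and reject same-chromosome overlaps."""
    if (domains["end"] <= domains["start"]).any():
        raise ValueError("domain with end <= start")
    domains = domains.sort_values(["chrom", "start"],
                                  kind="stable").reset_index(drop=True)
    for chrom, grp in domains.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        overlap = np.flatnonzero(starts[1:] < ends[:-1])
        if len(overlap):
            i = overlap[0]
            raise ValueError(
                f"overlapping domains on {chrom}: "
                f"[{starts[i]}, {ends[i]}) and [{starts[i+1]}, {ends[i+1]})"
            )
    return domains


def add_gray_complement(domains: pd.DataFrame,
                        chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Append GRAY intervals covering every unannotated base."""
    rows = []
    for chrom, size in chrom_sizes.items():
        grp = domains[domains["chrom"] == chrom]
        pos = 0
        for row in grp.sort_values("start").itertuples(index=False):
            if row.start > pos:
                rows.append((chrom, pos, row.start, "GRAY"))
            pos = max(pos, row.end)
        if pos < size:
            rows.append((chrom, pos, size, "GRAY"))
    gray = pd.DataFrame(rows, columns=DOMAIN_COLUMNS)
    out = pd.concat([domains[domains["state"] != "GRAY"], gray],
                    ignore_index=True)
    return out.sort_values(["chrom", "start"],
                           kind="stable").reset_index(drop=True)


def assign_genes_to_domains(genes: pd.DataFrame,
                            domains: pd.DataFrame) -> pd.Series:
    """Assign each gene the state of its nearest chromatin domain.

    Nearest means minimal gap between the gene body and the domain
    (0 when they touch or overlap). A gene overlapping several states gets
    the state with the largest overlap length; remaining ties go to the
    domain with the smaller start coordinate. Genes on chromosomes absent
    from the annotation are assigned GRAY with a logged warning.

    Returns a Series of states indexed like ``genes``.
    """
    if not len(genes) or not len(domains):
        raise ValueError("genes and domains must both be non-empty")
    states = pd.Series(index=genes.index, dtype=object)
    by_chrom = {c: g.sort_values("start") for c, g in
                domains.groupby("chrom", sort=False)}
    missing = 0
    for chrom, grp in genes.groupby("chrom", sort=False):
        dom = by_chrom.get(chrom)
        if dom is None:
            states.loc[grp.index] = "GRAY"
            missing += len(grp)
            continue
        ds = dom["start"].to_numpy()
        de = dom["end"].to_numpy()
        dstate = dom["state"].to_numpy()
        for idx, gs, ge in zip(grp.index, grp["start"].to_numpy(),
                               grp["end"].to_numpy()):
            overlap = np.minimum(ge, de) - np.maximum(gs, ds)
            if overlap.max() > 0:
                best = overlap.max()
                cand = np.flatnonzero(overlap == best)
            else:
                gap = np.maximum(-overlap, 0)
                cand = np.flatnonzero(gap == gap.min())
            if len(cand) > 1:  # tie: smaller domain start wins
                cand = cand[np.argsort(ds[cand], kind="stable")]
            states.loc[idx] = dstate[cand[0]]
    if missing:
        logger.warning(
            "%d gene(s) on chromosomes absent from the domain annotation; "
            "assigned GRAY", missing,
        )
    return states


def average_mark_over_genes(signal: pd.DataFrame,
                            genes: pd.DataFrame) -> pd.Series:
    """Length-weighted mean of a windowed signal over each gene body.

    ``signal`` is a (chrom, start, end, value) table of non-overlapping
    windows (per-base signal is the 1 bp special case). Genes with no
    covered base get NaN.
    """
    out = pd.Series(np.nan, index=genes.index, dtype=float)
    by_chrom = {c: g.sort_values("start") for c, g in
                signal.groupby("chrom", sort=False)}
    for chrom, grp in genes.groupby("chrom", sort=False):
        sig = by_chrom.get(chrom)
        if sig is None:
            continue
        ss = sig["start"].to_numpy()
        se = sig["end"].to_numpy()
        sv = sig["value"].to_numpy(dtype=float)
        for idx, gs, ge in zip(grp.index, grp["start"].to_numpy(),
                               grp["end"].to_numpy()):
            ov = np.minimum(ge, se) - np.maximum(gs, ss)
            w = np.clip(ov, 0, None)
            total = w.sum()
            if total > 0:
                out.loc[idx] = float((w * sv).sum() / total)
    return out


def bimodal_cutoff(reference_values, grid_points: int = 512) -> float:
    """Cutoff at the deepest density minimum between the two largest modes.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a ``grid_points``
    grid spanning the data range ± 3 bandwidths; the abscissa of the
    deepest interior local minimum between the two highest local maxima is
    returned. Raises ValueError ("no bimodality detected") for unimodal
    densities.
    """
    vals = np.asarray(reference_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 50:
        raise ValueError(
            f"need >= 50 non-missing reference values, got {vals.size}"
        )
    kde = gaussian_kde(vals, bw_method="silverman")
    bw = kde.factor * vals.std(ddof=1)
    grid = np.linspace(vals.min() - 3 * bw, vals.max() + 3 * bw, grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    is_max = (dens[interior] > dens[interior - 1]) & \
             (dens[interior] >= dens[interior + 1])
    maxima = interior[is_max]
    if len(maxima) < 2:
        raise ValueError("no bimodality detected in reference density")
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    seg = np.arange(lo + 1, hi)
    is_min = (dens[seg] < dens[seg - 1]) & (dens[seg] <= dens[seg + 1])
    minima = seg[is_min]
    if not len(minima):
        raise ValueError("no bimodality detected in reference density")
    deepest = minima[np.argmin(dens[minima])]
    return float(grid[deepest])


def classify_high_low(values, reference_values=None) -> tuple[pd.Series, float]:
    """Label per-gene mark levels high/low by a density-valley cutoff.

    The cutoff comes from ``reference_values`` (defaults to ``values``
    itself, the per-mark mode; passing the H3K36me3 levels reproduces the
    single-reference variant). Values strictly above the cutoff are
    labelled "high".
    """
    values = pd.Series(values, dtype=float)
    ref = values if reference_values is None else reference_values
    cutoff = bimodal_cutoff(ref)
    labels = pd.Series(
        np.where(values > cutoff, "high", "low"), index=values.index
    )
    labels[values.isna()] = np.nan
    return labels, cutoff


def classify_marked(labels: pd.DataFrame,
                    marks=HISTONE_MARKS) -> pd.Series:
    """Genes are marked iff their level is high in all four histone marks.

    ``labels`` is a genes × marks frame of "high"/"low". Genes missing a
    label are excluded (logged).
    """
    missing_cols = [m for m in marks if m not in labels.columns]
    if missing_cols:
        raise ValueError(f"missing mark label column(s): {missing_cols}")
    sub = labels[list(marks)]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        logger.warning("%d gene(s) excluded for missing mark labels",
                       int((~complete).sum()))
    marked = (sub[complete] == "high").all(axis=1)
    return marked.map({True: "marked", False: "unmarked"})
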