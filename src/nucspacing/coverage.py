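"""Dyad-density coverage from paired-end MNase-seq fragments.

Mononucleosome-sized templates (121–199 bp by default, i.e. length > 120 and
< 200) are resized to a fixed 50 bp window centred on the fragment midpoint;
stacking those windows per base yields the dyad-density vector that the
regularity analysis autocorrelates.

The fragment centre is ``floor((start + end) / 2)``; for even-length
fragments this picks the left-of-centre base. The resized window is
``[c - 25, c + 25)``, clipped at chromosome bounds.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .core import FRAGMENT_COLUMNS, empty_fragments, validate_fragments

logger = logging.getLogger(__name__)

#: Inclusive size-selection bounds for mononucleosomal templates
#: (length > 120 and < 200 bp).
MIN_FRAGMENT_LENGTH = 121
MAX_FRAGMENT_LENGTH = 199

#: Width of the dyad window each fragment is resized to.
DYAD_WINDOW = 50


def read_fragments(path, format: str | None = None) -> pd.DataFrame:
    """Read paired-end fragments from BED or BAM/SAM into a fragment table.

    Parameters
    ----------
    path
        Input file. BED needs at least chrom/start/end columns; BAM/SAM
        templates are reconstructed from properly paired forward mates.
    format
        "bed" or "bam"; inferred from the file extension when omitted
        (".bam"/".sam" -> bam, anything else -> bed).

    Returns
    -------
    DataFrame with columns chrom, start, end sorted by (chrom, start).
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "bam" if ext in {".bam", ".sam", ".cram"} else "bed"
    if format == "bed":
        frags = _read_bed(path)
    elif format == "bam":
        frags = _read_bam(path)
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    frags = frags.sort_values(["chrom", "start"], kind="stable")
    return frags.reset_index(drop=True)


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: "
                    f"expected >= 3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: {exc}"
                ) from None
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: end ({end}) <= start ({start})"
                )
            rows.append((fields[0], start, end))
    if not rows:
        return empty_fragments()
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def _read_bam(path) -> pd.DataFrame:
    import pysam

    rows = []
    skipped = 0
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired or not read.is_proper_pair:
                skipped += 1
                continue
            # count each template once, from the leftmost (tlen > 0) mate
            if read.template_length <= 0:
                continue
            start = read.reference_start
            rows.append((read.reference_name, start,
                         start + read.template_length))
    if skipped:
        logger.warning("skipped %d unpaired/improper records", skipped)
    if not rows:
        return empty_fragments()
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def filter_fragments_by_length(
    fragments: pd.DataFrame,
    min_length: int = MIN_FRAGMENT_LENGTH,
    max_length: int = MAX_FRAGMENT_LENGTH,
) -> pd.DataFrame:
    """Size-select fragments with min_length <= length <= max_length.

    The defaults implement the mononucleosome selection of fragments longer
    than 120 and shorter than 200 bp. Order is preserved; the operation is
    idempotent.
    """
    if not len(fragments):
        return fragments.copy()
    length = fragments["end"] - fragments["start"]
    keep = (length >= min_length) & (length <= max_length)
    return fragments.loc[keep].copy()


def fragments_to_dyad_coverage(
    fragments: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window: int = DYAD_WINDOW,
) -> dict[str, np.ndarray]:
    """Accumulate per-base dyad density from fragment-centre windows.

    Each fragment contributes +1 over the ``window`` bp interval
    ``[c - window//2, c + window - window//2)`` around its centre
    ``c = floor((start + end)/2)``, clipped at chromosome bounds.

    Returns a dict mapping chromosome name to an int64 vector of the
    chromosome's length.
    """
    validate_fragments(fragments)
    coverage = {
        chrom: np.zeros(size, dtype=np.int64)
        for chrom, size in chrom_sizes.items()
    }
    if not len(fragments):
        return coverage
    unknown = set(fragments["chrom"].unique()) - set(chrom_sizes)
    if unknown:
        raise ValueError(
            "fragments on chromosomes absent from chrom_sizes: "
            + ", ".join(sorted(unknown))
        )
    half = window // 2
    for chrom, grp in fragments.groupby("chrom", sort=False):
        size = chrom_sizes[chrom]
        centers = (grp["start"].to_numpy() + grp["end"].to_numpy()) // 2
        lo = np.clip(centers - half, 0, size)
        hi = np.clip(centers + (window - half), 0, size)
        # difference-array accumulation: O(n_fragments + chrom length)
        diff = np.zeros(size + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        coverage[chrom] += np.cumsum(diff[:-1])
    return coverage


def write_coverage(
    coverage: dict[str, np.ndarray], path, format: str | None = None
) -> None:
    """Write per-base coverage as bedGraph or bigWig (by extension).

    bedGraph merges runs of equal value and omits zero runs, so a
    write/read round trip reproduces the vectors exactly.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "bigwig" if ext in {".bw", ".bigwig"} else "bedgraph"
    if format == "bedgraph":
        _write_bedgraph(coverage, path)
    elif format == "bigwig":
        _write_bigwig(coverage, path)
    else:
        raise ValueError(f"unknown coverage format {format!r}")


def _value_runs(values: np.ndarray):
    """Yield (start, end, value) runs of constant value, zeros skipped."""
    if not len(values):
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    for s, e in zip(starts, ends):
        v = values[s]
        if v != 0:
            yield int(s), int(e), v


def _write_bedgraph(coverage, path) -> None:
    with open(path, "w") as fh:
        for chrom in coverage:
            for s, e, v in _value_runs(np.asarray(coverage[chrom])):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _write_bigwig(coverage, path) -> None:
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(c, len(v)) for c, v in coverage.items()])
        for chrom, values in coverage.items():
            runs = list(_value_runs(np.asarray(values)))
            if not runs:
                continue
            bw.addEntries(
                [chrom] * len(runs),
                [s for s, _, _ in runs],
                ends=[e for _, e, _ in runs],
                values=[float(v) for _, _, v in runs],
            )
    finally:
        bw.close()


def read_coverage(
    path, chrom_sizes: dict[str, int] | None = None, format: str | None = None
) -> dict[str, np.ndarray]:
    """Read coverage written by :func:`write_coverage` back into vectors.

    bedGraph requires ``chrom_sizes`` (zero runs are implicit); bigWig
    carries its own chromosome sizes.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = "bigwig" if ext in {".bw", ".bigwig"} else "bedgraph"
    if format == "bedgraph":
        if chrom_sizes is None:
            raise ValueError("chrom_sizes required to read bedGraph")
        coverage = {
            chrom: np.zeros(size) for chrom, size in chrom_sizes.items()
        }
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "value"],
        )
        for row in df.itertuples(index=False):
            coverage[row.chrom][row.start:row.end] = row.value
        return coverage
    import pyBigWig

    bw = pyBigWig.open(str(path))
    try:
        out = {}
        for chrom, size in bw.chroms().items():
            vals = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, size), dtype=float)
            )
            out[chrom] = vals
        return out
    finally:
        bw.close()
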