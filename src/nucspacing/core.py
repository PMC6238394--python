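"""Shared genomic primitives.

All coordinates are 0-based, half-open (BED convention), declared here once
and used everywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Column order for fragment tables throughout the package.
FRAGMENT_COLUMNS = ["chrom", "start", "end"]

#: The five chromatin states of the Drosophila five-state model plus GRAY,
#: the complement of the annotated states.
CHROMATIN_STATES = ("BLACK", "BLUE", "YELLOW", "RED", "GREEN", "GRAY")

#: The four histone marks used for the marked/unmarked gene classification.
HISTONE_MARKS = ("H3K27me3", "H3K36me3", "H3K9me3", "H3K4me3")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file into a dict."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "length"],
        dtype={"chrom": str, "length": int},
    )
    if (df["length"] <= 0).any():
        bad = df.loc[df["length"] <= 0, "chrom"].iloc[0]
        raise ValueError(f"non-positive length for chromosome {bad!r}")
    return dict(zip(df["chrom"], df["length"]))


def write_chrom_sizes(chrom_sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def empty_fragments() -> pd.DataFrame:
    """An empty fragment table with the canonical columns."""
    return pd.DataFrame(
        {"chrom": pd.Series(dtype=str),
         "start": pd.Series(dtype=int),
         "end": pd.Series(dtype=int)}
    )


def validate_fragments(fragments: pd.DataFrame) -> pd.DataFrame:
    """Check fragment-table invariants (start < end, non-negative)."""
    for col in FRAGMENT_COLUMNS:
        if col not in fragments.columns:
            raise ValueError(f"fragment table missing column {col!r}")
    if len(fragments):
        if (fragments["start"] < 0).any():
            raise ValueError("fragment with negative start")
        if (fragments["end"] <= fragments["start"]).any():
            idx = fragments.index[fragments["end"] <= fragments["start"]][0]
            raise ValueError(f"fragment at row {idx} has end <= start")
    return fragments
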