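"""Core domain types and tabular plumbing shared by all pipeline stages.

Dual-label nucleotide-recoding RNA-seq pools an s4U-labelled sample and an
s6G-labelled sample in one library; each read then carries two independent
mutation channels: T-to-C mismatches report s4U content and G-to-A mismatches
report s6G content.  This module defines the per-read tally record, the
grouped count table consumed by the mixture model (reads grouped by gene,
sample, mutation channel and mutations-per-read), the sample design sheet
(forward / reverse / unlabelled label combinations), raw per-gene mutation
rate summaries, and the TSV readers/writers for all of them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationType",
    "Combination",
    "SampleDesign",
    "ReadTally",
    "TALLY_COLUMNS",
    "COUNT_COLUMNS",
    "aggregate_reads",
    "filter_low_coverage",
    "raw_mutation_rates",
    "tallies_to_frame",
    "read_tallies",
    "write_tallies",
    "read_count_table",
    "write_count_table",
    "read_sample_sheet",
    "write_sample_sheet",
]


class MutationType(str, enum.Enum):
    """The two recoding mutation channels.

    TC observes U sites (reference T): s4U incorporation recodes to give
    T-to-C mismatches.  GA observes G sites: s6G gives G-to-A mismatches.
    """

    TC = "TC"
    GA = "GA"

    @property
    def site_column(self) -> str:
        return "n_U" if self is MutationType.TC else "n_G"

    @property
    def count_column(self) -> str:
        return "y_TC" if self is MutationType.TC else "y_GA"


class Combination(str, enum.Enum):
    """Label combination of one sample.

    ``forward``: experimental condition fed s4U, control fed s6G — so the
    T-to-C channel reads out the experimental labelled fraction and G-to-A
    the control fraction.  ``reverse`` swaps the labels.  ``unlabelled``
    received neither analogue and pins down background mutation rates.
    """

    FORWARD = "forward"
    REVERSE = "reverse"
    UNLABELLED = "unlabelled"


#: channel -> condition routing for each labelled combination
_ROUTING = {
    Combination.FORWARD: {MutationType.TC: "experimental", MutationType.GA: "control"},
    Combination.REVERSE: {MutationType.TC: "control", MutationType.GA: "experimental"},
    Combination.UNLABELLED: {},
}


@dataclass(frozen=True)
class SampleDesign:
    """One sample's role in the experimental design."""

    sample_id: str
    combination: Combination
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "combination", Combination(self.combination))
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def labelled_indicator(self) -> int:
        """Likelihood indicator I_s: 0 for unlabelled controls, else 1."""
        return 0 if self.combination is Combination.UNLABELLED else 1

    def condition_for(self, mutation_type: MutationType) -> str | None:
        """Condition ('experimental'/'control') read out by a channel; None if unlabelled."""
        return _ROUTING[self.combination].get(MutationType(mutation_type))


@dataclass(frozen=True)
class ReadTally:
    """Mutation content of a single aligned read, in transcript-strand space."""

    read_id: str
    sample_id: str
    gene_id: str
    feature_class: str  # exonic | intronic | ambiguous
    n_U: int
    n_G: int
    y_TC: int
    y_GA: int

    def __post_init__(self) -> None:
        if not (0 <= self.y_TC <= self.n_U):
            raise ValueError(
                f"read {self.read_id}: y_TC={self.y_TC} outside [0, n_U={self.n_U}]"
            )
        if not (0 <= self.y_GA <= self.n_G):
            raise ValueError(
                f"read {self.read_id}: y_GA={self.y_GA} outside [0, n_G={self.n_G}]"
            )


TALLY_COLUMNS = [
    "read_id",
    "sample_id",
    "gene_id",
    "feature_class",
    "n_U",
    "n_G",
    "y_TC",
    "y_GA",
]

COUNT_COLUMNS = ["gene_id", "sample_id", "mutation_type", "n_mut", "n_reads", "mean_bases"]

RATE_COLUMNS = [
    "gene_id",
    "sample_id",
    "feature_class",
    "rate_TC",
    "rate_GA",
    "n_reads",
]


def tallies_to_frame(tallies: Iterable[ReadTally]) -> pd.DataFrame:
    """Stack ReadTally records into the canonical tally DataFrame."""
    rows = [
        (t.read_id, t.sample_id, t.gene_id, t.feature_class, t.n_U, t.n_G, t.y_TC, t.y_GA)
        for t in tallies
    ]
    return pd.DataFrame(rows, columns=TALLY_COLUMNS)


def _validate_tallies(tallies: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TALLY_COLUMNS if c not in tallies.columns]
    if missing:
        raise ValueError(f"tally table missing columns: {missing}")
    bad = (tallies["y_TC"] > tallies["n_U"]) | (tallies["y_GA"] > tallies["n_G"])
    neg = (tallies[["n_U", "n_G", "y_TC", "y_GA"]] < 0).any(axis=1)
    if bool((bad | neg).any()):
        ids = tallies.loc[bad | neg, "read_id"].head(5).tolist()
        raise ValueError(f"malformed tallies (y > n or negative counts), e.g. reads {ids}")
    return tallies


def aggregate_reads(tallies: pd.DataFrame | Iterable[ReadTally]) -> pd.DataFrame:
    """Group reads into (gene, sample, mutation channel, mutations-per-read) counts.

    Every read contributes one increment per channel: one row-count for its
    T-to-C mutation count and one for its G-to-A count, so each channel's
    group counts sum to the number of input reads.  The mean covered-base
    count of the group (mean n_U or n_G) is retained as metadata.

    Reads with an ambiguous or missing gene assignment must be removed
    upstream; they are rejected here.
    """
    if not isinstance(tallies, pd.DataFrame):
        tallies = tallies_to_frame(tallies)
    tallies = _validate_tallies(tallies)
    ambiguous = tallies["feature_class"].isin(["ambiguous"]) | tallies["gene_id"].isin(
        ["", "ambiguous", "none"]
    )
    if bool(ambiguous.any()):
        raise ValueError(
            f"{int(ambiguous.sum())} tallies lack a unique gene assignment; "
            "drop ambiguous reads before aggregating"
        )
    parts = []
    for mt in MutationType:
        grouped = (
            tallies.groupby(["gene_id", "sample_id", mt.count_column], sort=False)
            .agg(n_reads=("read_id", "size"), mean_bases=(mt.site_column, "mean"))
            .reset_index()
            .rename(columns={mt.count_column: "n_mut"})
        )
        grouped.insert(2, "mutation_type", mt.value)
        parts.append(grouped)
    table = pd.concat(parts, ignore_index=True)[COUNT_COLUMNS]
    return table.sort_values(
        ["gene_id", "sample_id", "mutation_type", "n_mut"], kind="mergesort"
    ).reset_index(drop=True)


def reads_per_gene_sample(table: pd.DataFrame) -> pd.DataFrame:
    """Total read count per (gene, sample) from a grouped count table.

    Both channels tally every read, so the per-channel totals agree; the
    maximum over channels guards partially-built tables.
    """
    per_channel = table.groupby(["gene_id", "sample_id", "mutation_type"], sort=False)[
        "n_reads"
    ].sum()
    return per_channel.groupby(["gene_id", "sample_id"]).max().reset_index(name="n_reads")


def filter_low_coverage(
    table: pd.DataFrame, min_reads: int = 200, min_samples: int = 2
) -> pd.DataFrame:
    """Remove genes without >= ``min_reads`` reads in >= ``min_samples`` samples.

    The 200-read floor is the coverage threshold below which ratio estimates
    are unreliable; the boundary is inclusive (a gene with exactly 200 reads
    in two samples is kept).
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    if min_samples < 1:
        raise ValueError(f"min_samples must be >= 1, got {min_samples}")
    if table.empty:
        return table.copy()
    totals = reads_per_gene_sample(table)
    ok_samples = totals[totals["n_reads"] >= min_reads].groupby("gene_id").size()
    keep = set(ok_samples[ok_samples >= min_samples].index)
    return table[table["gene_id"].isin(keep)].reset_index(drop=True)


def raw_mutation_rates(
    tallies: pd.DataFrame | Iterable[ReadTally], min_reads: int = 200
) -> pd.DataFrame:
    """Per-(gene, sample, feature class) raw mutation rates.

    rate_TC = sum(y_TC) / sum(n_U) and rate_GA = sum(y_GA) / sum(n_G) over
    the group's reads — mutations per observed base, in [0, 1].  Only groups
    with strictly more than ``min_reads`` reads are reported; groups whose
    base denominator is zero are omitted rather than reported as 0/0.
    """
    if not isinstance(tallies, pd.DataFrame):
        tallies = tallies_to_frame(tallies)
    tallies = _validate_tallies(tallies)
    g = (
        tallies.groupby(["gene_id", "sample_id", "feature_class"], sort=False)
        .agg(
            sum_yTC=("y_TC", "sum"),
            sum_nU=("n_U", "sum"),
            sum_yGA=("y_GA", "sum"),
            sum_nG=("n_G", "sum"),
            n_reads=("read_id", "size"),
        )
        .reset_index()
    )
    g = g[(g["n_reads"] > min_reads) & (g["sum_nU"] > 0) & (g["sum_nG"] > 0)]
    out = g[["gene_id", "sample_id", "feature_class"]].copy()
    out["rate_TC"] = g["sum_yTC"] / g["sum_nU"]
    out["rate_GA"] = g["sum_yGA"] / g["sum_nG"]
    out["n_reads"] = g["n_reads"]
    return out.sort_values(["gene_id", "sample_id", "feature_class"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# TSV input/output.  All tables are plain tab-separated text with a header
# row and a deterministic sort so outputs are diffable.


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    table = table[COUNT_COLUMNS].sort_values(
        ["gene_id", "sample_id", "mutation_type", "n_mut"], kind="mergesort"
    )
    table.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "gene_id": str,
            "sample_id": str,
            "mutation_type": str,
            "n_mut": np.int64,
            "n_reads": np.int64,
            "mean_bases": float,
        },
    )
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table {path} missing columns: {missing}")
    bad = ~table["mutation_type"].isin([m.value for m in MutationType])
    if bool(bad.any()):
        raise ValueError(f"count table {path}: unknown mutation_type values "
                         f"{sorted(table.loc[bad, 'mutation_type'].unique())}")
    return table[COUNT_COLUMNS]


def write_tallies(tallies: pd.DataFrame, path: str | Path) -> None:
    tallies[TALLY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_tallies(path: str | Path) -> pd.DataFrame:
    tallies = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample_id": str, "gene_id": str})
    return _validate_tallies(tallies)


def write_sample_sheet(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        [(d.sample_id, d.combination.value, d.replicate) for d in design],
        columns=["sample_id", "combination", "replicate"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    needed = {"sample_id", "combination"}
    if not needed.issubset(sheet.columns):
        raise ValueError(f"sample sheet {path} must have columns {sorted(needed)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"sample sheet {path} has duplicate sample ids")
    reps = sheet["replicate"] if "replicate" in sheet.columns else [1] * len(sheet)
    return [
        SampleDesign(sample_id=s, combination=Combination(c), replicate=int(r))
        for s, c, r in zip(sheet["sample_id"], sheet["combination"], reps)
    ]
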