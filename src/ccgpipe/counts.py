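"""Count matrices and read tables.

A :class:`CountMatrix` is a genes x samples table of non-negative integers
(floats once normalized) plus light metadata: the assay it came from,
per-sample times for time courses, and size factors once computed.

Read positions travel as plain pandas DataFrames in BED6 layout
(chrom, start, end, name, score, strand; 0-based half-open) where the
``name`` column carries the sample label, so one BED file holds a whole
time course.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

_TIME_LABEL = re.compile(r"^t(\d+(?:\.\d+)?)$")


def time_label(hours: float) -> str:
    """Canonical sample label for a time point, e.g. ``t04`` for 4 h."""
    if float(hours).is_integer():
        return f"t{int(hours):02d}"
    return f"t{hours}"


def parse_time_labels(labels) -> np.ndarray | None:
    """Recover hours from ``t00``-style labels; None if any label differs."""
    out = []
    for lab in labels:
        m = _TIME_LABEL.match(str(lab))
        if not m:
            return None
        out.append(float(m.group(1)))
    return np.asarray(out, dtype=float)


@dataclass
class CountMatrix:
    data: pd.DataFrame
    assay: str = "rna"
    normalized: bool = False
    size_factors: pd.Series | None = None
    #: reads falling into each gene's overlap regions (same shape subset),
    #: filled by exonic counting when the annotation has overlapping genes
    overlap_counts: pd.DataFrame | None = None
    #: per-sample tally of reads not assigned to any gene
    unassigned: pd.Series | None = None

    def __post_init__(self) -> None:
        if (np.asarray(self.data) < 0).any():
            raise ValueError("counts must be non-negative")

    # ------------------------------------------------------------ properties

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def times(self) -> np.ndarray | None:
        return parse_time_labels(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    # ------------------------------------------------------------ operations

    def subset(self, gene_ids) -> "CountMatrix":
        return CountMatrix(
            self.data.loc[list(gene_ids)].copy(),
            assay=self.assay,
            normalized=self.normalized,
            size_factors=self.size_factors,
            overlap_counts=(
                None
                if self.overlap_counts is None
                else self.overlap_counts.reindex(list(gene_ids)).dropna(how="all")
            ),
            unassigned=self.unassigned,
        )

    def normalize(self, factors: pd.Series | None = None) -> "CountMatrix":
        """Divide each sample by its size factor (median-of-ratios)."""
        from .quantify import size_factors as _sf

        if self.normalized:
            raise ValueError("matrix already normalized")
        if factors is None:
            factors = _sf(self)
        out = self.data.div(factors, axis=1)
        return CountMatrix(
            out,
            assay=self.assay,
            normalized=True,
            size_factors=factors,
            overlap_counts=self.overlap_counts,
            unassigned=self.unassigned,
        )

    # ------------------------------------------------------------------- I/O

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, assay: str = "rna", normalized: bool = False) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, assay=assay, normalized=normalized)


def write_bed(reads: pd.DataFrame, path) -> None:
    reads.loc[:, BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS)
    return df


def reads_from_sam(path) -> pd.DataFrame:
    """Load aligned reads from SAM/BAM into the BED6 layout.

    The sample label is taken from the read-group ``ID`` when present,
    otherwise from the leading token of the query name before the first
    ``/``. Unmapped and secondary/supplementary records are skipped.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                sample = rec.get_tag("RG")
            except KeyError:
                sample = rec.query_name.split("/")[0]
            rows.append(
                (
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    sample,
                    0,
                    "-" if rec.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def five_prime_positions(reads: pd.DataFrame) -> pd.Series:
    """0-based position of each read's 5'-most aligned base."""
    minus = reads["strand"].to_numpy() == "-"
    pos = reads["start"].to_numpy().copy()
    pos[minus] = reads["end"].to_numpy()[minus] - 1
    return pd.Series(pos, index=reads.index)
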