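"""Gene models and GFF3 I/O.

Coordinates are stored 0-based half-open internally; GFF3 is written and
read as 1-based closed intervals at the I/O boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Exon:
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[Exon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty span for {self.gene_id}")
        for ex in self.exons:
            if ex.start < self.start or ex.end > self.end:
                raise ValueError(f"exon outside gene span in {self.gene_id}")
        if not self.exons:
            self.exons = [Exon(self.start, self.end)]

    @property
    def length(self) -> int:
        """Gene span length L_G in bp."""
        return self.end - self.start

    @property
    def exonic_length(self) -> int:
        return sum(ex.length for ex in self.exons)

    def terminal_window(self, window_bp: int = 500) -> tuple[int, int]:
        """Strand-aware window of ``window_bp`` ending at the 3' end.

        Truncated at the gene start for genes shorter than the window.
        """
        if window_bp <= 0:
            raise ValueError("window_bp must be positive")
        w = min(window_bp, self.length)
        if self.strand == "+":
            return self.end - w, self.end
        return self.start, self.start + w


@dataclass(frozen=True)
class OverlapRecord:
    gene_a: str
    gene_b: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneAnnotation:
    """A set of gene models on one or more chromosomes.

    Overlap records between gene spans are computed eagerly; they feed the
    influence-factor contamination filter downstream.
    """

    def __init__(self, genes: list[Gene], chrom_sizes: dict[str, int] | None = None):
        self.genes: dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
        if chrom_sizes is None:
            chrom_sizes = {}
            for g in genes:
                chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end + 1000)
        self.chrom_sizes = dict(chrom_sizes)
        self.overlaps: list[OverlapRecord] = self._compute_overlaps()

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def _compute_overlaps(self) -> list[OverlapRecord]:
        records = []
        by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes = sorted(genes, key=lambda g: (g.start, g.end))
            for a, b in itertools.combinations(genes, 2):
                if b.start >= a.end:
                    continue
                lo, hi = max(a.start, b.start), min(a.end, b.end)
                if hi > lo:
                    records.append(OverlapRecord(a.gene_id, b.gene_id, lo, hi))
        return records

    def overlap_intervals(self, gene_id: str) -> list[tuple[int, int]]:
        """Merged intervals where ``gene_id`` overlaps any neighbour."""
        ivals = sorted(
            (r.start, r.end)
            for r in self.overlaps
            if gene_id in (r.gene_a, r.gene_b)
        )
        merged: list[tuple[int, int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def overlap_length(self, gene_id: str) -> int:
        return sum(e - s for s, e in self.overlap_intervals(gene_id))

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path) -> None:
        lines = ["##gff-version 3"]
        for chrom in sorted(self.chrom_sizes):
            lines.append(f"##sequence-region {chrom} 1 {self.chrom_sizes[chrom]}")
        for g in self.genes.values():
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "ccgpipe",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
            )
            for i, ex in enumerate(g.exons, start=1):
                lines.append(
                    "\t".join(
                        [
                            g.chrom,
                            "ccgpipe",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
                        ]
                    )
                )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path) -> "GeneAnnotation":
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        chrom_sizes: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    _, chrom, _, size = line.split()
                    chrom_sizes[chrom] = int(size)
                elif not line.startswith("#"):
                    break
        genes = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            exons = [
                Exon(ex.start - 1, ex.end)
                for ex in db.children(feat, featuretype="exon", order_by="start")
            ]
            genes.append(
                Gene(
                    gene_id=feat.id,
                    chrom=feat.seqid,
                    strand=feat.strand,
                    start=feat.start - 1,
                    end=feat.end,
                    exons=exons,
                )
            )
        return cls(genes, chrom_sizes=chrom_sizes or None)


def merged_exon_union(annotation: GeneAnnotation, chrom: str) -> np.ndarray:
    """Merged exonic intervals on ``chrom`` as an (n, 2) array."""
    ivals = sorted(
        (ex.start, ex.end)
        for g in annotation
        if g.chrom == chrom
        for ex in g.exons
    )
    if not ivals:
        return np.empty((0, 2), dtype=np.int64)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)
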