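"""Read counting, contamination and expression filters, normalization.

Counting convention: a read is assigned to a feature when its 5'-most
aligned base falls inside the feature interval. Exonic counting is
unstranded; strand is only used to orient 3'-terminal windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneAnnotation, merged_exon_union
from .counts import CountMatrix, five_prime_positions


def _positions_by_chrom_sample(reads: pd.DataFrame):
    """{chrom: {sample: sorted 5' positions}} plus ordered sample list."""
    pos = five_prime_positions(reads).to_numpy()
    chroms = reads["chrom"].to_numpy()
    samples = reads["name"].astype(str).to_numpy()
    order = sorted(pd.unique(samples))
    index: dict[str, dict[str, np.ndarray]] = {}
    df = pd.DataFrame({"chrom": chroms, "sample": samples, "pos": pos})
    for (chrom, sample), grp in df.groupby(["chrom", "sample"], sort=True):
        index.setdefault(chrom, {})[sample] = np.sort(grp["pos"].to_numpy())
    return index, order


def _count_intervals(positions: np.ndarray, intervals) -> int:
    """Number of positions falling in a list of half-open intervals."""
    total = 0
    for s, e in intervals:
        total += int(
            np.searchsorted(positions, e, side="left")
            - np.searchsorted(positions, s, side="left")
        )
    return total


def count_exonic(reads: pd.DataFrame, annotation: GeneAnnotation) -> CountMatrix:
    """Count reads whose 5' base falls into annotated exons.

    A read inside exons of two overlapping genes increments both genes
    (contamination is handled by the influence-factor filter). Reads on
    chromosomes absent from the annotation, or outside every exon, are
    tallied per sample in ``CountMatrix.unassigned``.
    """
    index, samples = _positions_by_chrom_sample(reads)
    gene_ids = annotation.gene_ids
    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    ov_counts = np.zeros_like(counts)
    assigned_union = np.zeros(len(samples), dtype=np.int64)
    totals = np.zeros(len(samples), dtype=np.int64)

    for chrom, per_sample in index.items():
        union = merged_exon_union(annotation, chrom)
        for j, sample in enumerate(samples):
            p = per_sample.get(sample)
            if p is None:
                continue
            totals[j] += len(p)
            if len(union):
                assigned_union[j] += _count_intervals(p, union)

    for i, gid in enumerate(gene_ids):
        g = annotation[gid]
        per_sample = index.get(g.chrom, {})
        exons = [(ex.start, ex.end) for ex in g.exons]
        ovl = annotation.overlap_intervals(gid)
        for j, sample in enumerate(samples):
            p = per_sample.get(sample)
            if p is None:
                continue
            counts[i, j] = _count_intervals(p, exons)
            if ovl:
                ov_counts[i, j] = _count_intervals(p, ovl)

    data = pd.DataFrame(counts, index=gene_ids, columns=samples)
    return CountMatrix(
        data,
        assay="rna",
        overlap_counts=pd.DataFrame(ov_counts, index=gene_ids, columns=samples),
        unassigned=pd.Series(totals - assigned_union, index=samples),
    )


def count_terminal_window(
    reads: pd.DataFrame, annotation: GeneAnnotation, window_bp: int = 500
) -> CountMatrix:
    """Count reads in the strand-aware window ending at each gene's 3' end."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    index, samples = _positions_by_chrom_sample(reads)
    gene_ids = annotation.gene_ids
    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    ov_counts = np.zeros_like(counts)
    for i, gid in enumerate(gene_ids):
        g = annotation[gid]
        per_sample = index.get(g.chrom, {})
        win = g.terminal_window(window_bp)
        ws, we = win
        ovl = [
            (max(s, ws), min(e, we))
            for s, e in annotation.overlap_intervals(gid)
            if min(e, we) > max(s, ws)
        ]
        for j, sample in enumerate(samples):
            p = per_sample.get(sample)
            if p is None:
                continue
            counts[i, j] = _count_intervals(p, [win])
            if ovl:
                ov_counts[i, j] = _count_intervals(p, ovl)
    data = pd.DataFrame(counts, index=gene_ids, columns=samples)
    return CountMatrix(
        data,
        assay="rnapii",
        overlap_counts=pd.DataFrame(ov_counts, index=gene_ids, columns=samples),
    )


def influence_factor(G: float, L_G: float, O: float, L_O: float) -> float:
    """Contamination ratio of overall read density to non-overlap density.

    ``(G / L_G) / ((G - O) / (L_G - L_O))`` where G is the gene's read
    count, L_G its length, O the count in the region overlapping a
    neighbouring gene and L_O that region's length. Returns 1.0 for genes
    without overlap, +inf when every read sits in the overlap.
    """
    if L_O >= L_G or L_O < 0 or L_G <= 0:
        raise ValueError("need L_G > L_O >= 0")
    if O > G or O < 0:
        raise ValueError("need G >= O >= 0")
    if O == 0 and L_O == 0:
        return 1.0
    if G == 0:
        return 1.0
    if G == O:
        return float("inf")
    return (G / L_G) / ((G - O) / (L_G - L_O))


@dataclass
class FilterReport:
    """Which genes a filter removed and why."""

    removed: pd.DataFrame  # columns: gene_id, reason, statistic

    def to_tsv(self, path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)


def apply_influence_filter(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    threshold: float = 2.0,
) -> tuple[CountMatrix, FilterReport]:
    """Drop genes whose influence factor strictly exceeds ``threshold``.

    The factor is computed once per gene on counts summed over all samples
    of the assay; a factor of exactly ``threshold`` is retained. Overlap
    counts must have been recorded during counting; genes without overlap
    partners (or matrices lacking overlap data entirely, e.g. loaded from
    plain TSV) are always retained.
    """
    if counts.normalized:
        raise ValueError("apply the influence filter before normalization")
    keep, removed = [], []
    totals = counts.data.sum(axis=1)
    for gid in counts.gene_ids:
        g = annotation[gid]
        L_O = annotation.overlap_length(gid)
        if L_O == 0 or counts.overlap_counts is None:
            keep.append(gid)
            continue
        O = float(counts.overlap_counts.loc[gid].sum()) if gid in counts.overlap_counts.index else 0.0
        factor = influence_factor(float(totals.loc[gid]), g.length, O, L_O)
        if factor > threshold:
            removed.append((gid, "influence_factor", factor))
        else:
            keep.append(gid)
    report = FilterReport(
        pd.DataFrame(removed, columns=["gene_id", "reason", "statistic"])
    )
    return counts.subset(keep), report


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per gene the reference is the geometric mean across samples (genes
    with a zero in any sample are excluded); each sample's factor is the
    median over genes of count / reference.
    """
    X = counts.data.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two samples")
    positive = (X > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logX = np.log(X[positive])
    ref = logX.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logX - ref, axis=0))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def filter_low_expression(
    counts: CountMatrix, quantile: float = 0.20
) -> tuple[CountMatrix, FilterReport]:
    """Remove the lowest-``quantile`` fraction of genes by mean level.

    Requires normalized counts. Ties are broken by stable input order, so
    with all-equal means the first fraction in input order is removed.
    """
    if not counts.normalized:
        raise ValueError("filter_low_expression expects normalized counts")
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    n_remove = int(np.floor(quantile * len(counts) + 1e-9))
    means = counts.data.mean(axis=1).to_numpy()
    order = np.argsort(means, kind="stable")
    removed_idx = order[:n_remove]
    removed_ids = [counts.gene_ids[i] for i in removed_idx]
    keep = [gid for gid in counts.gene_ids if gid not in set(removed_ids)]
    report = FilterReport(
        pd.DataFrame(
            {
                "gene_id": removed_ids,
                "reason": "low_expression",
                "statistic": means[removed_idx],
            }
        )
    )
    return counts.subset(keep), report


def sample_background_windows(
    annotation: GeneAnnotation,
    n_windows: int,
    min_gene_distance: int,
    seed: int,
    window_bp: int = 500,
) -> list[tuple[str, int, int]]:
    """Seeded non-overlapping intergenic windows for background estimation.

    Candidate windows are tiled at ``window_bp`` stride inside every
    intergenic gap trimmed by ``min_gene_distance`` on both sides, then
    sampled without replacement.
    """
    candidates: list[tuple[str, int, int]] = []
    for chrom, size in sorted(annotation.chrom_sizes.items()):
        spans = sorted(
            (g.start, g.end) for g in annotation if g.chrom == chrom
        )
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps = []
        prev = 0
        for s, e in merged:
            gaps.append((prev, s))
            prev = e
        gaps.append((prev, size))
        for gs, ge in gaps:
            lo, hi = gs + min_gene_distance, ge - min_gene_distance
            for w in range(lo, hi - window_bp + 1, window_bp):
                candidates.append((chrom, w, w + window_bp))
    if len(candidates) < n_windows:
        raise ValueError(
            f"genome too small: {len(candidates)} candidate windows < {n_windows}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_windows, replace=False)
    return [candidates[i] for i in sorted(chosen)]


def chip_background_filter(
    counts: CountMatrix,
    reads: pd.DataFrame,
    annotation: GeneAnnotation,
    n_windows: int = 2000,
    min_gene_distance: int = 1000,
    seed: int = 0,
    window_bp: int = 500,
) -> tuple[CountMatrix, FilterReport, float]:
    """Drop genes whose terminal-window signal is below intergenic background.

    Background = per-window median count across samples over ``n_windows``
    random non-coding windows; the cutoff is the median over windows. A
    gene is removed when its median terminal-window count across time
    points is strictly below the cutoff.
    """
    windows = sample_background_windows(
        annotation, n_windows, min_gene_distance, seed, window_bp
    )
    index, samples = _positions_by_chrom_sample(reads)
    win_counts = np.zeros((len(windows), len(samples)), dtype=np.int64)
    for i, (chrom, s, e) in enumerate(windows):
        per_sample = index.get(chrom, {})
        for j, sample in enumerate(samples):
            p = per_sample.get(sample)
            if p is None:
                continue
            win_counts[i, j] = _count_intervals(p, [(s, e)])
    cutoff = float(np.median(np.median(win_counts, axis=1)))
    gene_medians = counts.data.median(axis=1)
    keep = [gid for gid in counts.gene_ids if gene_medians.loc[gid] >= cutoff]
    removed = [
        (gid, "chip_background", float(gene_medians.loc[gid]))
        for gid in counts.gene_ids
        if gene_medians.loc[gid] < cutoff
    ]
    report = FilterReport(
        pd.DataFrame(removed, columns=["gene_id", "reason", "statistic"])
    )
    return counts.subset(keep), report, cutoff
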