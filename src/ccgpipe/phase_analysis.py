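"""Integration of RNA and polymerase rhythm results.

Headline classifications: concordance groups (1 = in-phase rhythms with at
least one significant profile; 2 = significant transcription rhythm
without an in-phase significant RNA rhythm; 3 = significant RNA rhythm
without an in-phase significant transcription rhythm), the
robust-oscillator set (fold amplitude and FDR thresholds), overlap
summaries with hypergeometric enrichment, and cross-genotype phase-shift
tables.

Group precedence when several raw predicates hold: 1, then 2, then 3
(concordance first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rhythms import phase_difference, signed_phase_shift


def classify_groups(
    rna: pd.DataFrame,
    chip: pd.DataFrame,
    alpha: float = 0.05,
    in_phase_tol_hours: float = 3.0,
    period: float = 22.0,
) -> pd.DataFrame:
    """Assign concordance groups from per-assay rhythm tables.

    ``rna`` and ``chip`` are :func:`ccgpipe.rhythms.rhythm_analysis`
    tables (need columns ``p_min`` and ``phase``). Genes present in only
    one table are excluded. Returns one row per shared gene with the
    group, both p-values and phases, the circular phase difference and the
    in-phase flag; genes significant in neither assay get group 'none'.
    """
    shared = [g for g in rna.index if g in set(chip.index)]
    r = rna.loc[shared]
    c = chip.loc[shared]
    dphase = np.array(
        [
            phase_difference(pr, pc, period)
            if np.isfinite(pr) and np.isfinite(pc)
            else np.nan
            for pr, pc in zip(r["phase"], c["phase"])
        ]
    )
    rna_sig = r["p_min"].to_numpy() < alpha
    chip_sig = c["p_min"].to_numpy() < alpha
    in_phase = dphase <= in_phase_tol_hours  # NaN -> False
    group = np.full(len(shared), "none", dtype=object)
    group[(rna_sig | chip_sig) & in_phase] = "1"
    group[(group == "none") & chip_sig] = "2"
    group[(group == "none") & rna_sig] = "3"
    return pd.DataFrame(
        {
            "group": group,
            "rna_p": r["p_min"].to_numpy(),
            "chip_p": c["p_min"].to_numpy(),
            "rna_phase": r["phase"].to_numpy(),
            "chip_phase": c["phase"].to_numpy(),
            "phase_difference": dphase,
            "in_phase": in_phase,
            "both_significant": rna_sig & chip_sig,
        },
        index=pd.Index(shared, name="gene_id"),
    )


def group_sizes(assignments: pd.DataFrame) -> dict:
    """Summary counts, including the both-significant subset."""
    out = {f"group_{g}": int((assignments["group"] == g).sum()) for g in "123"}
    out["none"] = int((assignments["group"] == "none").sum())
    out["both_significant"] = int(assignments["both_significant"].sum())
    out["rhythmically_transcribed"] = out["group_1"] + out["group_2"]
    return out


def robust_oscillators(
    fits: pd.DataFrame,
    fdr: pd.Series,
    amp_threshold: float = 3.0,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """Genes with fold amplitude strictly above ``amp_threshold`` and FDR
    strictly below ``fdr_threshold``."""
    amp = fits["fold_amplitude"]
    f = fdr.reindex(fits.index)
    mask = (amp > amp_threshold) & (f < fdr_threshold)
    return list(fits.index[mask.fillna(False)])


@dataclass
class PhaseShiftTable:
    records: pd.DataFrame
    n_dropped: int  # rhythmic in A but not expressed in B

    @property
    def similar_fraction(self) -> float:
        n = len(self.records)
        return float((self.records["classification"] == "similar").sum() / n) if n else float("nan")


def compare_phase_between_conditions(
    fits_A: pd.DataFrame,
    fits_B: pd.DataFrame,
    rhythmic_A: list[str],
    rhythmic_calls_B: pd.Series | None = None,
    similar_tol_hours: float = 4.0,
    period: float = 22.0,
) -> PhaseShiftTable:
    """Phase-shift records for genes rhythmic in condition A.

    Genes absent from ``fits_B`` (not expressed in B) are dropped and
    counted. The signed circular shift is from A to B; a gene is
    'similar' when |shift| <= ``similar_tol_hours``. ``rhythmic_calls_B``
    optionally flags whether each gene's rhythm is itself significant in
    B (the blue/grey split).
    """
    rows = []
    n_dropped = 0
    b_index = set(fits_B.index)
    for gid in rhythmic_A:
        if gid not in b_index:
            n_dropped += 1
            continue
        pa = float(fits_A.loc[gid, "phase"])
        pb = float(fits_B.loc[gid, "phase"])
        shift = signed_phase_shift(pa, pb, period)
        rows.append(
            {
                "gene_id": gid,
                "phase_A": pa,
                "phase_B": pb,
                "shift": shift,
                "classification": (
                    "similar" if abs(shift) <= similar_tol_hours else "shifted"
                ),
                "rhythmic_in_B": (
                    bool(rhythmic_calls_B.get(gid, False))
                    if rhythmic_calls_B is not None
                    else None
                ),
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "phase_A",
            "phase_B",
            "shift",
            "classification",
            "rhythmic_in_B",
        ],
    ).set_index("gene_id")
    return PhaseShiftTable(records, n_dropped)


def phase_histogram(
    phases, period: float = 22.0, bin_hours: float = 2.0
) -> pd.DataFrame:
    """Tabular histogram / rose-plot export of phases in fixed-width bins."""
    edges = np.arange(0.0, period + 1e-9, bin_hours)
    if edges[-1] < period:
        edges = np.append(edges, period)
    ph = np.asarray(phases, dtype=float)
    ph = ph[np.isfinite(ph)] % period
    counts, _ = np.histogram(ph, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def overlap_summary(
    set_A,
    set_B,
    universe,
    phases_A=None,
    phases_B=None,
    period: float = 22.0,
) -> dict:
    """Venn counts plus hypergeometric enrichment of the overlap.

    The enrichment p is the upper tail P(X >= |A & B|) drawing |B| items
    from a universe with |A| marked.
    """
    A, B, U = set(set_A), set(set_B), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    inter = A & B
    p = float(stats.hypergeom.sf(len(inter) - 1, len(U), len(A), len(B)))
    out = {
        "n_A": len(A),
        "n_B": len(B),
        "n_intersection": len(inter),
        "n_A_only": len(A - B),
        "n_B_only": len(B - A),
        "n_universe": len(U),
        "hypergeom_p": p,
    }
    if phases_A is not None:
        out["phase_histogram_A"] = phase_histogram(phases_A, period).to_dict("list")
    if phases_B is not None:
        out["phase_histogram_B"] = phase_histogram(phases_B, period).to_dict("list")
    return out
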