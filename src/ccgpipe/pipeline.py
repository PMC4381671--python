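"""End-to-end orchestration: simulate -> count -> filter -> rhythms -> fdr
-> de -> phases, with one config, one master seed and a JSON manifest.

Every stage output is written as TSV/JSON under the output directory; the
manifest records parameters, seeds, per-stage row counts and a SHA-256 of
every artifact, so bit-reproducibility under a fixed seed can be checked
by comparing manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, fdr as fdr_mod, phase_analysis, quantify, synthetic_data
from .counts import CountMatrix, write_bed
from .rhythms import rhythm_analysis


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the reference protocol
    (500 bp terminal windows, influence threshold 2, lower 20% expression
    cut, 18-26 h detection, 22 h fixed-period fit, alpha 0.05)."""

    out_dir: str = "ccgpipe_out"
    seed: int = 0

    # simulation (used when no input paths are given)
    n_genes: int = 3000
    frac_rhythmic: float = 0.3
    frac_stable_transcript: float = 0.1
    frac_rna_only: float = 0.05
    n_overlap_pairs: int = 10
    emit_reads: bool = False
    write_reads: bool = False

    # inputs (optional; TSV count matrices switch off simulation)
    rna_counts: str | None = None
    chip_counts: str | None = None

    # quantify
    window_bp: int = 500
    influence_threshold: float = 2.0
    low_expr_quantile: float = 0.20
    n_background_windows: int = 50
    min_gene_distance: int = 1000

    # rhythms
    period_min: float = 18.0
    period_max: float = 26.0
    fit_period: float = 22.0
    alpha: float = 0.05

    # fdr
    n_shuffles: int = 50
    fdr_bins: int = 20

    # diffexpr
    run_de: bool = False
    n_replicates: int = 3
    frac_de: float = 0.1
    de_log2fc: float = 2.0

    # phases
    in_phase_tol_hours: float = 3.0
    similar_tol_hours: float = 4.0

    def validate(self) -> None:
        if not 0 <= self.low_expr_quantile < 1:
            raise ValueError("low_expr_quantile must be in [0, 1)")
        if self.period_min >= self.period_max:
            raise ValueError("period_min must be < period_max")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}, "files": {}}
    summary: dict = {}

    def log(stage, **info):
        manifest["stages"][stage] = info

    # ---------------------------------------------------------- stage: data
    sim_cfg = None
    truth = None
    if config.rna_counts and config.chip_counts:
        rna_cm = CountMatrix.from_tsv(config.rna_counts, assay="rna")
        chip_cm = CountMatrix.from_tsv(config.chip_counts, assay="rnapii")
        annotation = None
        chip_reads = None
        log("input", rna_genes=len(rna_cm), chip_genes=len(chip_cm))
    else:
        sim_cfg = synthetic_data.SimulationConfig(
            n_genes=config.n_genes,
            frac_rhythmic=config.frac_rhythmic,
            frac_stable_transcript=config.frac_stable_transcript,
            frac_rna_only=config.frac_rna_only,
            n_overlap_pairs=config.n_overlap_pairs,
            seed=config.seed,
        )
        annotation = synthetic_data.build_toy_annotation(sim_cfg)
        annotation.to_gff3(out / "annotation.gff3")
        truth = synthetic_data.build_truth(sim_cfg, annotation.gene_ids)
        synthetic_data.write_truth(truth, out / "truth.json")
        sim_cfg.to_json(out / "simulation_config.json")
        rna_sim = synthetic_data.simulate_timecourse(
            annotation, truth, sim_cfg, "rna", emit_reads=config.emit_reads
        )
        chip_sim = synthetic_data.simulate_timecourse(
            annotation, truth, sim_cfg, "rnapii", emit_reads=config.emit_reads
        )
        rna_cm, chip_cm = rna_sim.counts, chip_sim.counts
        if config.emit_reads and config.write_reads:
            write_bed(rna_sim.reads, out / "rna_reads.bed")
            write_bed(chip_sim.reads, out / "chip_reads.bed")
        log("simulate", n_genes=config.n_genes,
            rna_reads=0 if rna_sim.reads is None else len(rna_sim.reads),
            chip_reads=0 if chip_sim.reads is None else len(chip_sim.reads))
        chip_reads = chip_sim.reads
    rna_cm.to_tsv(out / "rna_counts_raw.tsv")
    chip_cm.to_tsv(out / "chip_counts_raw.tsv")

    # --------------------------------------------------------- stage: filter
    reports = []
    if annotation is not None:
        rna_cm, rep = quantify.apply_influence_filter(
            rna_cm, annotation, config.influence_threshold
        )
        reports.append(rep.removed)
        chip_cm, rep = quantify.apply_influence_filter(
            chip_cm, annotation, config.influence_threshold
        )
        reports.append(rep.removed)
        if config.emit_reads and chip_reads is not None:
            chip_cm, rep, cutoff = quantify.chip_background_filter(
                chip_cm, chip_reads, annotation,
                n_windows=config.n_background_windows,
                min_gene_distance=config.min_gene_distance,
                seed=config.seed,
                window_bp=config.window_bp,
            )
            reports.append(rep.removed)
            summary["chip_background_cutoff"] = cutoff
    rna_norm = rna_cm.normalize()
    chip_norm = chip_cm.normalize()
    rna_norm, rep = quantify.filter_low_expression(rna_norm, config.low_expr_quantile)
    reports.append(rep.removed)
    reports = [r for r in reports if len(r)]
    filter_report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["gene_id", "reason", "statistic"])
    )
    filter_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    rna_norm.to_tsv(out / "rna_counts_filtered.tsv")
    chip_norm.to_tsv(out / "chip_counts_filtered.tsv")
    log("filter", rna_genes=len(rna_norm), chip_genes=len(chip_norm),
        removed=len(filter_report))

    # -------------------------------------------------------- stage: rhythms
    period_range = (config.period_min, config.period_max)
    rna_rhy = rhythm_analysis(
        rna_norm, period_range, config.fit_period, config.alpha
    )
    chip_rhy = rhythm_analysis(
        chip_norm, period_range, config.fit_period, config.alpha
    )
    rna_rhy.to_csv(out / "rna_rhythms.tsv", sep="\t")
    chip_rhy.to_csv(out / "chip_rhythms.tsv", sep="\t")
    summary["n_rhythmic_rna"] = int(rna_rhy["rhythmic"].sum())
    summary["n_rhythmic_chip"] = int(chip_rhy["rhythmic"].sum())
    log("rhythms", rna_rhythmic=summary["n_rhythmic_rna"],
        chip_rhythmic=summary["n_rhythmic_chip"])

    # ------------------------------------------------------------ stage: fdr
    per_gene_fdr = {}
    fdr_notes = {}
    for name, cm, rhy in (("rna", rna_norm, rna_rhy), ("chip", chip_norm, chip_rhy)):
        try:
            edges = fdr_mod.make_bins(
                np.log2(rhy.loc[rhy["rhythmic"], "fold_amplitude"].to_numpy()),
                n_bins=config.fdr_bins,
            )
            obs = fdr_mod.observed_occurrence(rhy, rhy["rhythmic"].to_numpy(), edges)
            bg = fdr_mod.shuffle_null(
                cm, edges, n_shuffles=config.n_shuffles, seed=config.seed,
                alpha=config.alpha, fit_period=config.fit_period,
            )
            curve = fdr_mod.fdr_curve(
                fdr_mod.fit_decay(obs), fdr_mod.fit_decay(bg), obs_hist=obs
            )
        except ValueError as exc:
            # run too small for decay fitting (e.g. < 3 nonzero bins):
            # report missing FDRs rather than aborting the whole run
            per_gene_fdr[name] = pd.Series(
                np.nan, index=rhy.index, name="fdr_amplitude"
            )
            fdr_notes[name] = str(exc)
            continue
        curve.to_frame().to_csv(out / f"{name}_fdr_curve.tsv", sep="\t", index=False)
        per_gene_fdr[name] = fdr_mod.assign_fdr(rhy, curve)
        per_gene_fdr[name].to_frame().to_csv(out / f"{name}_fdr.tsv", sep="\t")
    log("fdr", n_shuffles=config.n_shuffles, **{f"{k}_skipped": v for k, v in fdr_notes.items()})

    # ------------------------------------------------------------- stage: de
    if config.run_de and sim_cfg is not None and truth is not None:
        de_rng = synthetic_data.rng_for(config.seed, "de_effects")
        lfc = np.where(
            de_rng.random(len(truth)) < config.frac_de,
            np.where(de_rng.random(len(truth)) < 0.5, 1.0, -1.0) * config.de_log2fc,
            0.0,
        )
        truth["de_log2fc"] = lfc
        treat, control = synthetic_data.simulate_condition_pair(
            truth, sim_cfg, n_replicates=config.n_replicates
        )
        de_table = diffexpr.run_de(treat, control, alpha=config.alpha)
        de_table.to_csv(out / "de_results.tsv", sep="\t")
        summary["n_de_calls"] = int(de_table["call"].sum())
        log("de", n_calls=summary["n_de_calls"])

    # --------------------------------------------------------- stage: phases
    groups = phase_analysis.classify_groups(
        rna_rhy, chip_rhy, alpha=config.alpha,
        in_phase_tol_hours=config.in_phase_tol_hours, period=config.fit_period,
    )
    groups.to_csv(out / "groups.tsv", sep="\t")
    summary.update(phase_analysis.group_sizes(groups))
    robust = phase_analysis.robust_oscillators(rna_rhy, per_gene_fdr["rna"])
    summary["n_robust_oscillators"] = len(robust)
    rhythmic_rna = rna_rhy.index[rna_rhy["rhythmic"]]
    rhythmic_chip = chip_rhy.index[chip_rhy["rhythmic"]]
    universe = set(rna_rhy.index) | set(chip_rhy.index)
    overlap = phase_analysis.overlap_summary(
        set(rhythmic_rna) & universe, set(rhythmic_chip) & universe, universe,
        phases_A=rna_rhy.loc[rhythmic_rna, "phase"],
        phases_B=chip_rhy.loc[rhythmic_chip, "phase"],
        period=config.fit_period,
    )
    with open(out / "overlap_summary.json", "w") as fh:
        json.dump(overlap, fh, indent=2)
    rhythmic_phase_class = rna_rhy.loc[rhythmic_rna, "phase_class"]
    n_rhy = max(len(rhythmic_rna), 1)
    summary["dawn_fraction_rna"] = float((rhythmic_phase_class == "dawn").sum() / n_rhy)
    summary["dusk_fraction_rna"] = float((rhythmic_phase_class == "dusk").sum() / n_rhy)
    log("phases", **{k: v for k, v in summary.items() if isinstance(v, (int, float))})

    # --------------------------------------------------------------- wrap-up
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    for path in sorted(out.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["files"][path.name] = _sha256(path)
    manifest["summary"] = summary
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
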