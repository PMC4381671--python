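"""Synthetic annotations, reads, and count time courses with ground truth.

Every downstream stage is exercised on data from this module: toy GFF3
annotations with designed overlapping gene pairs, NB count matrices whose
mean follows a log-linear cosine ``mu_g(t) = m_g * exp(A_g cos(w(t -
phi_g)))``, optional per-read BED positions (with bleed-through into
overlap regions), and a truth table recording what each gene really is.

RNA rhythms are derived from the transcription rhythm through first-order
degradation kinetics: a transcript with turnover rate ``k`` driven by a
sinusoidal synthesis rate oscillates with relative amplitude
``k / sqrt(k^2 + w^2)`` and phase delay ``atan(w / k) / w`` — slow
turnover means a blunted, delayed RNA rhythm.

Reproducibility: each stage draws from its own generator derived from
``config.seed`` and a stage name via CRC32 spawn keys (see
:func:`rng_for`), so stages can be re-run independently.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Exon, Gene, GeneAnnotation
from .counts import BED_COLUMNS, CountMatrix, time_label


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Independent, documented RNG stream for a named pipeline stage.

    The stream is ``default_rng(SeedSequence(seed, spawn_key=(crc32(stage),)))``;
    the same (seed, stage) pair always yields the same stream.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def default_dispersion(mu, phi0: float = 0.05, c: float = 5.0):
    """Variance with a dispersion that decays toward phi0 at high means.

    ``var = mu + phi(mu) * mu^2`` with ``phi(mu) = phi0 * (1 + c / mu)``.
    """
    mu = np.asarray(mu, dtype=float)
    return mu + phi0 * (1.0 + c / np.maximum(mu, 1e-12)) * mu * mu


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_timepoints: int = 12
    dt_hours: float = 2.0
    period_hours: float = 22.0
    frac_rhythmic: float = 0.3
    #: (dawn mean CT, dusk mean CT, von Mises concentration)
    phase_mixture: tuple[float, float, float] = (0.0, 11.0, 8.0)
    #: log-amplitude A sampler; fold amplitude is exp(2A)
    amplitude_dist: object = None
    #: baseline mean sampler
    mean_expr_dist: object = None
    #: variance as a function of mean; must satisfy var >= mu
    dispersion_fn: object = None
    frac_light_spike: float = 0.10
    light_spike_factor: float = 4.0
    n_overlap_pairs: int = 0
    overlap_length: int = 200
    bleed_rate: float = 0.30
    #: RNA turnover rate sampler (1/hour)
    degradation_rate_dist: object = None
    #: archetype fractions among rhythmic genes (rest are concordant)
    frac_stable_transcript: float = 0.0
    frac_rna_only: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise ValueError("frac_rhythmic must be in [0, 1]")
        if self.period_hours <= 0:
            raise ValueError("period_hours must be positive")
        if self.n_timepoints < 4:
            raise ValueError("need at least 4 time points")
        if self.amplitude_dist is None:
            self.amplitude_dist = lambda rng, n: rng.uniform(0.35, 1.1, n)
        if self.mean_expr_dist is None:
            self.mean_expr_dist = lambda rng, n: np.exp(
                rng.normal(math.log(150.0), 0.8, n)
            )
        if self.dispersion_fn is None:
            self.dispersion_fn = default_dispersion
        if self.degradation_rate_dist is None:
            self.degradation_rate_dist = lambda rng, n: np.exp(
                rng.uniform(math.log(0.3), math.log(2.0), n)
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.dt_hours

    @property
    def omega(self) -> float:
        return 2.0 * math.pi / self.period_hours

    def echo(self) -> dict:
        """JSON-serializable record of the scalar parameters."""
        return {
            k: v
            for k, v in self.__dict__.items()
            if isinstance(v, (int, float, str, tuple, list, bool))
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.echo(), fh, indent=2, default=list)


@dataclass(frozen=True)
class KineticResponse:
    """Amplitude attenuation and phase delay of RNA behind transcription."""

    attenuation: float  # ratio in (0, 1]
    delay_hours: float  # in [0, period/4]


def kinetic_rna_response(k: float, period: float) -> KineticResponse:
    """Closed-form response of first-order turnover to sinusoidal input.

    For ``dR/dt = s(t) - k R`` with sinusoidal synthesis at angular
    frequency ``w = 2 pi / period``, the stationary RNA rhythm has relative
    amplitude ``k / sqrt(k^2 + w^2)`` and lags by ``atan(w / k) / w``
    hours. Fast turnover (k >> w) tracks transcription; slow turnover
    blunts and delays the abundance rhythm.
    """
    if k <= 0 or period <= 0:
        raise ValueError("k and period must be positive")
    w = 2.0 * math.pi / period
    return KineticResponse(
        attenuation=k / math.sqrt(k * k + w * w),
        delay_hours=math.atan2(w, k) / w,
    )


# ------------------------------------------------------------- truth table

ARCHETYPES = ("concordant", "stable_transcript", "rna_only", "arrhythmic")


def build_truth(config: SimulationConfig, gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Ground-truth table: one row per gene.

    Columns: is_rhythmic, true_phase (CT h), true_amplitude (log units),
    true_fold_amplitude, group_archetype, k_deg, light_spike,
    baseline_mean, de_log2fc.
    """
    rng = rng_for(config.seed, "truth")
    n = config.n_genes
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(n)]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length must equal n_genes")

    is_rhythmic = rng.random(n) < config.frac_rhythmic
    dawn_ct, dusk_ct, kappa = config.phase_mixture
    comp = rng.random(n) < 0.5
    mean_angle = np.where(comp, dawn_ct, dusk_ct) * config.omega
    phase = (rng.vonmises(mean_angle, kappa) / config.omega) % config.period_hours
    amp = np.asarray(config.amplitude_dist(rng, n), dtype=float)
    if np.any(amp <= 0) or not np.all(np.isfinite(amp)):
        raise ValueError("amplitude_dist must produce finite positive values")
    amp = np.where(is_rhythmic, amp, 0.0)
    phase = np.where(is_rhythmic, phase, np.nan)

    arch = np.where(is_rhythmic, "concordant", "arrhythmic").astype(object)
    r_idx = np.where(is_rhythmic)[0]
    rng.shuffle(r_idx)
    n_stable = int(round(config.frac_stable_transcript * len(r_idx)))
    n_rna = int(round(config.frac_rna_only * len(r_idx)))
    arch[r_idx[:n_stable]] = "stable_transcript"
    arch[r_idx[n_stable : n_stable + n_rna]] = "rna_only"

    k = np.asarray(config.degradation_rate_dist(rng, n), dtype=float)
    if np.any(k <= 0) or not np.all(np.isfinite(k)):
        raise ValueError("degradation_rate_dist must produce finite positive rates")
    # stable-transcript genes get slow turnover; others fast enough to track
    k[arch == "stable_transcript"] = np.exp(
        rng.uniform(math.log(0.03), math.log(0.08), n_stable)
    )
    k[arch == "concordant"] = np.maximum(k[arch == "concordant"], 1.0)

    means = np.asarray(config.mean_expr_dist(rng, n), dtype=float)
    if np.any(means <= 0) or not np.all(np.isfinite(means)):
        raise ValueError("mean_expr_dist must produce finite positive values")
    spike = rng.random(n) < config.frac_light_spike

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_rhythmic": is_rhythmic,
            "true_phase": phase,
            "true_amplitude": amp,
            "true_fold_amplitude": np.exp(2.0 * amp),
            "group_archetype": arch,
            "k_deg": k,
            "light_spike": spike,
            "baseline_mean": means,
            "de_log2fc": 0.0,
        }
    ).set_index("gene_id")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.reset_index().to_json(path, orient="records", indent=2)


def read_truth(path) -> pd.DataFrame:
    return pd.read_json(path, orient="records").set_index("gene_id")


# -------------------------------------------------------------- annotation


def build_toy_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Toy single-chromosome annotation with designed overlap pairs.

    The first ``2 * n_overlap_pairs`` genes are laid out as tail-to-tail
    single-exon pairs sharing ``config.overlap_length`` bp; remaining
    genes are disjoint with 1-3 exons. Deterministic given the seed.
    """
    if config.n_genes < 2 * config.n_overlap_pairs:
        raise ValueError("n_genes must be >= 2 * n_overlap_pairs")
    rng = rng_for(config.seed, "annotation")
    genes: list[Gene] = []
    cursor = 50_000  # leading margin so background windows fit upstream
    chrom = "chr_sim"
    i = 0
    for _ in range(config.n_overlap_pairs):
        la = int(rng.integers(1200, 3000))
        lb = int(rng.integers(1200, 3000))
        ov = config.overlap_length
        if ov >= min(la, lb):
            raise ValueError("overlap_length must be shorter than both genes")
        a_start = cursor
        b_start = a_start + la - ov
        genes.append(Gene(f"g{i:05d}", chrom, "+", a_start, a_start + la))
        genes.append(Gene(f"g{i + 1:05d}", chrom, "-", b_start, b_start + lb))
        cursor = b_start + lb + int(rng.integers(1000, 4000))
        i += 2
    while i < config.n_genes:
        length = int(rng.integers(800, 3000))
        start = cursor
        n_ex = int(rng.integers(1, 4))
        exons = _split_exons(rng, start, start + length, n_ex)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"g{i:05d}", chrom, strand, start, start + length, exons))
        cursor = start + length + int(rng.integers(1000, 4000))
        i += 1
    chrom_size = cursor + 50_000
    return GeneAnnotation(genes, chrom_sizes={chrom: chrom_size})


def _split_exons(rng, start: int, end: int, n_exons: int) -> list[Exon]:
    if n_exons == 1:
        return [Exon(start, end)]
    length = end - start
    # introns take ~20% of the span, split points away from the edges
    cuts = np.sort(rng.integers(length // 5, 4 * length // 5, size=2 * (n_exons - 1)))
    exons, pos = [], start
    bounds = [start] + [start + int(c) for c in cuts] + [end]
    for j in range(0, len(bounds) - 1, 2):
        s, e = bounds[j], bounds[j + 1]
        if e > s:
            exons.append(Exon(s, e))
    if not exons:
        exons = [Exon(start, end)]
    # pin first/last exon to the gene span ends
    exons[0] = Exon(start, exons[0].end)
    exons[-1] = Exon(exons[-1].start, end)
    return exons


# ------------------------------------------------------------- time course


def _nb_draw(rng, mu: np.ndarray, dispersion_fn) -> np.ndarray:
    """NB (or Poisson-limit) draws with variance from ``dispersion_fn``."""
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(dispersion_fn(mu), dtype=float)
    if np.any(var < mu - 1e-9):
        raise ValueError("dispersion_fn returned variance < mean")
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_like = var <= mu * (1.0 + 1e-9)
    out[poisson_like] = rng.poisson(mu[poisson_like])
    nbm = ~poisson_like
    if nbm.any():
        m, v = mu[nbm], var[nbm]
        r = m * m / (v - m)
        out[nbm] = rng.negative_binomial(r, r / (r + m))
    return out


def expected_means(
    truth: pd.DataFrame, config: SimulationConfig, assay: str
) -> np.ndarray:
    """Deterministic (genes, timepoints) mean surface for an assay.

    ``rnapii`` means follow the transcription rhythm directly; ``rna``
    means are attenuated and delayed through :func:`kinetic_rna_response`
    (except ``rna_only`` genes, whose RNA rhythm is post-transcriptional,
    and whose transcription is flat).
    """
    if assay not in {"rna", "rnapii"}:
        raise ValueError("assay must be 'rna' or 'rnapii'")
    t = config.times
    m = truth["baseline_mean"].to_numpy(dtype=float)
    A = truth["true_amplitude"].to_numpy(dtype=float).copy()
    phi = np.nan_to_num(truth["true_phase"].to_numpy(dtype=float))
    arch = truth["group_archetype"].to_numpy()
    if assay == "rnapii":
        A = np.where(arch == "rna_only", 0.0, A)
    else:
        kin = np.array(
            [
                kinetic_rna_response(k, config.period_hours)
                for k in truth["k_deg"].to_numpy(dtype=float)
            ]
        )
        att = np.array([r.attenuation for r in kin])
        delay = np.array([r.delay_hours for r in kin])
        transcribed = ~np.isin(arch, ["rna_only"])
        A = np.where(transcribed, A * att, A)
        phi = np.where(transcribed, (phi + delay) % config.period_hours, phi)
    mu = m[:, None] * np.exp(
        A[:, None] * np.cos(config.omega * (t[None, :] - phi[:, None]))
    )
    spike = truth["light_spike"].to_numpy(dtype=bool)
    if 0.0 in t:
        j0 = int(np.where(t == 0.0)[0][0])
        mu[spike, j0] *= config.light_spike_factor
    return mu


@dataclass
class TimecourseSim:
    counts: CountMatrix
    reads: pd.DataFrame | None = None  # BED6 layout, None in counts mode


def simulate_timecourse(
    annotation: GeneAnnotation | None,
    truth: pd.DataFrame,
    config: SimulationConfig,
    assay: str = "rna",
    emit_reads: bool = False,
) -> TimecourseSim:
    """Simulate a gene x time-point NB count matrix (optionally with reads).

    With ``emit_reads`` the function places one BED record per count (5'
    positions uniform over exons for RNA, over the 3'-terminal window for
    the polymerase assay), adds bleed-through reads into overlap regions
    at ``config.bleed_rate`` x the weaker partner's density, and returns
    the matrix obtained by *recounting the emitted reads*, so counts and
    reads are consistent by construction.
    """
    if annotation is not None and list(truth.index) != annotation.gene_ids:
        raise ValueError("truth rows must match annotation genes")
    rng = rng_for(config.seed, f"timecourse_{assay}")
    mu = expected_means(truth, config, assay)
    base = _nb_draw(rng, mu, config.dispersion_fn)
    labels = [time_label(h) for h in config.times]

    if not emit_reads:
        data = pd.DataFrame(base, index=list(truth.index), columns=labels)
        return TimecourseSim(CountMatrix(data, assay=assay))

    if annotation is None:
        raise ValueError("emit_reads requires an annotation")
    reads = _emit_reads(rng, annotation, truth, config, assay, base, labels)
    from .quantify import count_exonic, count_terminal_window

    if assay == "rna":
        cm = count_exonic(reads, annotation)
    else:
        cm = count_terminal_window(reads, annotation)
    cm.assay = assay
    return TimecourseSim(cm, reads)


def _emit_reads(rng, annotation, truth, config, assay, base, labels) -> pd.DataFrame:
    chunks = []
    gene_ids = list(truth.index)
    read_len = 50
    for gi, gid in enumerate(gene_ids):
        g = annotation[gid]
        if assay == "rna":
            targets = [(ex.start, ex.end) for ex in g.exons]
        else:
            targets = [g.terminal_window(500)]
        lens = np.array([e - s for s, e in targets])
        starts = np.array([s for s, _ in targets])
        cum = np.concatenate([[0], np.cumsum(lens)])
        total_len = int(cum[-1])
        for j, lab in enumerate(labels):
            c = int(base[gi, j])
            if c == 0:
                continue
            offs = rng.integers(0, total_len, size=c)
            seg = np.searchsorted(cum, offs, side="right") - 1
            pos = starts[seg] + (offs - cum[seg])
            chunks.append(_read_frame(g.chrom, pos, lab, g.strand, read_len,
                                      annotation.chrom_sizes[g.chrom]))
    if assay == "rna" and config.bleed_rate > 0:
        chunks.extend(
            _bleed_reads(rng, annotation, truth, config, base, labels, read_len)
        )
    if not chunks:
        return pd.DataFrame(columns=BED_COLUMNS)
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["chrom", "start", "name"], kind="stable").reset_index(
        drop=True
    )


def _read_frame(chrom, pos5, label, strand, read_len, chrom_size) -> pd.DataFrame:
    pos5 = np.asarray(pos5, dtype=np.int64)
    if strand == "+":
        start = pos5
        end = np.minimum(pos5 + read_len, chrom_size)
    else:
        end = pos5 + 1
        start = np.maximum(end - read_len, 0)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "name": label,
            "score": 0,
            "strand": strand,
        }
    )


def _bleed_reads(rng, annotation, truth, config, base, labels, read_len):
    """Extra reads in overlap regions, Poisson at bleed_rate x weak density."""
    chunks = []
    gene_ids = list(truth.index)
    idx = {gid: i for i, gid in enumerate(gene_ids)}
    for rec in annotation.overlaps:
        ga, gb = annotation[rec.gene_a], annotation[rec.gene_b]
        for j, lab in enumerate(labels):
            ca, cb = base[idx[rec.gene_a], j], base[idx[rec.gene_b], j]
            dens = min(ca / ga.exonic_length, cb / gb.exonic_length)
            lam = config.bleed_rate * dens * rec.length
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            pos = rng.integers(rec.start, rec.end, size=n)
            chunks.append(
                _read_frame(ga.chrom, pos, lab, "+", read_len,
                            annotation.chrom_sizes[ga.chrom])
            )
    return chunks


# ---------------------------------------------------------- condition pairs


def simulate_condition_pair(
    truth: pd.DataFrame,
    config: SimulationConfig,
    effect_model=None,
    n_replicates: int = 3,
) -> tuple[CountMatrix, CountMatrix]:
    """Paired treat/control count matrices with NB replicate noise.

    ``effect_model`` maps the truth table to a per-gene log2 fold change
    (default: the truth's ``de_log2fc`` column); the truth table is
    updated in place with the effects used.
    """
    rng = rng_for(config.seed, "condition_pair")
    if effect_model is None:
        lfc = truth["de_log2fc"].to_numpy(dtype=float)
    else:
        lfc = np.asarray(effect_model(truth), dtype=float)
        truth["de_log2fc"] = lfc
    m = truth["baseline_mean"].to_numpy(dtype=float)
    mu_c = np.repeat(m[:, None], n_replicates, axis=1)
    mu_t = mu_c * (2.0 ** lfc)[:, None]
    treat = _nb_draw(rng, mu_t, config.dispersion_fn)
    control = _nb_draw(rng, mu_c, config.dispersion_fn)
    cols_t = [f"treat_{r + 1}" for r in range(n_replicates)]
    cols_c = [f"control_{r + 1}" for r in range(n_replicates)]
    gid = list(truth.index)
    return (
        CountMatrix(pd.DataFrame(treat, index=gid, columns=cols_t), assay="rna"),
        CountMatrix(pd.DataFrame(control, index=gid, columns=cols_c), assay="rna"),
    )
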