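"""Shuffle-based false discovery rates stratified by amplitude or coverage.

Null data are built by randomly permuting the time points of every gene's
series (one shared permutation per shuffle, preserving cross-gene
structure) and re-running the dual rhythm detector. The occurrence of
rhythmic calls decays roughly exponentially in amplitude, so exponential
decay curves ``c * exp(-lambda x)`` are fitted to the observed and
background occurrence histograms and combined as

    FDR(x) = f_bg(x) / (f_ob(x) + f_bg(x)) * Weight(x)

then clamped to [0, 1] and made monotone non-increasing by an isotonic
pass. ``Weight`` down-weights sparsely populated high-amplitude bins
(default: ``1 - exp(-n_obs(bin))``); ``identity`` is also available. A
``background-over-observed`` variant (``f_bg / f_ob``) is provided behind
a flag because the printed denominator tends to 0.5 rather than 1 on
pure-null data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .counts import CountMatrix
from .rhythms import detect_rhythm_dual_matrix, fit_sine_nb_matrix


# ------------------------------------------------------------------- types


@dataclass
class OccurrenceHistogram:
    edges: np.ndarray  # bin edges on the stratifier scale (log2 amp / log10 cov)
    counts: np.ndarray  # genes called rhythmic per bin (per-shuffle average)
    source: str  # 'observed' or 'shuffled(n)'
    stratifier: str = "amplitude"

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class DecayFit:
    intercept: float  # c > 0
    rate: float  # lambda >= 0
    domain: tuple[float, float]
    residual_rms: float

    def __call__(self, x) -> np.ndarray:
        return self.intercept * np.exp(-self.rate * np.asarray(x, dtype=float))


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators projection onto non-increasing sequences."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    level = list(y)
    weight = [1.0] * n
    i = 0
    while i < len(level) - 1:
        if level[i] < level[i + 1] - 1e-15:
            merged = (level[i] * weight[i] + level[i + 1] * weight[i + 1]) / (
                weight[i] + weight[i + 1]
            )
            level[i : i + 2] = [merged]
            weight[i : i + 2] = [weight[i] + weight[i + 1]]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty(n)
    pos = 0
    for lv, w in zip(level, weight):
        out[pos : pos + int(w)] = lv
        pos += int(w)
    return out


@dataclass
class FdrCurve:
    stratifier: str
    observed: DecayFit
    background: DecayFit
    x: np.ndarray  # evaluation grid (bin centers)
    fdr: np.ndarray  # clamped + isotonic values on the grid
    weight_name: str = "saturating"
    weights: np.ndarray | None = None

    def __call__(self, x) -> np.ndarray:
        """FDR at stratifier value(s) ``x``, clamped to the fitted domain."""
        xq = np.clip(np.asarray(x, dtype=float), self.x[0], self.x[-1])
        return np.interp(xq, self.x, self.fdr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "f_ob": self.observed(self.x),
                "f_bg": self.background(self.x),
                "weight": self.weights if self.weights is not None else 1.0,
                "fdr": self.fdr,
            }
        )


# -------------------------------------------------------------- histograms


def make_bins(values: np.ndarray, n_bins: int = 20, lo_pct: float = 1.0,
              hi_pct: float = 99.0) -> np.ndarray:
    """Equal-width bin edges over the central percentile range of ``values``."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values to bin")
    lo, hi = np.percentile(v, [lo_pct, hi_pct])
    if hi <= lo:
        hi = lo + 1e-6
    return np.linspace(lo, hi, n_bins + 1)


def _stratifier_values(fits: pd.DataFrame, stratifier: str) -> np.ndarray:
    if stratifier == "amplitude":
        return np.log2(fits["fold_amplitude"].to_numpy(dtype=float))
    if stratifier == "coverage":
        return np.log10(np.maximum(fits["coverage"].to_numpy(dtype=float), 0.5))
    raise ValueError("stratifier must be 'amplitude' or 'coverage'")


def observed_occurrence(
    fits: pd.DataFrame,
    rhythmic: np.ndarray,
    edges: np.ndarray,
    stratifier: str = "amplitude",
) -> OccurrenceHistogram:
    """Histogram of rhythmic calls along the stratifier."""
    x = _stratifier_values(fits, stratifier)[np.asarray(rhythmic, dtype=bool)]
    counts, _ = np.histogram(x, bins=edges)
    return OccurrenceHistogram(edges, counts.astype(float), "observed", stratifier)


def shuffle_null(
    counts: CountMatrix,
    edges: np.ndarray,
    n_shuffles: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    stratifier: str = "amplitude",
    fit_period: float = 22.0,
    variance_model=None,
    per_gene_permutation: bool = False,
    identity: bool = False,
) -> OccurrenceHistogram:
    """Occurrence histogram of rhythmic calls on time-shuffled data.

    Each shuffle permutes the time labels (shared across genes unless
    ``per_gene_permutation``), reruns dual detection, and histograms the
    NB-sine amplitudes (or coverages) of genes called rhythmic at
    ``alpha``. Returns per-shuffle average counts per bin.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    times = counts.times
    if times is None:
        raise ValueError("count matrix lacks parseable time labels")
    X = counts.values.astype(float)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(edges) - 1, dtype=float)
    for _ in range(n_shuffles):
        if identity:  # degenerate no-op permutation, for testing
            Xs = X
        elif per_gene_permutation:
            Xs = np.stack([row[rng.permutation(len(times))] for row in X])
        else:
            perm = rng.permutation(len(times))
            Xs = X[:, perm]
        det = detect_rhythm_dual_matrix(Xs, times)
        called = det["p_min"].to_numpy() < alpha
        if not called.any():
            continue
        fits = fit_sine_nb_matrix(Xs[called], times, fit_period, variance_model)
        fits["coverage"] = np.median(Xs[called], axis=1)
        x = _stratifier_values(fits, stratifier)
        h, _ = np.histogram(x, bins=edges)
        acc += h
    return OccurrenceHistogram(
        edges, acc / n_shuffles, f"shuffled({n_shuffles})", stratifier
    )


# ------------------------------------------------------------------ fitting


def fit_decay(hist: OccurrenceHistogram, from_mode: bool = True) -> DecayFit:
    """Count-weighted nonlinear least-squares fit of ``c * exp(-lambda x)``.

    Weights are derived from the bin counts assuming Poisson sampling
    (inverse-variance, i.e. sigma_i = sqrt(count_i)); empty bins are
    retained with unit variance. This equalizes *relative* error across
    bins spanning orders of magnitude, which a plain least-squares fit of
    an exponential does not. Occurrence histograms rise to a mode before
    decaying (low-amplitude calls are truncated by the detection
    threshold), so by default only bins from the modal bin onward enter
    the fit — the decay regime. Requires at least 3 nonzero bins.
    """
    x = hist.centers
    y = np.asarray(hist.counts, dtype=float)
    if from_mode and y.max() > 0:
        start = int(np.argmax(y))
        if len(y) - start >= 3:
            x, y = x[start:], y[start:]
    nonzero = y > 0
    if nonzero.sum() < 3:
        raise ValueError(
            "fewer than 3 nonzero bins; widen the bins or add data"
        )
    sigma = np.sqrt(np.maximum(y, 1.0))
    # log-linear start values on the nonzero bins
    slope, icept = np.polyfit(x[nonzero], np.log(y[nonzero]), 1)
    p0 = (float(np.exp(icept)), float(max(-slope, 0.0)))
    popt, _ = curve_fit(
        lambda t, c, lam: c * np.exp(-lam * t),
        x,
        y,
        p0=p0,
        sigma=sigma,
        bounds=([1e-12, 0.0], [np.inf, np.inf]),
        maxfev=20_000,
    )
    fit = DecayFit(
        intercept=float(popt[0]),
        rate=float(popt[1]),
        domain=(float(x[0]), float(x[-1])),
        residual_rms=float(np.sqrt(np.mean((popt[0] * np.exp(-popt[1] * x) - y) ** 2))),
    )
    return fit


WEIGHT_FUNCTIONS = {
    "identity": lambda n_obs: np.ones_like(np.asarray(n_obs, dtype=float)),
    "saturating": lambda n_obs: 1.0 - np.exp(-np.asarray(n_obs, dtype=float)),
}


def fdr_curve(
    observed: DecayFit,
    background: DecayFit,
    obs_hist: OccurrenceHistogram | None = None,
    weight: str = "saturating",
    denominator: str = "printed",
) -> FdrCurve:
    """Combine decay fits into an evaluable FDR(x) curve.

    ``denominator='printed'`` uses ``f_bg / (f_ob + f_bg)``;
    ``'observed'`` uses ``f_bg / f_ob`` (capped at 1), which reaches 1
    rather than 0.5 on pure-null data.
    """
    if weight not in WEIGHT_FUNCTIONS:
        raise ValueError(f"unknown weight {weight!r}")
    lo = min(observed.domain[0], background.domain[0])
    hi = max(observed.domain[1], background.domain[1])
    if obs_hist is not None:
        x = obs_hist.centers
        n_obs = obs_hist.counts
    else:
        x = np.linspace(lo, hi, 41)
        n_obs = np.full_like(x, 50.0)
    f_ob, f_bg = observed(x), background(x)
    wts = WEIGHT_FUNCTIONS[weight](n_obs)
    denom = (f_ob + f_bg) if denominator == "printed" else f_ob
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(denom > 0, f_bg / denom, np.nan) * wts
    raw = np.clip(raw, 0.0, 1.0)
    valid = np.isfinite(raw)
    fdr = raw.copy()
    fdr[valid] = _pava_decreasing(raw[valid])
    return FdrCurve(
        stratifier=(obs_hist.stratifier if obs_hist is not None else "amplitude"),
        observed=observed,
        background=background,
        x=x,
        fdr=fdr,
        weight_name=weight,
        weights=wts,
    )


def assign_fdr(fits: pd.DataFrame, curve: FdrCurve) -> pd.Series:
    """Per-gene FDR from the curve evaluated at each gene's stratifier value.

    Values outside the fitted domain are clamped to the domain edges.
    """
    x = _stratifier_values(fits, curve.stratifier)
    return pd.Series(curve(x), index=fits.index, name=f"fdr_{curve.stratifier}")


def combine_fdr(*series: pd.Series) -> pd.Series:
    """Conservative combination across stratifiers: per-gene maximum."""
    out = pd.concat(series, axis=1).max(axis=1)
    out.name = "fdr"
    return out
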