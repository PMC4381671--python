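"""Negative-binomial exact differential test with a fitted mean-variance fit.

Counts are modelled as ``G_i ~ NB(mu_i, sigma_i^2)`` where the variance is
a smooth function of the mean, fitted across genes by local regression
(LOWESS of ``log(var - mean + eps)`` on ``log mean``), floored at Poisson.

The two-sided exact test conditions on the total ``s = G_treat +
G_control``: under the null both samples share mean ``s / 2`` and variance
``sigma^2(s / 2)``, and

    p = sum over {a + b = s : f(a) f(b) <= f(G_treat) f(G_control)}
        of f(a) f(b), divided by the total over a + b = s,

with ``f`` the NB probability mass function. The enumeration is exact and
vectorized (adapted two-sided Robinson-Smyth test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix

_MAX_ENUMERATION = 1_000_000


class MeanVarianceModel:
    """Smooth, monotone variance-given-mean function fitted across genes.

    Internally a smoothed dispersion curve ``phi(mu)`` on a log-mean grid;
    callable as ``model(mu) -> sigma^2 = mu + phi(mu) * mu^2``, linearly
    extrapolated at the grid ends (phi clamped at 0) and floored at
    ``mu * (1 + floor_eps)`` so the NB parameterization stays valid.
    """

    def __init__(self, log_mu_grid, phi_grid, floor_eps: float = 1e-6,
                 n_genes: int = 0):
        self.log_mu_grid = np.asarray(log_mu_grid, dtype=float)
        self.phi_grid = np.asarray(phi_grid, dtype=float)
        self.floor_eps = float(floor_eps)
        self.n_genes = n_genes

    def _phi(self, mu: np.ndarray) -> np.ndarray:
        lm = np.log(np.maximum(mu, 1e-12))
        g, v = self.log_mu_grid, self.phi_grid
        phi = np.interp(lm, g, v)
        lo, hi = lm < g[0], lm > g[-1]
        if lo.any() and len(g) > 1:
            slope = (v[1] - v[0]) / (g[1] - g[0])
            phi[lo] = v[0] + slope * (lm[lo] - g[0])
        if hi.any() and len(g) > 1:
            slope = (v[-1] - v[-2]) / (g[-1] - g[-2])
            phi[hi] = v[-1] + slope * (lm[hi] - g[-1])
        return np.maximum(phi, 0.0)

    def __call__(self, mu):
        mu = np.asarray(mu, dtype=float)
        scalar = mu.ndim == 0
        mu = np.atleast_1d(mu)
        var = mu + self._phi(mu) * mu * mu
        # monotone non-decreasing in mu is guaranteed by construction:
        # mu and phi(mu) * mu^2 (phi >= 0, smooth) are both non-decreasing
        # after the cummax applied to the grid at fit time
        var = np.maximum(var, mu * (1.0 + self.floor_eps))
        return var[0] if scalar else var

    def scaled(self, factor: float) -> "MeanVarianceModel":
        """Model for sums of ``factor`` i.i.d. draws: ``factor * var(mu / factor)``."""
        parent = self

        class _Scaled(MeanVarianceModel):
            def __init__(self):
                self.floor_eps = parent.floor_eps
                self.n_genes = parent.n_genes

            def __call__(self, mu):
                return factor * parent(np.asarray(mu, dtype=float) / factor)

        return _Scaled()


def poisson_model() -> MeanVarianceModel:
    """Degenerate model with sigma^2 = mu exactly (Poisson limit)."""

    class _Poisson(MeanVarianceModel):
        def __init__(self):
            self.floor_eps = 0.0
            self.n_genes = 0

        def __call__(self, mu):
            return np.asarray(mu, dtype=float)

    return _Poisson()


def fit_mean_variance(
    matrices: list[pd.DataFrame] | pd.DataFrame,
    frac: float = 0.4,
    floor_eps: float = 1e-6,
    min_genes: int = 30,
) -> MeanVarianceModel:
    """Fit the variance-vs-mean trend from replicated count matrices.

    ``matrices`` holds one genes x replicates frame per condition (each
    with >= 2 replicates); per gene and condition the sample mean and
    variance are pooled. The per-gene dispersion ``(var - mean) / mean^2``
    is smoothed against ``log mean`` by LOWESS in linear dispersion space
    (sample variances are unbiased there, so the smooth is too, unlike a
    log-variance fit). Fails when fewer than ``min_genes`` genes show
    positive excess variance.
    """
    if isinstance(matrices, pd.DataFrame):
        matrices = [matrices]
    means, variances = [], []
    for m in matrices:
        arr = np.asarray(m, dtype=float)
        if arr.shape[1] < 2:
            raise ValueError("need >= 2 replicates per condition")
        means.append(arr.mean(axis=1))
        variances.append(arr.var(axis=1, ddof=1))
    mu = np.concatenate(means)
    var = np.concatenate(variances)
    ok = mu > 0
    mu, var = mu[ok], var[ok]
    excess = var - mu
    if (excess > 0).sum() < min_genes:
        raise ValueError(
            f"only {(excess > 0).sum()} genes with positive excess variance; "
            "the mean-variance trend is unidentifiable"
        )
    x = np.log(mu)
    phi = excess / (mu * mu)
    sm = lowess(phi, x, frac=frac, it=0, return_sorted=True)
    gx, uniq = np.unique(sm[:, 0], return_index=True)
    gphi = np.maximum(sm[:, 1][uniq], 0.0)
    # re-grid and enforce a monotone non-decreasing variance curve
    grid = np.linspace(gx[0], gx[-1], 256)
    mu_grid = np.exp(grid)
    var_grid = mu_grid + np.interp(grid, gx, gphi) * mu_grid * mu_grid
    var_grid = np.maximum.accumulate(np.maximum(var_grid, mu_grid))
    phi_grid = np.maximum((var_grid - mu_grid) / (mu_grid * mu_grid), 0.0)
    return MeanVarianceModel(grid, phi_grid, floor_eps=floor_eps,
                             n_genes=int(ok.sum()))


def fit_mean_variance_timecourse(
    counts: CountMatrix, period: float = 22.0, **kwargs
) -> MeanVarianceModel:
    """Fallback fit using time points as pseudo-replicates.

    The fitted harmonic (NB sine at ``period``) is divided out of each
    gene's series first, so the rhythm itself does not inflate the
    variance estimate. The t=0 sample, when present, is excluded: its
    light-inflated values would otherwise bias the variance upward.
    """
    from .rhythms import fit_sine_nb_matrix

    times = counts.times
    if times is None:
        raise ValueError("count matrix lacks parseable time labels")
    X = counts.values.astype(float)
    keep = times != 0.0
    if keep.sum() >= 8:
        X, times = X[:, keep], times[keep]
    fits = fit_sine_nb_matrix(X, times, period)
    w = 2.0 * np.pi / period
    trend = np.exp(
        fits["beta1"].to_numpy()[:, None] * np.cos(w * times)[None, :]
        + fits["beta2"].to_numpy()[:, None] * np.sin(w * times)[None, :]
    )
    flat = X / trend
    return fit_mean_variance(pd.DataFrame(flat), **kwargs)


# --------------------------------------------------------------- exact test


def _nb_logpmf(k: np.ndarray, mu: float, var: float) -> np.ndarray:
    if var <= mu * (1.0 + 1e-12):
        return stats.poisson.logpmf(k, mu)
    r = mu * mu / (var - mu)
    return stats.nbinom.logpmf(k, r, r / (r + mu))


def nb_exact_pvalue(G_treat: int, G_control: int, model) -> float:
    """Two-sided NB exact p-value conditioning on the total count.

    ``model`` is a :class:`MeanVarianceModel` (or any callable mu ->
    sigma^2). Counts must already be size-factor normalized and rounded to
    integers. ``s = 0`` returns 1 by convention.
    """
    a_obs, b_obs = int(G_treat), int(G_control)
    if a_obs < 0 or b_obs < 0:
        raise ValueError("counts must be non-negative")
    s = a_obs + b_obs
    if s == 0:
        return 1.0
    if s > _MAX_ENUMERATION:
        raise ValueError(f"total count {s} exceeds enumeration cap {_MAX_ENUMERATION}")
    mu = s / 2.0
    var = float(model(mu))
    a = np.arange(s + 1)
    lp = _nb_logpmf(a, mu, var)
    joint = lp + lp[::-1]  # log f(a) + log f(s - a)
    obs = joint[a_obs]
    keep = joint <= obs + 1e-12  # tolerate float ties including the observed
    m = np.max(joint)
    num = np.sum(np.exp(joint[keep] - m))
    den = np.sum(np.exp(joint - m))
    return float(num / den)


def run_de(
    counts_treat: CountMatrix,
    counts_control: CountMatrix,
    model: MeanVarianceModel | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided NB exact test between two conditions.

    Size factors are computed jointly across all samples; normalized
    counts are summed over replicates per condition (requires equal
    replicate numbers), rounded half-to-even, and fed to
    :func:`nb_exact_pvalue` with the variance model rescaled for sums.
    Multiple testing is controlled by Benjamini-Hochberg at ``alpha``.
    """
    if list(counts_treat.gene_ids) != list(counts_control.gene_ids):
        raise ValueError("gene sets must match")
    r_t, r_c = len(counts_treat.samples), len(counts_control.samples)
    if r_t != r_c:
        raise ValueError("equal replicate numbers per condition are required")
    joint = CountMatrix(
        pd.concat([counts_treat.data, counts_control.data], axis=1),
        assay=counts_treat.assay,
    )
    norm = joint.normalize()
    nt = norm.data[counts_treat.samples]
    nc = norm.data[counts_control.samples]
    if model is None:
        model = fit_mean_variance([nt, nc])
    sum_model = model.scaled(float(r_t)) if r_t > 1 else model

    st = np.round(nt.sum(axis=1)).astype(np.int64)
    sc = np.round(nc.sum(axis=1)).astype(np.int64)
    pvals = np.array(
        [nb_exact_pvalue(a, b, sum_model) for a, b in zip(st, sc)]
    )
    mean_t = nt.mean(axis=1)
    mean_c = nc.mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "mean_treat": mean_t,
            "mean_control": mean_c,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": p_adj,
            "call": reject,
        },
        index=pd.Index(counts_treat.gene_ids, name="gene_id"),
    )
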