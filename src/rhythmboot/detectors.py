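"""Rhythmicity detectors for uniformly sampled expression time courses.

Three independent detectors, each an sklearn-style estimator over a
``genes x timepoints`` matrix:

``ArserDetector``
    Linear detrend -> autoregressive spectral estimation of candidate
    periods in [20, 28] h (Yule-Walker, Burg and conditional-least-squares
    AR fits at several orders, union of spectral peaks) -> harmonic
    regression at each candidate with AIC model selection and local period
    refinement -> F-test p-value -> Benjamini-Hochberg q-value across all
    genes; a gene is rhythmic iff q <= 0.05.

``HaystackDetector``
    Pearson correlation of each profile against a library of phase-shifted
    24 h template shapes (cosine, sine, box-like, spike, rigid, asymmetric);
    rhythmic iff best correlation >= 0.8, fold change >= 2 after background
    flooring, and correlation p-value <= 0.05.

``FftNllsDetector``
    Linear detrend, discrete-Fourier initialisation, nonlinear least-squares
    fit of a single cosine with the period constrained to [20, 28] h;
    rhythmic iff the fit converges and the relative amplitude error (95%
    amplitude confidence half-width / amplitude) is below 0.5.

All internals are vectorised across genes so that genome-scale inputs
(tens of thousands of profiles) are processed in seconds; the public
single-series helpers (:func:`linear_detrend`, :func:`ar_spectral_periods`,
:func:`harmonic_regression`, :func:`bh_fdr`) are thin views onto the same
code paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .simdata import ExpressionDataset

__all__ = [
    "linear_detrend",
    "ar_spectral_periods",
    "harmonic_regression",
    "bh_fdr",
    "build_pattern_library",
    "PatternLibrary",
    "ArserDetector",
    "HaystackDetector",
    "FftNllsDetector",
    "arser_detect",
    "haystack_detect",
    "fftnlls_detect",
    "make_detector",
]

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# shared numerical primitives
# ---------------------------------------------------------------------------

def _as_matrix(series) -> tuple[np.ndarray, bool]:
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        return y[None, :], True
    if y.ndim == 2:
        return y, False
    raise InputError("expected a 1-D series or a 2-D gene x timepoint matrix")


def _check_times(times, n) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size != n:
        raise InputError("times must be 1-D and match the series length")
    return t


def _uniform_interval(times) -> float:
    d = np.diff(times)
    if d.size == 0 or not np.allclose(d, d[0], rtol=1e-8, atol=1e-10):
        raise InputError("uniform sampling intervals are required")
    return float(d[0])


def linear_detrend(series, times):
    """OLS residuals of the series regressed on (intercept, time).

    Removes mean and any linear trend; residuals are orthogonal to both
    regressors.  Accepts one series or a gene x timepoint matrix.
    """
    y, squeeze = _as_matrix(series)
    t = _check_times(times, y.shape[1])
    if t.size < 3:
        raise InputError("need at least 3 timepoints to detrend")
    X = np.column_stack([np.ones_like(t), t])
    q, _ = np.linalg.qr(X)
    resid = y - (y @ q) @ q.T
    return resid[0] if squeeze else resid


# -- batched AR model fits ---------------------------------------------------

def _autocovariances(Y: np.ndarray, maxlag: int) -> np.ndarray:
    """Biased sample autocovariances r_0..r_maxlag per row (demeaned)."""
    n = Y.shape[1]
    Yc = Y - Y.mean(axis=1, keepdims=True)
    R = np.empty((Y.shape[0], maxlag + 1))
    for k in range(maxlag + 1):
        R[:, k] = np.einsum("ij,ij->i", Yc[:, : n - k], Yc[:, k:]) / n
    return R


def _levinson_all_orders(R: np.ndarray, maxorder: int):
    """Levinson-Durbin recursion, batched over rows.

    Returns ``([phi_1, ..., phi_maxorder], [sigma2_1, ...])`` where
    ``phi_m`` is the (G, m) Yule-Walker coefficient array of the order-m
    model ``y_t = sum_k phi_k y_{t-k} + e_t``.
    """
    G = R.shape[0]
    phi = np.zeros((G, maxorder + 1))
    E = R[:, 0].copy()
    coeffs, sigmas = [], []
    for m in range(1, maxorder + 1):
        if m == 1:
            acc = R[:, 1]
        else:
            acc = R[:, m] - np.einsum("ij,ij->i", phi[:, 1:m], R[:, m - 1:0:-1])
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(E > 0, acc / np.where(E > 0, E, 1.0), 0.0)
        prev = phi[:, 1:m].copy()
        phi[:, m] = k
        if m > 1:
            phi[:, 1:m] = prev - k[:, None] * prev[:, ::-1]
        E = E * (1.0 - k**2)
        coeffs.append(phi[:, 1 : m + 1].copy())
        sigmas.append(E.copy())
    return coeffs, sigmas


def _burg_all_orders(Y: np.ndarray, maxorder: int):
    """Burg's method, batched over rows; same return layout as Levinson."""
    Yc = Y - Y.mean(axis=1, keepdims=True)
    G, n = Yc.shape
    A = np.zeros((G, maxorder + 1))
    A[:, 0] = 1.0
    f = Yc.copy()
    b = Yc.copy()
    sigma2 = np.einsum("ij,ij->i", Yc, Yc) / n
    coeffs, sigmas = [], []
    for m in range(1, maxorder + 1):
        ff = f[:, 1:]
        bb = b[:, :-1]
        den = np.einsum("ij,ij->i", ff, ff) + np.einsum("ij,ij->i", bb, bb)
        num = -2.0 * np.einsum("ij,ij->i", ff, bb)
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        A[:, : m + 1] = A[:, : m + 1] + k[:, None] * A[:, m::-1]
        f, b = ff + k[:, None] * bb, bb + k[:, None] * ff
        sigma2 = sigma2 * (1.0 - k**2)
        coeffs.append(-A[:, 1 : m + 1])
        sigmas.append(sigma2.copy())
    return coeffs, sigmas


def _cls_ar(Y: np.ndarray, order: int):
    """Conditional least-squares AR fit (conditional MLE), batched over rows."""
    Yc = Y - Y.mean(axis=1, keepdims=True)
    G, n = Yc.shape
    # lag design L[g, i, k] = y_{order+i-1-k}; target y_{order+i}
    L = np.stack([Yc[:, order - 1 - k : n - 1 - k] for k in range(order)], axis=2)
    target = Yc[:, order:]
    M = np.einsum("gik,gil->gkl", L, L)
    v = np.einsum("gik,gi->gk", L, target)
    ridge = 1e-10 * np.trace(M, axis1=1, axis2=2).max() + 1e-30
    M = M + ridge * np.eye(order)[None, :, :]
    phi = np.linalg.solve(M, v[:, :, None])[:, :, 0]
    resid = target - np.einsum("gik,gk->gi", L, phi)
    sigma2 = np.einsum("ij,ij->i", resid, resid) / max(n - order, 1)
    return phi, sigma2


def _spectral_peak_freqs(phi, freqs_ext, dt):
    """Indices (into freqs_ext, interior only) of AR spectral local maxima.

    The AR spectral density is ``sigma2 / |1 - sum_k phi_k e^{-2 i pi f k
    dt}|^2``; since sigma2 is a positive per-gene constant, its local
    maxima over frequency are exactly the strict local minima of the
    denominator, so neither sigma2 nor the division is needed.  A flat
    spectrum (all-zero coefficients) therefore yields nothing.  Returns
    (gene_idx, freq_idx) with freq_idx relative to ``freqs_ext``.
    """
    p = phi.shape[1]
    karr = np.arange(1, p + 1)
    ang = 2.0 * np.pi * np.outer(freqs_ext * dt, karr)  # (F, p)
    re = 1.0 - phi @ np.cos(ang).T
    im = phi @ np.sin(ang).T
    den = re**2 + im**2
    is_min = (den[:, 1:-1] < den[:, :-2]) & (den[:, 1:-1] < den[:, 2:])
    gi, fi = np.nonzero(is_min)
    return gi, fi + 1


def _candidate_periods_batch(
    Y, times, period_min, period_max, methods, max_order, n_freq
):
    """Per-gene candidate periods from the union of AR spectral peaks.

    Returns (gene_idx, period) arrays of candidate rows, deduplicated per
    gene at grid resolution.
    """
    dt = _uniform_interval(times)
    n = Y.shape[1]
    if max_order is None:
        max_order = max(2, n // 3)
    max_order = min(max_order, n - 2)
    freqs = np.linspace(0.0, 0.5 / dt, n_freq + 1)[1:]
    periods_grid = 1.0 / freqs
    band = (periods_grid >= period_min) & (periods_grid <= period_max)
    if not band.any():
        return np.empty(0, int), np.empty(0)
    # evaluate the spectrum only on the band plus one guard bin each side:
    # peaks inside the band depend on nothing else
    b_lo = max(int(np.argmax(band)) - 1, 0)
    b_hi = min(int(len(band) - np.argmax(band[::-1])) + 1, freqs.size)
    freqs_ext = freqs[b_lo:b_hi]
    band_ext = band[b_lo:b_hi]
    gi_all, fi_all = [], []

    def collect(phi):
        gi, fi = _spectral_peak_freqs(phi, freqs_ext, dt)
        keep = band_ext[fi]
        gi_all.append(gi[keep])
        fi_all.append(fi[keep] + b_lo)

    for method in methods:
        if method == "yule_walker":
            R = _autocovariances(Y, max_order)
            cs, _ = _levinson_all_orders(R, max_order)
            for phi in cs:
                collect(phi)
        elif method == "burg":
            cs, _ = _burg_all_orders(Y, max_order)
            for phi in cs:
                collect(phi)
        elif method in ("mle", "cls"):
            for order in range(1, max_order + 1):
                phi, _ = _cls_ar(Y, order)
                collect(phi)
        else:
            raise InputError(f"unknown AR estimation method {method!r}")

    if not gi_all:
        return np.empty(0, int), np.empty(0)
    gi = np.concatenate(gi_all)
    fi = np.concatenate(fi_all)
    if gi.size == 0:
        return gi, np.empty(0)
    pair = np.unique(np.stack([gi, fi], axis=1), axis=0)
    return pair[:, 0], periods_grid[pair[:, 1]]


def ar_spectral_periods(series, times, period_min=20.0, period_max=28.0,
                        methods=("yule_walker", "burg", "mle"),
                        max_order=None, n_freq=512):
    """Candidate periods (hours) of a single detrended series.

    AR models are fitted at orders 1..len(series)//3 by each estimation
    method; the union of local maxima of their spectral densities falling
    inside [period_min, period_max] is returned, sorted descending in
    period.  May be empty.
    """
    y, squeeze = _as_matrix(series)
    if not squeeze:
        raise InputError("ar_spectral_periods expects a single series")
    t = _check_times(times, y.shape[1])
    gi, per = _candidate_periods_batch(
        y, t, period_min, period_max, methods, max_order, n_freq
    )
    return sorted(float(p) for p in per[gi == 0])


# -- harmonic regression -----------------------------------------------------

def _harmonic_rss(Y, t, tau, sum_y2, trend=False):
    """RSS of per-gene OLS harmonic fits at per-gene periods ``tau``.

    Design is ``[1, cos, sin]`` or, with ``trend=True``, ``[1, t_c, cos,
    sin]`` (centered time; trend and rhythm fitted jointly, which is the
    exact-linear-model form of detrend-then-fit).  Normal equations are
    solved batched.  Returns (rss, beta) with beta columns (mu[, slope],
    a, b).
    """
    w = 2.0 * np.pi / tau[:, None] * t[None, :]
    C = np.cos(w)
    S = np.sin(w)
    n = t.size
    G = tau.size
    k = 4 if trend else 3
    M = np.empty((G, k, k))
    v = np.empty((G, k))
    M[:, 0, 0] = n
    v[:, 0] = Y.sum(axis=1)
    if trend:
        tc = t - t.mean()
        M[:, 0, 1] = M[:, 1, 0] = 0.0  # sum of centered time
        M[:, 1, 1] = tc @ tc
        M[:, 1, 2] = M[:, 2, 1] = C @ tc
        M[:, 1, 3] = M[:, 3, 1] = S @ tc
        v[:, 1] = Y @ tc
    j = k - 2  # cos column
    M[:, 0, j] = M[:, j, 0] = C.sum(axis=1)
    M[:, 0, j + 1] = M[:, j + 1, 0] = S.sum(axis=1)
    M[:, j, j] = np.einsum("ij,ij->i", C, C)
    M[:, j, j + 1] = M[:, j + 1, j] = np.einsum("ij,ij->i", C, S)
    M[:, j + 1, j + 1] = np.einsum("ij,ij->i", S, S)
    v[:, j] = np.einsum("ij,ij->i", Y, C)
    v[:, j + 1] = np.einsum("ij,ij->i", Y, S)
    # guard rank deficiency (period aliasing with the grid)
    scale = np.abs(M).max() or 1.0
    M = M + (1e-12 * scale) * np.eye(k)[None, :, :]
    beta = np.linalg.solve(M, v[:, :, None])[:, :, 0]
    rss = sum_y2 - np.einsum("ij,ij->i", beta, v)
    return np.maximum(rss, 0.0), beta


def _refine_periods(Y, t, tau0, lo, hi, trend=False, iters=45):
    """Batched golden-section minimisation of harmonic RSS over the period.

    Each gene gets its own bracket [lo, hi]; unimodality over the +/-0.5 h
    neighbourhood of the AIC-selected candidate is assumed.
    """
    sum_y2 = np.einsum("ij,ij->i", Y, Y)

    def f(tau):
        rss, _ = _harmonic_rss(Y, t, tau, sum_y2, trend=trend)
        return rss

    a = lo.copy()
    b = hi.copy()
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = f(x1)
    f2 = f(x2)
    for _ in range(iters):
        go_left = f1 < f2
        b = np.where(go_left, x2, b)
        a = np.where(go_left, a, x1)
        x1_new = np.where(go_left, b - _GOLDEN * (b - a), x2)
        x2_new = np.where(go_left, x1, a + _GOLDEN * (b - a))
        fx_new = f(np.where(go_left, x1_new, x2_new))
        f1_old = f1
        f1 = np.where(go_left, fx_new, f2)
        f2 = np.where(go_left, f1_old, fx_new)
        x1, x2 = x1_new, x2_new
    best = np.where(f1 < f2, x1, x2)
    # keep the candidate if refinement did not improve on it
    return np.where(f(best) <= f(tau0), best, tau0)


@dataclass
class _HarmonicFit:
    period: np.ndarray
    mean_level: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    rss: np.ndarray
    pvalue: np.ndarray
    flagged: np.ndarray
    fallback: np.ndarray


def _harmonic_batch(
    Y,
    t,
    cand_gene,
    cand_period,
    fallback_period=24.0,
    refine=True,
    refine_halfwidth=0.5,
    period_min=20.0,
    period_max=28.0,
    trend=False,
) -> _HarmonicFit:
    """AIC-best harmonic regression per gene over its candidate periods.

    With ``trend=True`` the trend and harmonic terms are fitted jointly on
    the raw series and the F-test compares against the trend-only model.
    """
    G, n = Y.shape
    sum_y2 = np.einsum("ij,ij->i", Y, Y)

    has_cand = np.zeros(G, dtype=bool)
    has_cand[cand_gene] = True
    fb_idx = np.nonzero(~has_cand)[0]
    all_gene = np.concatenate([cand_gene, fb_idx])
    all_period = np.concatenate([cand_period, np.full(fb_idx.size, fallback_period)])

    # Evaluate RSS for every (gene, candidate) row, batched by unique period.
    rss_rows = np.empty(all_gene.size)
    uniq, inv = np.unique(all_period, return_inverse=True)
    for u in range(uniq.size):
        rows = np.nonzero(inv == u)[0]
        genes = all_gene[rows]
        r, _ = _harmonic_rss(
            Y[genes], t, np.full(rows.size, uniq[u]), sum_y2[genes], trend=trend
        )
        rss_rows[rows] = r
    # AIC = n log(RSS/n) + 2k with k identical across candidates -> min RSS wins.
    best_rss = np.full(G, np.inf)
    np.minimum.at(best_rss, all_gene, rss_rows)
    is_best = rss_rows <= best_rss[all_gene] * (1 + 1e-12) + 1e-300
    best_period = np.full(G, fallback_period)
    # numpy fancy assignment keeps the last write per index; rows are ordered
    # so the smallest tied period lands last (deterministic tie-break)
    order = np.lexsort((-all_period, ~is_best))
    sel = order[is_best[order]]
    best_period[all_gene[sel]] = all_period[sel]

    if refine and has_cand.any():
        idx = np.nonzero(has_cand)[0]
        tau0 = best_period[idx]
        lo = np.maximum(tau0 - refine_halfwidth, period_min)
        hi = np.minimum(tau0 + refine_halfwidth, period_max)
        best_period[idx] = _refine_periods(Y[idx], t, tau0, lo, hi, trend=trend)

    rss1, beta = _harmonic_rss(Y, t, best_period, sum_y2, trend=trend)
    mu = beta[:, 0]
    a = beta[:, -2]
    b = beta[:, -1]
    amplitude = np.hypot(a, b)
    phase = (best_period / (2.0 * np.pi)) * np.arctan2(b, a) % best_period
    phase = np.where(best_period - phase < 1e-9 * best_period, 0.0, phase)
    if trend:
        resid0 = linear_detrend(Y, t)
        rss0 = np.einsum("ij,ij->i", resid0, resid0)
        df2 = n - 4
    else:
        rss0 = sum_y2 - Y.sum(axis=1) ** 2 / n
        df2 = n - 3
    if df2 < 1:
        # saturated model: no residual degrees of freedom, no test possible
        return _HarmonicFit(
            period=best_period, mean_level=mu, amplitude=amplitude,
            phase=phase, rss=rss1, pvalue=np.ones(G),
            flagged=np.ones(G, dtype=bool), fallback=~has_cand,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    # F = +inf (perfect fit) is a legitimate zero p-value; only NaN (0/0,
    # i.e. a constant or exactly-linear series) marks a degenerate gene
    flagged = np.isnan(F) | (rss0 <= 1e-12 * np.maximum(sum_y2, 1.0))
    pvalue = np.ones(G)
    ok = ~flagged
    pvalue[ok] = stats.f.sf(np.maximum(F[ok], 0.0), 2, df2)
    return _HarmonicFit(
        period=best_period,
        mean_level=mu,
        amplitude=amplitude,
        phase=phase,
        rss=rss1,
        pvalue=pvalue,
        flagged=flagged,
        fallback=~has_cand,
    )


def harmonic_regression(series, times, periods):
    """Fit ``y ~ mu + a cos + b sin`` at each candidate period; keep the best.

    Model selection is by minimum AIC (equivalently minimum RSS, the
    parameter count being equal); returns
    ``(period, amplitude, phase, mean_level, pvalue)`` with the p-value from
    the F-test of the harmonic pair against the intercept-only model.
    """
    y, squeeze = _as_matrix(series)
    if not squeeze:
        raise InputError("harmonic_regression expects a single series")
    t = _check_times(times, y.shape[1])
    periods = np.asarray(periods, dtype=float)
    if periods.size == 0:
        raise InputError("periods must be non-empty")
    gene = np.zeros(periods.size, dtype=int)
    fit = _harmonic_batch(y, t, gene, periods, refine=False,
                          period_min=periods.min(), period_max=periods.max())
    return (
        float(fit.period[0]),
        float(fit.amplitude[0]),
        float(fit.phase[0]),
        float(fit.mean_level[0]),
        float(fit.pvalue[0]),
    )


def bh_fdr(pvalues):
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# detector estimators
# ---------------------------------------------------------------------------

def _coerce_input(X, times):
    if isinstance(X, ExpressionDataset):
        if X.n_replicates != 1:
            raise InputError(
                "detectors run on single-replicate data; index a replicate, "
                "average, or resample first"
            )
        return X.replicate(0), X.timepoints, list(X.gene_ids)
    Y = np.asarray(X, dtype=float)
    if Y.ndim != 2:
        raise InputError("expected a 2-D gene x timepoint matrix")
    if times is None:
        raise InputError("sampling times (hours) are required")
    t = _check_times(times, Y.shape[1])
    return Y, t, None


class _DetectorBase(BaseEstimator):
    """Shared plumbing: input coercion, fitted-result table, fit_predict."""

    _result_fields: tuple[str, ...] = ()

    def fit_predict(self, X, times=None):
        return self.fit(X, times=times).rhythmic_

    def results_frame(self) -> pd.DataFrame:
        data = {"rhythmic": self.rhythmic_}
        for name in self._result_fields:
            data[name] = getattr(self, name + "_")
        idx = self.gene_ids_ if self.gene_ids_ is not None else pd.RangeIndex(
            len(self.rhythmic_)
        )
        df = pd.DataFrame(data, index=idx)
        df.index.name = "gene_id"
        return df


class ArserDetector(_DetectorBase):
    """AR-spectrum + harmonic-regression rhythmicity test with FDR control.

    Parameters
    ----------
    period_min, period_max : float
        Period band searched, hours (default [20, 28]).
    q_threshold : float
        BH q-value cutoff for calling a gene rhythmic (default 0.05).
    ar_methods : tuple of str
        AR estimation methods pooled for candidate periods; any of
        'yule_walker', 'burg', 'mle' (conditional least squares).
    max_order : int or None
        Maximum AR order; default ``n_timepoints // 3``.
    n_freq : int
        Size of the spectral frequency grid.
    fallback_period : float
        Period tested when no spectral peak falls inside the band.
    refine : bool
        Refine the selected period by minimising the harmonic RSS within
        +/-0.5 h of the spectral candidate.
    """

    _result_fields = (
        "period", "amplitude", "phase", "mean_level", "pvalue", "qvalue",
    )

    def __init__(
        self,
        period_min=20.0,
        period_max=28.0,
        q_threshold=0.05,
        ar_methods=("yule_walker", "burg", "mle"),
        max_order=None,
        n_freq=512,
        fallback_period=24.0,
        refine=True,
    ):
        self.period_min = period_min
        self.period_max = period_max
        self.q_threshold = q_threshold
        self.ar_methods = ar_methods
        self.max_order = max_order
        self.n_freq = n_freq
        self.fallback_period = fallback_period
        self.refine = refine

    def fit(self, X, times=None):
        Y, t, gene_ids = _coerce_input(X, times)
        self.gene_ids_ = gene_ids
        self.times_ = t
        D = linear_detrend(Y, t)
        gi, per = _candidate_periods_batch(
            D, t, self.period_min, self.period_max,
            self.ar_methods, self.max_order, self.n_freq,
        )
        # final model: trend and harmonic fitted jointly on the raw series
        # (the exact linear-model form of detrend-then-fit)
        fit = _harmonic_batch(
            Y, t, gi, per,
            fallback_period=self.fallback_period,
            refine=self.refine,
            period_min=self.period_min,
            period_max=self.period_max,
            trend=True,
        )
        self.period_ = fit.period
        self.amplitude_ = fit.amplitude
        self.phase_ = fit.phase
        self.mean_level_ = fit.mean_level
        self.pvalue_ = fit.pvalue
        self.qvalue_ = bh_fdr(fit.pvalue)
        self.flagged_ = fit.flagged
        self.fallback_ = fit.fallback
        self.rhythmic_ = (self.qvalue_ <= self.q_threshold) & ~fit.flagged
        return self


# -- HAYSTACK ----------------------------------------------------------------

def _shape_cosine(u, dt_frac):
    return np.cos(2.0 * np.pi * u)


def _shape_sine(u, dt_frac):
    return np.sin(2.0 * np.pi * u)


def _shape_box(u, dt_frac):
    return np.where(u < 0.5, 1.0, -1.0)


def _shape_spike(u, dt_frac):
    # 1 at the grid point nearest the phase origin in each cycle, 0 elsewhere
    d = np.abs(((u + 0.5) % 1.0) - 0.5)
    return (d <= d.min() + 1e-12).astype(float)


def _shape_rigid(u, dt_frac):
    # cosine with troughs clipped at its own 25th percentile (cos 135 deg)
    return np.maximum(np.cos(2.0 * np.pi * u), np.cos(0.75 * np.pi))


def _shape_asymmetric(u, dt_frac):
    # sawtooth: rise over the first third of the cycle, fall over the rest
    return np.where(u < 1.0 / 3.0, -1.0 + 6.0 * u, 1.0 - 3.0 * (u - 1.0 / 3.0))


DEFAULT_SHAPES = {
    "asymmetric": _shape_asymmetric,
    "box-like": _shape_box,
    "cosine": _shape_cosine,
    "rigid": _shape_rigid,
    "sine": _shape_sine,
    "spike": _shape_spike,
}


@dataclass
class PatternEntry:
    shape: str
    phase: float
    vector: np.ndarray = field(repr=False)


@dataclass
class PatternLibrary:
    """Centered, unit-norm periodic templates sampled on the dataset grid.

    Entries are ordered by (phase, shape) so that ties in best-pattern
    selection resolve to the lowest phase shift, then lexicographic shape.
    """

    entries: list[PatternEntry]
    timepoints: np.ndarray

    def __len__(self):
        return len(self.entries)

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([e.vector for e in self.entries])


def build_pattern_library(
    timepoints, shapes=None, phase_step=1.0, period=24.0
) -> PatternLibrary:
    """Sample every (shape, phase shift) template at the dataset timepoints.

    Templates are ``period``-periodic, shifted on ``[0, period)`` at
    ``phase_step``, centered and normalised to unit norm; templates that are
    constant on the grid are excluded with a warning.
    """
    t = np.asarray(timepoints, dtype=float)
    dt = _uniform_interval(t)
    if shapes is None:
        shapes = DEFAULT_SHAPES
    entries = []
    for phase in np.arange(0.0, period, phase_step):
        for name in sorted(shapes):
            fn = shapes[name]
            u = ((t - phase) % period) / period
            v = np.asarray(fn(u, dt / period), dtype=float)
            v = v - v.mean()
            nrm = np.linalg.norm(v)
            if nrm < 1e-9:
                warnings.warn(
                    f"pattern {name!r} at phase {phase:g} h is constant on "
                    "this sampling grid; excluded",
                    stacklevel=2,
                )
                continue
            entries.append(PatternEntry(name, float(phase), v / nrm))
    return PatternLibrary(entries, t)


class HaystackDetector(_DetectorBase):
    """Pattern-correlation rhythmicity classifier.

    A gene is rhythmic iff its best Pearson correlation against the template
    library reaches ``corr_cut``, its fold change (row max over row min,
    after flooring values below ``background_cut`` times the dataset's 95th
    percentile) reaches ``fold_cut``, and the correlation p-value (t-
    distribution transform, n-2 df, two-sided) is at most ``p_cut``.
    """

    _result_fields = ("best_pattern", "best_phase", "correlation",
                      "fold_change", "pvalue")

    def __init__(
        self,
        p_cut=0.05,
        fold_cut=2.0,
        corr_cut=0.8,
        background_cut=0.01,
        phase_step=1.0,
        period=24.0,
        shapes=None,
        library=None,
    ):
        self.p_cut = p_cut
        self.fold_cut = fold_cut
        self.corr_cut = corr_cut
        self.background_cut = background_cut
        self.phase_step = phase_step
        self.period = period
        self.shapes = shapes
        self.library = library

    def fit(self, X, times=None):
        Y, t, gene_ids = _coerce_input(X, times)
        self.gene_ids_ = gene_ids
        self.times_ = t
        lib = self.library
        if lib is None:
            lib = build_pattern_library(
                t, shapes=self.shapes, phase_step=self.phase_step,
                period=self.period,
            )
        elif not np.allclose(lib.timepoints, t):
            raise InputError("pattern library was built on different timepoints")
        self.library_ = lib
        L = lib.matrix
        Yc = Y - Y.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Yc, axis=1)
        flagged = norms < 1e-12
        safe = np.where(flagged, 1.0, norms)
        R = (Yc / safe[:, None]) @ L.T
        best = np.argmax(R, axis=1)
        r = np.clip(R[np.arange(Y.shape[0]), best], -1.0, 1.0)
        n = t.size
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
        floor = max(self.background_cut * np.percentile(Y, 95.0), 1e-12)
        Yf = np.maximum(Y, floor)
        fold = Yf.max(axis=1) / Yf.min(axis=1)
        self.correlation_ = np.where(flagged, np.nan, r)
        self.best_pattern_ = np.array([lib.entries[i].shape for i in best])
        self.best_phase_ = np.array([lib.entries[i].phase for i in best])
        self.fold_change_ = fold
        self.pvalue_ = np.where(flagged, 1.0, pval)
        self.flagged_ = flagged
        self.rhythmic_ = (
            (self.correlation_ >= self.corr_cut)
            & (fold >= self.fold_cut)
            & (self.pvalue_ <= self.p_cut)
            & ~flagged
        )
        return self


# -- FFT-NLLS ----------------------------------------------------------------

def _fftnlls_single(y, t, dt, period_min, period_max, conf):
    """Constrained cosine fit of one series, trend fitted jointly.

    Fitting the linear trend inside the model (rather than subtracting an
    OLS line first) keeps a trend-free cosine exactly representable; the
    initialisation still comes from the Fourier spectrum of the detrended
    series.
    """
    n = t.size
    tc = t - t.mean()
    X = np.column_stack([np.ones(n), tc])
    b_lin = np.linalg.lstsq(X, y, rcond=None)[0]
    y_det = y - X @ b_lin
    coef = np.fft.rfft(y_det)
    freqs = np.fft.rfftfreq(n, d=dt)
    amps = np.abs(coef) * 2.0 / n
    amps[0] = 0.0
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    in_band = (periods >= period_min) & (periods <= period_max)
    if in_band.any():
        k = int(np.flatnonzero(in_band)[np.argmax(amps[in_band])])
    else:
        k = int(np.argmax(amps))
    tau0 = float(np.clip(periods[k], period_min, period_max))
    a0 = max(float(amps[k]), 1e-6)
    phi0 = float((-np.angle(coef[k]) / (2.0 * np.pi)) % 1.0) * tau0

    def resid(p):
        tau, amp, phi, mu, slope = p
        return mu + slope * tc + amp * np.cos(2.0 * np.pi * (t - phi) / tau) - y

    res = least_squares(
        resid,
        x0=[tau0, a0, phi0, float(b_lin[0]), float(b_lin[1])],
        bounds=([period_min, 0.0, -np.inf, -np.inf, -np.inf],
                [period_max, np.inf, np.inf, np.inf, np.inf]),
        method="trf",
        max_nfev=300,
    )
    tau, amp, phi, mu, _slope = res.x
    out = {
        "period": tau,
        "amplitude": amp,
        "phase": phi % tau,
        "mean_level": mu,
        "converged": bool(res.success),
        "rae": np.inf,
    }
    if not res.success:
        return out
    dof = n - 5
    if dof <= 0:
        return out
    J = res.jac
    JTJ = J.T @ J
    try:
        cov = np.linalg.inv(JTJ) * (2.0 * res.cost / dof)
    except np.linalg.LinAlgError:
        return out
    se_amp = float(np.sqrt(max(cov[1, 1], 0.0)))
    half = stats.t.ppf(0.5 + conf / 2.0, dof) * se_amp
    out["rae"] = half / amp if amp > 0 else np.inf
    return out


class FftNllsDetector(_DetectorBase):
    """Discrete-Fourier-initialised cosine NLLS fit with an RAE call rule.

    A single cosine ``A cos(2 pi (t - phi)/tau)`` plus a linear trend is
    fitted with ``tau`` constrained to the period band, initialised from
    the dominant Fourier component of the detrended series nearest the
    band (detrending enters the model as the jointly fitted trend).  A
    gene is rhythmic iff the fit converges and the relative amplitude error
    (95% confidence half-width over amplitude, from the linearised
    covariance at the optimum) is below ``rae_threshold``.
    """

    _result_fields = ("period", "amplitude", "phase", "mean_level", "rae")

    def __init__(self, period_min=20.0, period_max=28.0, rae_threshold=0.5,
                 conf_level=0.95, n_jobs=None):
        self.period_min = period_min
        self.period_max = period_max
        self.rae_threshold = rae_threshold
        self.conf_level = conf_level
        self.n_jobs = n_jobs

    def fit(self, X, times=None):
        Y, t, gene_ids = _coerce_input(X, times)
        self.gene_ids_ = gene_ids
        self.times_ = t
        dt = _uniform_interval(t)
        args = (t, dt, self.period_min, self.period_max, self.conf_level)
        if self.n_jobs and self.n_jobs != 1:
            from joblib import Parallel, delayed

            rows = Parallel(n_jobs=self.n_jobs)(
                delayed(_fftnlls_single)(y, *args) for y in Y
            )
        else:
            rows = [_fftnlls_single(y, *args) for y in Y]
        for name in ("period", "amplitude", "phase", "mean_level", "rae"):
            setattr(self, name + "_", np.array([row[name] for row in rows]))
        self.converged_ = np.array([row["converged"] for row in rows])
        self.flagged_ = ~self.converged_
        self.rhythmic_ = self.converged_ & (self.rae_ < self.rae_threshold)
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

_DETECTORS = {
    "arser": ArserDetector,
    "haystack": HaystackDetector,
    "fftnlls": FftNllsDetector,
}


def make_detector(method: str, **params) -> _DetectorBase:
    """Instantiate a detector by name ('arser', 'haystack', 'fftnlls')."""
    try:
        cls = _DETECTORS[method]
    except KeyError:
        raise InputError(f"unknown detector {method!r}") from None
    return cls(**params)


def arser_detect(X, times=None, q_threshold=0.05, **params) -> pd.DataFrame:
    """Run the AR-spectrum/harmonic-regression pipeline; per-gene table."""
    return ArserDetector(q_threshold=q_threshold, **params).fit(
        X, times=times
    ).results_frame()


def haystack_detect(X, times=None, library=None, **params) -> pd.DataFrame:
    """Run the pattern-correlation classifier; per-gene table."""
    return HaystackDetector(library=library, **params).fit(
        X, times=times
    ).results_frame()


def fftnlls_detect(X, times=None, **params) -> pd.DataFrame:
    """Run the constrained cosine NLLS fit; per-gene table."""
    return FftNllsDetector(**params).fit(X, times=times).results_frame()
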