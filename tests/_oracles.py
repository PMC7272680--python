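"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they check: Pearson r is the
textbook covariance/sigma-sigma formula, correlation p-values go through
the regularized incomplete beta function or direct quadrature of the t
density, and studentized-range quantiles come from Gauss-Legendre
integration of the range distribution — not from scipy.stats.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import betainc, ndtr

# ---------------------------------------------------------------- Pearson


def pearson_brute(x, y) -> float:
    """Textbook covariance / (sigma_x * sigma_y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    cov = np.sum((x - x.mean()) * (y - y.mean())) / n
    sx = math.sqrt(np.sum((x - x.mean()) ** 2) / n)
    sy = math.sqrt(np.sum((y - y.mean()) ** 2) / n)
    if sx == 0 or sy == 0:
        return float("nan")
    return cov / (sx * sy)


def pvalue_beta(r: float, n: int) -> float:
    """Two-tailed p via the incomplete-beta identity for the t tail."""
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t2 = r * r * df / (1.0 - r * r)
    return float(betainc(df / 2.0, 0.5, df / (df + t2)))


def t_tail_quad(t_value: float, df: int) -> float:
    """Two-tailed t tail by direct quadrature of the explicit density."""
    c = math.gamma((df + 1) / 2.0) / (math.sqrt(df * math.pi) * math.gamma(df / 2.0))

    def pdf(x):
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2.0)

    tail, _ = quad(pdf, abs(t_value), np.inf, epsabs=1e-13, epsrel=1e-13)
    return 2.0 * tail


def pvalue_quad(r: float, n: int) -> float:
    df = n - 2
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    return t_tail_quad(t, df)


# --------------------------------------------- studentized range quantile

_NODES, _WEIGHTS = leggauss(240)


def _range_cdf_normal(w: np.ndarray, k: int) -> np.ndarray:
    """P(range of k iid standard normals <= w) for an array of w >= 0."""
    z = 9.0 * _NODES  # integration over z in [-9, 9]
    zw = 9.0 * _WEIGHTS
    phi = np.exp(-0.5 * z**2) / math.sqrt(2.0 * math.pi)
    big_phi = ndtr(z)
    w = np.atleast_1d(np.asarray(w, float))
    inner = np.clip(big_phi[:, None] - ndtr(z[:, None] - w[None, :]), 0.0, 1.0)
    return k * np.einsum("i,i,ij->j", zw, phi, inner ** (k - 1))


def studentized_range_cdf(q: float, k: int, df: int) -> float:
    """CDF of the studentized range by nested Gauss-Legendre quadrature."""
    s = 2.0 * (_NODES + 1.0)  # s in (0, 4]
    sw = 2.0 * _WEIGHTS
    log_c = (
        math.log(2.0)
        + (df / 2.0) * math.log(df)
        - (df / 2.0) * math.log(2.0)
        - math.lgamma(df / 2.0)
    )
    log_fs = log_c + (df - 1) * np.log(s) - df * s**2 / 2.0
    fs = np.exp(log_fs)
    inner = _range_cdf_normal(q * s, k)
    return float(np.sum(sw * fs * inner))


def studentized_range_quantile(alpha: float, k: int, df: int) -> float:
    """Upper-alpha quantile q such that P(Q > q) = alpha."""
    target = 1.0 - alpha
    return brentq(lambda q: studentized_range_cdf(q, k, df) - target, 0.2, 40.0, xtol=1e-8)


# ---------------------------------------------------------------- filter


def dual_filter_brute(r: float, p: float, alpha: float, r_min: float, sign_mode: str) -> int:
    """Independent per-pair re-statement of the edge criterion."""
    if math.isnan(r) or math.isnan(p):
        return 0
    magnitude_ok = (r >= r_min) if sign_mode == "positive_only" else (abs(r) >= r_min)
    return int(p < alpha and magnitude_ok)
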