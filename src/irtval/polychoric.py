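"""Two-step maximum-likelihood polychoric correlations.

Step 1 estimates each item's thresholds from its margins (inverse normal
of cumulative proportions); step 2 maximizes each pair's bivariate-normal
likelihood over the correlation with thresholds held fixed.  The bivariate
normal CDF is evaluated by Gauss-Legendre integration of Plackett's
identity, which also yields the score dpi/drho = difference of bivariate
densities used for the asymptotic variance of each estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .banks import ResponseMatrix

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def bivariate_normal_cdf(h, k, rho: float) -> np.ndarray:
    """P(Z1 <= h, Z2 <= k) for standard bivariate normal with correlation rho.

    Vectorized over ``h``/``k`` via ``Phi(h)Phi(k) + int_0^rho phi2(h,k;r) dr``.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    base = norm.cdf(h) * norm.cdf(k)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)  # map [-1,1] -> [0, rho]
    w = 0.5 * rho * _GL_WEIGHTS
    hh = h[..., None]
    kk = k[..., None]
    om = 1.0 - r**2
    dens = np.exp(-(hh**2 - 2.0 * r * hh * kk + kk**2) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )
    return base + np.sum(w * dens, axis=-1)


def _bivariate_normal_pdf(h, k, rho: float) -> np.ndarray:
    om = 1.0 - rho**2
    return np.exp(-(h**2 - 2.0 * rho * h * k + k**2) / (2.0 * om)) / (
        2.0 * np.pi * np.sqrt(om)
    )


def estimate_thresholds(counts: np.ndarray) -> np.ndarray:
    """Normal thresholds from marginal category counts (length K-1)."""
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    return norm.ppf(np.clip(cum, 1e-10, 1 - 1e-10))


def _cell_probs(tau_i: np.ndarray, tau_j: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of the (K_i x K_j) table under the BVN model."""
    ti = np.concatenate([[-np.inf], tau_i, [np.inf]])
    tj = np.concatenate([[-np.inf], tau_j, [np.inf]])
    # CDF grid; infinite bounds handled via univariate margins
    H, Kk = np.meshgrid(ti, tj, indexing="ij")
    C = np.where(
        np.isinf(H) & (H < 0) | np.isinf(Kk) & (Kk < 0),
        0.0,
        np.where(
            np.isinf(H) & (H > 0),
            norm.cdf(Kk),
            np.where(
                np.isinf(Kk) & (Kk > 0),
                norm.cdf(H),
                bivariate_normal_cdf(np.where(np.isinf(H), 0.0, H),
                                     np.where(np.isinf(Kk), 0.0, Kk), rho),
            ),
        ),
    )
    C[-1, -1] = 1.0
    P = C[1:, 1:] - C[:-1, 1:] - C[1:, :-1] + C[:-1, :-1]
    return np.clip(P, 1e-12, None)


def polychoric_pair(table: np.ndarray) -> tuple[float, float]:
    """ML polychoric correlation and its asymptotic variance from a
    two-way contingency table of counts."""
    table = np.asarray(table, dtype=float)
    tau_i = estimate_thresholds(table.sum(axis=1))
    tau_j = estimate_thresholds(table.sum(axis=0))

    def negll(rho: float) -> float:
        P = _cell_probs(tau_i, tau_j, rho)
        return -float(np.sum(table * np.log(P)))

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(res.x)

    # Fisher information in rho via Plackett's identity: dP_cell/drho is a
    # difference of bivariate densities at the cell corners.
    ti = np.concatenate([[-np.inf], tau_i, [np.inf]])
    tj = np.concatenate([[-np.inf], tau_j, [np.inf]])
    H, Kk = np.meshgrid(ti, tj, indexing="ij")
    D = np.where(np.isinf(H) | np.isinf(Kk), 0.0,
                 _bivariate_normal_pdf(np.where(np.isinf(H), 0.0, H),
                                       np.where(np.isinf(Kk), 0.0, Kk), rho))
    dP = D[1:, 1:] - D[:-1, 1:] - D[1:, :-1] + D[:-1, :-1]
    P = _cell_probs(tau_i, tau_j, rho)
    n = table.sum()
    info = n * float(np.sum(dP**2 / P))
    avar = 1.0 / info if info > 0 else np.inf
    return rho, avar


@dataclass
class PolychoricResult:
    """Pairwise polychoric correlation matrix with thresholds and
    asymptotic variances (diagonal weights for DWLS fitting)."""

    correlations: pd.DataFrame
    thresholds: dict[str, np.ndarray]
    avar: pd.DataFrame
    smoothed: bool


def smooth_psd(R: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Eigenvalue clipping to restore positive semi-definiteness, followed
    by re-normalization to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= eps:
        return R, False
    vals = np.clip(vals, eps, None)
    S = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S, True


def polychoric_matrix(responses) -> PolychoricResult:
    """Pairwise polychoric correlations of an ordinal response matrix.

    Items with a single observed category are rejected (their thresholds
    are undefined).  The returned matrix is PSD-smoothed if necessary.
    """
    df = responses.data if isinstance(responses, ResponseMatrix) else pd.DataFrame(responses)
    ids = list(df.columns)
    p = len(ids)
    if p < 2:
        raise ValueError("need at least two items")
    if df.isna().any().any():
        raise ValueError("polychoric correlations require complete data")
    codes = {}
    thresholds = {}
    for c in ids:
        vals = df[c].to_numpy()
        uniq = np.unique(vals)
        if len(uniq) < 2:
            raise ValueError(f"item {c!r} has a single observed category")
        # contiguous codes in observed-category order
        codes[c] = np.searchsorted(uniq, vals)
        counts = np.bincount(codes[c], minlength=len(uniq))
        thresholds[c] = estimate_thresholds(counts)

    R = np.eye(p)
    A = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = codes[ids[i]], codes[ids[j]]
            Ki = xi.max() + 1
            Kj = xj.max() + 1
            table = np.zeros((Ki, Kj))
            np.add.at(table, (xi, xj), 1.0)
            rho, avar = polychoric_pair(table)
            R[i, j] = R[j, i] = rho
            A[i, j] = A[j, i] = avar

    R, smoothed = smooth_psd(R)
    return PolychoricResult(
        correlations=pd.DataFrame(R, index=ids, columns=ids),
        thresholds=thresholds,
        avar=pd.DataFrame(A, index=ids, columns=ids),
        smoothed=smoothed,
    )
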