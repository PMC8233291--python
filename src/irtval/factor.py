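"""Factor-analytic dimensionality checks on polychoric correlations.

A one-factor model fitted by diagonally weighted least squares (weights =
inverse asymptotic variances of the polychoric estimates) yields unscaled
CFI/TLI/RMSEA/SRMR against the zero-correlation baseline, plus the
residual correlations used for the local-independence rule (flag pairs
with |residual| >= 0.20).  When one-factor fit is insufficient, a bifactor
summary (hierarchical omega, explained common variance) judges whether a
general factor still dominates: omega_h > 0.80 and ECV > 0.60.

Mean-and-variance scaling corrections of the test statistic (WLSMV-style)
are intentionally not applied; the indices here are the plain DWLS ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from sklearn.base import BaseEstimator

from .banks import ResponseMatrix
from .polychoric import PolychoricResult, polychoric_matrix


@dataclass
class FitIndices:
    chi_square: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    srmr: float

    def meets_criteria(self, cfi_min: float = 0.95, tli_min: float = 0.95,
                       rmsea_max: float = 0.08, srmr_max: float = 0.10) -> dict[str, bool]:
        return {
            "cfi": self.cfi > cfi_min,
            "tli": self.tli > tli_min,
            "rmsea": self.rmsea < rmsea_max,
            "srmr": self.srmr < srmr_max,
        }


@dataclass
class BifactorSummary:
    omega_h: float
    ecv: float
    general_loadings: pd.Series
    specific_loadings: pd.DataFrame
    route: str  # "confirmatory" or "schmid-leiman"

    def meets_criteria(self, omega_min: float = 0.80, ecv_min: float = 0.60) -> dict[str, bool]:
        return {"omega_h": self.omega_h > omega_min, "ecv": self.ecv > ecv_min}


def _fit_indices(T: float, df: int, Tb: float, dfb: int, n: int,
                 resid: np.ndarray, p: int) -> FitIndices:
    d = max(T - df, 0.0)
    db = max(Tb - dfb, 0.0)
    cfi = 1.0 - d / max(db, d, np.finfo(float).tiny)
    if df > 0 and dfb > 0 and Tb / dfb > 1.0:
        tli = ((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0)
    else:
        tli = 1.0
    rmsea = np.sqrt(d / (df * max(n - 1, 1))) if df > 0 else 0.0
    iu = np.triu_indices(p, k=1)
    srmr = np.sqrt((np.sum(resid[iu] ** 2)) / (p * (p + 1) / 2.0))
    return FitIndices(chi_square=T, df=df, cfi=min(cfi, 1.0), tli=min(tli, 1.0),
                      rmsea=rmsea, srmr=srmr)


class OneFactorModel(BaseEstimator):
    """One-factor CFA on the polychoric matrix, fitted by DWLS.

    fit(X) accepts a ResponseMatrix/DataFrame of ordinal responses or a
    precomputed :class:`PolychoricResult`.  Fitted attributes:
    ``loadings_``, ``indices_``, ``residuals_`` (observed - implied
    correlations), ``heywood_items_``.
    """

    def __init__(self, sample_size: int | None = None):
        self.sample_size = sample_size

    def fit(self, X, y=None) -> "OneFactorModel":
        if isinstance(X, PolychoricResult):
            poly = X
            n = self.sample_size
            if n is None:
                raise ValueError("sample_size is required with a precomputed matrix")
        else:
            poly = polychoric_matrix(X)
            n = len(X.data) if isinstance(X, ResponseMatrix) else len(X)
        R = poly.correlations.to_numpy()
        ids = list(poly.correlations.columns)
        p = len(ids)
        if p < 3:
            raise ValueError("one-factor identification requires >= 3 items")
        W = 1.0 / np.clip(poly.avar.to_numpy(), 1e-12, None)
        iu = np.triu_indices(p, k=1)
        w = W[iu]
        r = R[iu]

        # Loadings are estimated by *unweighted* least squares: precision
        # weights would chase the most-correlated (possibly locally
        # dependent) pairs and absorb exactly the residuals the
        # local-independence check needs to see.  The test statistic below
        # is still evaluated in the DWLS metric.
        def residuals(lam: np.ndarray) -> np.ndarray:
            return r - (np.outer(lam, lam))[iu]

        def jac(lam: np.ndarray) -> np.ndarray:
            J = np.zeros((len(r), p))
            for idx, (i, j) in enumerate(zip(*iu)):
                J[idx, i] = -lam[j]
                J[idx, j] = -lam[i]
            return J

        # start from the first principal component
        vals, vecs = np.linalg.eigh(R)
        lam0 = np.clip(vecs[:, -1] * np.sqrt(vals[-1]), -0.95, 0.95)
        if lam0.sum() < 0:
            lam0 = -lam0
        sol = least_squares(residuals, lam0, jac=jac, method="lm", xtol=1e-12)
        lam = sol.x

        self.heywood_items_ = [ids[i] for i in np.where(np.abs(lam) > 1.0)[0]]
        if self.heywood_items_:
            warnings.warn(f"Heywood cases (|loading| > 1): {self.heywood_items_}")
        lam_resid = np.clip(lam, -1.0, 1.0)  # clipped only for residuals

        T = float(np.sum(w * residuals(lam) ** 2))
        df = p * (p + 1) // 2 - 2 * p
        Tb = float(np.sum(w * r**2))
        dfb = p * (p - 1) // 2
        resid = R - np.outer(lam_resid, lam_resid)
        np.fill_diagonal(resid, 0.0)

        self.item_ids_ = ids
        self.n_ = n
        self.polychoric_ = poly
        self.loadings_ = pd.Series(lam, index=ids)
        self.residuals_ = pd.DataFrame(resid, index=ids, columns=ids)
        self.indices_ = _fit_indices(T, df, Tb, dfb, n, resid, p)
        return self


def fit_one_factor(responses) -> tuple[FitIndices, pd.Series, pd.DataFrame]:
    """One-factor DWLS fit: indices, loadings, residual correlations."""
    m = OneFactorModel().fit(responses)
    return m.indices_, m.loadings_, m.residuals_


def check_local_independence(residuals: pd.DataFrame,
                             threshold: float = 0.20) -> list[tuple[str, str, float]]:
    """Item pairs whose |residual correlation| >= threshold (default 0.20,
    i.e. residuals strictly below 0.20 pass)."""
    ids = list(residuals.columns)
    out = []
    arr = residuals.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(arr[i, j]) >= threshold:
                out.append((ids[i], ids[j], float(arr[i, j])))
    return out


# ---------------------------------------------------------------------------
# Bifactor
# ---------------------------------------------------------------------------

def _principal_axis(R: np.ndarray, m: int, max_iter: int = 200,
                    tol: float = 1e-8) -> np.ndarray:
    """Iterated principal-axis EFA with SMC-start communalities."""
    p = R.shape[0]
    Rinv = np.linalg.pinv(R)
    h2 = np.clip(1.0 - 1.0 / np.diag(Rinv), 0.05, 0.995)
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        vals, vecs = np.linalg.eigh(Rh)
        idx = np.argsort(vals)[::-1][:m]
        L = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
        h2_new = np.clip(np.sum(L**2, axis=1), 0.0, 0.995)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    return L


def _varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    p, m = L.shape
    Rot = np.eye(m)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ Rot
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - (Lr * np.sum(Lr**2, axis=0)) / p)
        )
        Rot = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return L @ Rot


def _promax(L: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation: pattern matrix and factor correlations."""
    V = _varimax(L)
    # column signs: make each factor's loading sum positive
    signs = np.sign(V.sum(axis=0))
    signs[signs == 0] = 1.0
    V = V * signs
    target = np.abs(V) ** power * np.sign(V)
    coef, *_ = np.linalg.lstsq(V, target, rcond=None)
    # normalize so factor variances are 1
    d = np.sqrt(np.diag(np.linalg.pinv(coef.T @ coef)))
    coef = coef * d
    pattern = V @ coef
    phi = np.linalg.pinv(coef.T @ coef)
    return pattern, phi


def schmid_leiman(R: np.ndarray, n_specific: int) -> tuple[np.ndarray, np.ndarray]:
    """Schmid-Leiman transformation: general and specific loadings from an
    exploratory m-factor solution with a single second-order factor."""
    L1 = _principal_axis(R, n_specific)
    pattern, phi = _promax(L1)
    # second-order one-factor on the factor correlations
    g2 = _principal_axis(phi, 1).ravel()
    g2 = np.clip(np.abs(g2), 0.0, 0.999)  # sign-free second-order loadings
    general = pattern @ g2
    specific = pattern * np.sqrt(1.0 - g2**2)[None, :]
    return general, specific


def bifactor_indices(general: np.ndarray, specific: np.ndarray
                     ) -> tuple[float, float]:
    """Hierarchical omega and explained common variance from bifactor
    loadings.

    omega_h = (sum lambda_g)^2 / total variance;
    ECV = sum lambda_g^2 / (sum lambda_g^2 + sum sum lambda_s^2).
    With all specific loadings zero, ECV = 1 exactly.
    """
    general = np.asarray(general, dtype=float)
    specific = np.atleast_2d(np.asarray(specific, dtype=float))
    sum_g = float(np.sum(general))
    sum_g2 = float(np.sum(general**2))
    sum_s2 = float(np.sum(specific**2))
    col_sums = specific.sum(axis=0)
    h2 = np.clip(general**2 + np.sum(specific**2, axis=1), 0.0, 1.0)
    var_total = sum_g**2 + float(np.sum(col_sums**2)) + float(np.sum(1.0 - h2))
    omega_h = sum_g**2 / var_total if var_total > 0 else 0.0
    ecv = sum_g2 / (sum_g2 + sum_s2) if (sum_g2 + sum_s2) > 0 else 0.0
    return float(np.clip(omega_h, 0.0, 1.0)), float(np.clip(ecv, 0.0, 1.0))


class BifactorModel(BaseEstimator):
    """Bifactor summary (omega_h, ECV) of ordinal response data.

    With ``specific_assignment`` (mapping factor name -> item ids), an
    orthogonal confirmatory bifactor model is fitted by DWLS; without it,
    an exploratory Schmid-Leiman transformation with ``n_specific`` group
    factors is used.
    """

    def __init__(self, specific_assignment: dict[str, list[str]] | None = None,
                 n_specific: int = 3, sample_size: int | None = None):
        self.specific_assignment = specific_assignment
        self.n_specific = n_specific
        self.sample_size = sample_size

    def fit(self, X, y=None) -> "BifactorModel":
        poly = X if isinstance(X, PolychoricResult) else polychoric_matrix(X)
        R = poly.correlations.to_numpy()
        ids = list(poly.correlations.columns)
        p = len(ids)

        if self.specific_assignment is not None:
            assign = self.specific_assignment
            if len(assign) < 2:
                raise ValueError("need >= 2 specific factors")
            for name, members in assign.items():
                if len(members) < 2:
                    raise ValueError(f"specific factor {name!r} has < 2 items (unidentified)")
                unknown = set(members) - set(ids)
                if unknown:
                    raise ValueError(f"specific factor {name!r}: unknown items {sorted(unknown)}")
            fac_names = list(assign)
            fac_of_item = np.full(p, -1)
            for fi, name in enumerate(fac_names):
                for it in assign[name]:
                    fac_of_item[ids.index(it)] = fi
            iu = np.triu_indices(p, k=1)
            W = 1.0 / np.clip(poly.avar.to_numpy(), 1e-12, None)
            w = W[iu]
            r = R[iu]
            same = fac_of_item[iu[0]] == fac_of_item[iu[1]]
            both = same & (fac_of_item[iu[0]] >= 0)

            def resid(x):
                g = x[:p]
                s = x[p:]
                imp = np.outer(g, g)[iu]
                imp = imp + np.where(both, (np.outer(s, s))[iu], 0.0)
                return np.sqrt(w) * (r - imp)

            x0 = np.concatenate([np.full(p, 0.6), np.full(p, 0.3)])
            sol = least_squares(resid, x0, method="trf",
                                bounds=(-1.0, 1.0), xtol=1e-12)
            g = sol.x[:p]
            if g.sum() < 0:
                g = -g
            s = np.abs(sol.x[p:])
            spec = np.zeros((p, len(fac_names)))
            for i in range(p):
                if fac_of_item[i] >= 0:
                    spec[i, fac_of_item[i]] = s[i]
            route = "confirmatory"
            cols = fac_names
        else:
            g, spec = schmid_leiman(R, self.n_specific)
            route = "schmid-leiman"
            cols = [f"spec{j + 1}" for j in range(spec.shape[1])]

        omega_h, ecv = bifactor_indices(g, spec)

        self.item_ids_ = ids
        self.summary_ = BifactorSummary(
            omega_h=omega_h,
            ecv=ecv,
            general_loadings=pd.Series(g, index=ids),
            specific_loadings=pd.DataFrame(spec, index=ids, columns=cols),
            route=route,
        )
        return self


def fit_bifactor(responses, specific_assignment: dict[str, list[str]] | None = None,
                 n_specific: int = 3) -> BifactorSummary:
    """Bifactor omega_h / ECV summary (see :class:`BifactorModel`)."""
    return BifactorModel(specific_assignment=specific_assignment,
                         n_specific=n_specific).fit(responses).summary_
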