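"""Graded response model: probabilities, likelihood, EM calibration, EAP
scoring and information functions.

Calibration is marginal maximum likelihood with a standard-normal latent
prior, by EM over a fixed quadrature grid.  The E-step computes posterior
weights for every respondent on the grid; the M-step maximizes each item's
expected complete-data log-likelihood independently (quasi-Newton with
analytic gradients on an unconstrained reparameterization that keeps
``a > 0`` and thresholds strictly ordered).  Any M-step improvement keeps
the marginal likelihood non-decreasing (generalized EM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .banks import (
    DEFAULT_CALIBRATION_GRID,
    DEFAULT_SCORING_GRID,
    Item,
    ItemBank,
    QuadratureGrid,
    ResponseMatrix,
    ThetaEstimate,
)

_PCLIP = 1e-12


# ---------------------------------------------------------------------------
# Probabilities and information
# ---------------------------------------------------------------------------

def _cumulative(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P(X >= k+1 | theta) for k=1..K-1: logistic(a * (theta - b_k)).

    Returns array of shape (len(theta), K-1).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    return expit(a * (theta[:, None] - np.asarray(b)[None, :]))


def category_probabilities(item: Item, theta) -> np.ndarray:
    """GRM category probabilities at ``theta``.

    Returns shape (K,) for scalar theta, else (len(theta), K).  The K
    probabilities are differences of adjacent cumulative curves and sum
    to one by construction.
    """
    scalar = np.isscalar(theta)
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    s = _cumulative(item.a, np.array(item.b), th)  # (T, K-1)
    ones = np.ones((len(th), 1))
    zeros = np.zeros((len(th), 1))
    cum = np.hstack([ones, s, zeros])  # (T, K+1)
    probs = cum[:, :-1] - cum[:, 1:]
    return probs[0] if scalar else probs


def item_information(item: Item, theta) -> np.ndarray | float:
    """Fisher information of a GRM item at theta:
    ``I(theta) = sum_k P'_k(theta)^2 / P_k(theta)``."""
    scalar = np.isscalar(theta)
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    s = _cumulative(item.a, np.array(item.b), th)
    ds = item.a * s * (1.0 - s)  # derivative of each cumulative curve
    dcum = np.hstack([np.zeros((len(th), 1)), ds, np.zeros((len(th), 1))])
    dP = dcum[:, :-1] - dcum[:, 1:]
    P = category_probabilities(item, th)
    info = np.sum(dP**2 / np.clip(P, _PCLIP, None), axis=1)
    return float(info[0]) if scalar else info


def test_information(bank: ItemBank, theta) -> np.ndarray | float:
    """Test information: sum of item informations."""
    parts = [item_information(it, theta) for it in bank]
    return sum(parts)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _as_codes(X, item_ids: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Responses to 0-based integer codes; -1 marks missing."""
    if isinstance(X, ResponseMatrix):
        df = X.data
    elif isinstance(X, pd.DataFrame):
        df = X
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("responses must be 2-D (respondents x items)")
        cols = (list(item_ids) if item_ids is not None and len(item_ids) == arr.shape[1]
                else [f"item{j + 1:02d}" for j in range(arr.shape[1])])
        df = pd.DataFrame(arr, columns=cols)
    if item_ids is not None:
        missing = set(item_ids) - set(df.columns)
        if missing:
            raise ValueError(f"items missing from responses: {sorted(missing)}")
        df = df[list(item_ids)]
    vals = df.to_numpy(dtype=float)
    codes = np.full(vals.shape, -1, dtype=int)
    obs = np.isfinite(vals)
    codes[obs] = np.round(vals[obs]).astype(int) - 1
    if np.any(codes[obs] < 0):
        raise ValueError("categories must be >= 1")
    return codes, list(df.columns)


def _bank_probs(bank: ItemBank, nodes: np.ndarray) -> list[np.ndarray]:
    """Per-item category probabilities on the grid: list of (Q, K_j)."""
    return [category_probabilities(it, nodes) for it in bank]


def _loglik_matrix(prob_list: list[np.ndarray], codes: np.ndarray) -> np.ndarray:
    """Per-respondent log-likelihood at each node, shape (n, Q)."""
    n, p = codes.shape
    Q = prob_list[0].shape[0]
    L = np.zeros((n, Q))
    for j in range(p):
        logP = np.log(np.clip(prob_list[j], _PCLIP, None))  # (Q, K)
        xj = codes[:, j]
        m = xj >= 0
        if np.any(xj[m] >= prob_list[j].shape[1]):
            bad = np.where(m & (codes[:, j] >= prob_list[j].shape[1]))[0][0]
            raise ValueError(
                f"category {codes[bad, j] + 1} out of range for item index {j} "
                f"(K={prob_list[j].shape[1]}), respondent {bad}"
            )
        if m.any():
            L[m] += logP[:, xj[m]].T
    return L


def log_likelihood(bank: ItemBank, responses, thetas) -> float:
    """Joint log-likelihood of observed responses at given per-respondent
    thetas (no prior): sum of log category probabilities."""
    codes, ids = _as_codes(responses, bank.item_ids)
    thetas = np.atleast_1d(np.asarray(thetas, dtype=float))
    if len(thetas) != codes.shape[0]:
        raise ValueError("thetas length must equal respondent count")
    if codes.size == 0:
        return 0.0
    total = 0.0
    for j, it in enumerate(bank):
        P = category_probabilities(it, thetas)  # (n, K)
        xj = codes[:, j]
        m = xj >= 0
        if np.any(xj[m] >= it.n_categories):
            raise ValueError(f"category out of range for item {it.id!r}")
        total += float(np.sum(np.log(np.clip(P[m, xj[m]], _PCLIP, None))))
    return total


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def eap_scores(bank: ItemBank, responses, grid: QuadratureGrid | None = None) -> pd.DataFrame:
    """Vectorized EAP scores for every respondent.

    Returns a DataFrame with columns theta, se, t_score, t_se, n_items_used.
    """
    grid = grid or DEFAULT_SCORING_GRID
    codes, ids = _as_codes(responses, bank.item_ids)
    if codes.shape[1] == 0 or codes.shape[0] == 0:
        raise ValueError("empty response set")
    prob_list = _bank_probs(bank, grid.nodes)
    L = _loglik_matrix(prob_list, codes)
    logw = np.log(grid.weights)
    logpost = L + logw[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    theta = post @ grid.nodes
    second = post @ grid.nodes**2
    var = np.clip(second - theta**2, 0.0, None)
    se = np.sqrt(var)
    n_used = (codes >= 0).sum(axis=1)
    idx = responses.data.index if isinstance(responses, ResponseMatrix) else None
    return pd.DataFrame(
        {
            "theta": theta,
            "se": se,
            "t_score": 50.0 + 10.0 * theta,
            "t_se": 10.0 * se,
            "n_items_used": n_used,
        },
        index=idx,
    )


def eap_score(bank: ItemBank, response_vector, grid: QuadratureGrid | None = None) -> ThetaEstimate:
    """EAP estimate for one respondent.

    ``response_vector`` may be a mapping item_id -> category (subset scoring,
    as needed by short forms and CAT) or a sequence aligned with the bank.
    """
    if isinstance(response_vector, Mapping):
        ids = [i for i in bank.item_ids if i in response_vector]
        if not ids:
            raise ValueError("response vector covers no bank item")
        sub = bank.subset(ids)
        row = pd.DataFrame([{i: response_vector[i] for i in ids}])
    else:
        vec = np.asarray(response_vector, dtype=float)
        if vec.ndim != 1 or len(vec) != len(bank):
            raise ValueError("sequence response vector must have one entry per bank item")
        if not np.any(np.isfinite(vec)):
            raise ValueError("response vector is empty")
        keep = np.isfinite(vec)
        ids = [i for i, k in zip(bank.item_ids, keep) if k]
        sub = bank.subset(ids)
        row = pd.DataFrame([{i: v for i, v in zip(bank.item_ids, vec) if np.isfinite(v)}])
    df = eap_scores(sub, row[sub.item_ids], grid)
    return ThetaEstimate(
        theta=float(df["theta"].iloc[0]),
        se=float(df["se"].iloc[0]),
        n_items_used=int(df["n_items_used"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# EM calibration
# ---------------------------------------------------------------------------

def _item_start(codes_j: np.ndarray, K: int) -> tuple[float, np.ndarray]:
    obs = codes_j[codes_j >= 0]
    counts = np.bincount(obs, minlength=K).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    b = norm.ppf(np.clip(cum, 1e-4, 1 - 1e-4))
    # enforce strict ordering with a minimum gap
    for k in range(1, len(b)):
        b[k] = max(b[k], b[k - 1] + 0.05)
    return 1.0, np.clip(b, -3.9, 3.9)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    t = np.empty(1 + len(b))
    t[0] = np.log(a)
    t[1] = b[0]
    if len(b) > 1:
        t[2:] = np.log(np.clip(np.diff(b), 1e-6, None))
    return t


def _unpack(t: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(t[0]))
    b = np.empty(len(t) - 1)
    b[0] = t[1]
    if len(b) > 1:
        b[1:] = b[0] + np.cumsum(np.exp(t[2:]))
    return a, b


def _neg_q_and_grad(t: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood for one item and its
    gradient w.r.t. the unconstrained parameters.

    ``r`` is the (Q, K) matrix of expected category counts at each node.
    """
    a, b = _unpack(t)
    Q, K = r.shape
    s = expit(a * (nodes[:, None] - b[None, :]))  # (Q, K-1)
    cum = np.hstack([np.ones((Q, 1)), s, np.zeros((Q, 1))])
    P = np.clip(cum[:, :-1] - cum[:, 1:], _PCLIP, None)  # (Q, K)
    qval = float(np.sum(r * np.log(P)))

    ratio = r / P  # (Q, K)
    # dQ/ds_k = ratio[:, k] - ratio[:, k-1]   (s_k enters P_k with +, P_{k-1} with -)
    D = ratio[:, 1:] - ratio[:, :-1]  # (Q, K-1)
    u = s * (1.0 - s)
    grad_a = float(np.sum(D * u * (nodes[:, None] - b[None, :])))
    grad_b = -a * np.sum(D * u, axis=0)  # (K-1,)

    g = np.empty_like(t)
    g[0] = grad_a * a
    g[1] = grad_b.sum()
    if len(b) > 1:
        tail = np.cumsum(grad_b[::-1])[::-1]  # sum_{m>=k} grad_b[m]
        g[2:] = np.exp(t[2:]) * tail[1:]
    return -qval, -g


_MSTEP_BOUNDS_A = (np.log(0.01), np.log(50.0))


def _mstep_item(r: np.ndarray, nodes: np.ndarray, a0: float, b0: np.ndarray) -> tuple[float, np.ndarray]:
    t0 = _pack(a0, b0)
    bounds = [_MSTEP_BOUNDS_A, (-8.0, 8.0)] + [(-10.0, 3.0)] * (len(b0) - 1)
    res = minimize(
        _neg_q_and_grad, t0, args=(r, nodes), jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": 60, "ftol": 1e-12, "gtol": 1e-9},
    )
    q_old = -_neg_q_and_grad(t0, r, nodes)[0]
    if -res.fun >= q_old - 1e-10:
        return _unpack(res.x)
    return a0, b0  # generalized-EM safeguard: never decrease Q


@dataclass
class CalibrationDiagnostics:
    """Convergence record of an EM calibration."""

    converged: bool
    n_iter: int
    loglik_path: list[float] = field(default_factory=list)
    max_param_change: float = float("nan")
    collapse_map: dict[str, dict[int, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else float("nan")


class GradedResponseModel(BaseEstimator, TransformerMixin):
    """Graded response model with EM calibration and EAP scoring.

    Parameters
    ----------
    n_categories : int or None
        Declared number of response categories shared by all items.  When
        None, inferred per item from the data.  Declared categories that
        are never observed are collapsed downward before fitting (their
        thresholds are unidentified) and the mapping is reported in
        ``diagnostics_.collapse_map``.
    max_iter, tol : EM stopping rule — stop when the maximum absolute
        parameter change drops below ``tol`` (default 1e-4) or after
        ``max_iter`` cycles (default 500).
    calibration_grid, scoring_grid : optional QuadratureGrid overrides.

    Attributes (after fit)
    ----------------------
    bank_ : ItemBank of estimated discriminations and thresholds.
    diagnostics_ : CalibrationDiagnostics (monotone log-likelihood path).
    """

    def __init__(self, n_categories: int | None = None, max_iter: int = 500,
                 tol: float = 1e-4,
                 calibration_grid: QuadratureGrid | None = None,
                 scoring_grid: QuadratureGrid | None = None):
        self.n_categories = n_categories
        self.max_iter = max_iter
        self.tol = tol
        self.calibration_grid = calibration_grid
        self.scoring_grid = scoring_grid

    # -- construction from known parameters (scoring-only workflows) ----
    @classmethod
    def from_bank(cls, bank: ItemBank,
                  scoring_grid: QuadratureGrid | None = None) -> "GradedResponseModel":
        m = cls(scoring_grid=scoring_grid)
        m.bank_ = bank
        m.item_ids_ = bank.item_ids
        m.diagnostics_ = CalibrationDiagnostics(converged=True, n_iter=0)
        return m

    def fit(self, X, y=None) -> "GradedResponseModel":
        codes, ids = _as_codes(X)
        n, p = codes.shape
        if n == 0 or p == 0:
            raise ValueError("empty response matrix")
        grid = self.calibration_grid or DEFAULT_CALIBRATION_GRID
        diags = CalibrationDiagnostics(converged=False, n_iter=0)

        # per-item category handling: collapse unobserved categories downward
        K_declared = []
        for j, item_id in enumerate(ids):
            obs = codes[:, j][codes[:, j] >= 0]
            if len(obs) == 0:
                raise ValueError(f"item {item_id!r} has no observed responses")
            uniq = np.unique(obs)
            if len(uniq) < 2:
                raise ValueError(
                    f"degenerate item {item_id!r}: all respondents chose "
                    f"category {uniq[0] + 1}"
                )
            K = self.n_categories or int(obs.max()) + 1
            observed_set = set(uniq.tolist())
            if len(observed_set) < K:
                # full declared->fitted mapping (1-based): any category maps
                # to the highest observed category at or below it (downward
                # collapse), so unseen categories in later data stay scorable
                sorted_obs = sorted(observed_set)
                full = {}
                for old in range(K):
                    rank = int(np.searchsorted(sorted_obs, old, side="right"))
                    full[old + 1] = max(rank, 1)
                diags.collapse_map[item_id] = full
                mapping = {v: full[v + 1] - 1 for v in sorted_obs}
                col = codes[:, j]
                m = col >= 0
                codes[m, j] = np.array([mapping[v] for v in col[m]])
                K = len(observed_set)
            K_declared.append(K)
            if n < 10 * K:
                msg = f"item {item_id!r}: n={n} below recommended 10*K={10 * K}"
                diags.warnings.append(msg)
                warnings.warn(msg)

        # initial values
        a_cur = []
        b_cur = []
        for j in range(p):
            a0, b0 = _item_start(codes[:, j], K_declared[j])
            a_cur.append(a0)
            b_cur.append(b0)

        nodes, logw = grid.nodes, np.log(grid.weights)
        prev_ll = -np.inf
        for it in range(1, self.max_iter + 1):
            prob_list = [
                category_probabilities(Item(id=str(j), a=a_cur[j], b=tuple(b_cur[j])), nodes)
                for j in range(p)
            ]
            L = _loglik_matrix(prob_list, codes)
            lj = L + logw[None, :]
            ll_n = logsumexp(lj, axis=1)
            ll = float(ll_n.sum())
            diags.loglik_path.append(ll)
            post = np.exp(lj - ll_n[:, None])  # (n, Q)

            max_change = 0.0
            for j in range(p):
                K = K_declared[j]
                xj = codes[:, j]
                r = np.zeros((len(nodes), K))
                for k in range(K):
                    mask = xj == k
                    if mask.any():
                        r[:, k] = post[mask].sum(axis=0)
                a_new, b_new = _mstep_item(r, nodes, a_cur[j], b_cur[j])
                max_change = max(
                    max_change,
                    abs(a_new - a_cur[j]),
                    float(np.max(np.abs(b_new - b_cur[j]))),
                )
                a_cur[j], b_cur[j] = a_new, b_new

            diags.n_iter = it
            diags.max_param_change = max_change
            prev_ll = ll
            if max_change < self.tol:
                diags.converged = True
                break

        if not diags.converged:
            msg = (f"EM did not reach tol={self.tol} in {self.max_iter} cycles "
                   f"(last max parameter change {diags.max_param_change:.2e}); "
                   "returning partial result")
            diags.warnings.append(msg)
            warnings.warn(msg)

        self.bank_ = ItemBank(
            (Item(id=ids[j], a=a_cur[j], b=tuple(b_cur[j])) for j in range(p)),
            category_maps=diags.collapse_map or None,
        )
        self.item_ids_ = ids
        self.diagnostics_ = diags
        return self

    # -- scoring ---------------------------------------------------------
    def collapse_responses(self, X) -> pd.DataFrame:
        """Map declared categories onto the fitted (collapsed) categories.

        Identity when no categories were collapsed during fitting.
        """
        check_is_fitted(self, "bank_")
        if isinstance(X, ResponseMatrix):
            df = X.data.copy()
        elif isinstance(X, pd.DataFrame):
            df = X.copy()
        else:
            df = pd.DataFrame(np.asarray(X, dtype=float), columns=self.item_ids_)
        for item_id, mapping in self.diagnostics_.collapse_map.items():
            if item_id in df.columns:
                df[item_id] = df[item_id].map(
                    lambda v: mapping.get(int(v), np.nan) if pd.notna(v) else np.nan
                )
        return df

    def transform(self, X) -> np.ndarray:
        """EAP theta and SE per respondent, shape (n, 2)."""
        check_is_fitted(self, "bank_")
        df = self.score_table(X)
        return df[["theta", "se"]].to_numpy()

    def score_table(self, X) -> pd.DataFrame:
        check_is_fitted(self, "bank_")
        grid = self.scoring_grid or DEFAULT_SCORING_GRID
        return eap_scores(self.bank_, self.collapse_responses(X), grid)


def fit_grm_em(responses, grid: QuadratureGrid | None = None, max_iter: int = 500,
               tol: float = 1e-4, n_categories: int | None = None,
               ) -> tuple[ItemBank, CalibrationDiagnostics]:
    """Functional wrapper: marginal-maximum-likelihood GRM calibration."""
    model = GradedResponseModel(
        n_categories=n_categories, max_iter=max_iter, tol=tol, calibration_grid=grid
    ).fit(responses)
    return model.bank_, model.diagnostics_


def parameter_standard_errors(bank: ItemBank, responses,
                              grid: QuadratureGrid | None = None,
                              step: float = 1e-4) -> dict[str, np.ndarray]:
    """Approximate standard errors of item parameters by the empirical
    (outer-product-of-gradients) information of the marginal likelihood.

    Gradients of each respondent's log marginal likelihood are taken
    numerically (central differences) over all item parameters jointly.
    """
    grid = grid or DEFAULT_CALIBRATION_GRID
    codes, ids = _as_codes(responses, bank.item_ids)
    logw = np.log(grid.weights)

    params = []
    layout = []  # (item_index, n_params)
    for it in bank:
        params.extend([it.a, *it.b])
        layout.append(len(it.b) + 1)
    params = np.array(params, dtype=float)

    def per_case_ll(pvec: np.ndarray) -> np.ndarray:
        pos = 0
        items = []
        for it, npar in zip(bank, layout):
            a = pvec[pos]
            b = np.sort(pvec[pos + 1: pos + npar])
            items.append(Item(id=it.id, a=max(a, 1e-3), b=tuple(b)))
            pos += npar
        prob_list = _bank_probs(ItemBank(items), grid.nodes)
        L = _loglik_matrix(prob_list, codes)
        return logsumexp(L + logw[None, :], axis=1)

    n = codes.shape[0]
    G = np.zeros((n, len(params)))
    for i in range(len(params)):
        up = params.copy()
        dn = params.copy()
        up[i] += step
        dn[i] -= step
        G[:, i] = (per_case_ll(up) - per_case_ll(dn)) / (2 * step)
    info = G.T @ G
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    out = {}
    pos = 0
    for it, npar in zip(bank, layout):
        out[it.id] = se[pos: pos + npar]  # [se_a, se_b1, ...]
        pos += npar
    return out
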