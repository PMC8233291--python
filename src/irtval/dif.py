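"""Two-group differential item functioning via nested ordinal logistic
regressions with McFadden's pseudo-R-squared.

For each item, three proportional-odds models are compared:

    M1: response ~ theta
    M2: response ~ theta + group
    M3: response ~ theta + group + theta x group

with the matching variable theta taken as the EAP score from a pooled
(joint) calibration.  McFadden R^2 of a model is 1 - lnL_model / lnL_null
(null = intercepts only, whose ML log-likelihood is available in closed
form from the category proportions).  The R^2 *changes* between nested
models quantify uniform (M1->M2) and non-uniform (M2->M3) DIF; an item is
flagged when the total change (M1->M3) reaches the criterion (0.02).

With purification enabled, the matching score is recomputed from the
non-flagged (anchor) items only and the regressions are refitted until
the flag set stabilizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .banks import (
    DEFAULT_CALIBRATION_GRID,
    Item,
    ItemBank,
    QuadratureGrid,
    ResponseMatrix,
)
from .grm import (
    GradedResponseModel,
    _as_codes,
    _bank_probs,
    _loglik_matrix,
    _mstep_item,
    eap_scores,
)


@dataclass
class DIFItemResult:
    item_id: str
    r2_uniform: float | None
    r2_nonuniform: float | None
    r2_total: float | None
    flagged: bool | None
    dif_type: str  # "uniform" | "non-uniform" | "none" | "unevaluable"
    note: str = ""


@dataclass
class DIFResult:
    items: list[DIFItemResult]
    anchor_set: list[str]
    criterion: float
    n_purify_iter: int
    purify_converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "item": r.item_id,
                    "r2_uniform": r.r2_uniform,
                    "r2_nonuniform": r.r2_nonuniform,
                    "r2_total": r.r2_total,
                    "flagged": r.flagged,
                    "dif_type": r.dif_type,
                    "note": r.note,
                }
                for r in self.items
            ]
        )

    @property
    def flagged_items(self) -> list[str]:
        return [r.item_id for r in self.items if r.flagged]

    def __getitem__(self, item_id: str) -> DIFItemResult:
        for r in self.items:
            if r.item_id == item_id:
                return r
        raise KeyError(item_id)


def _null_loglik(y: np.ndarray) -> float:
    """Closed-form ML log-likelihood of the intercept-only ordinal model:
    categories fitted at their observed proportions."""
    counts = np.bincount(y)
    counts = counts[counts > 0]
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def _polr_negll_grad(t: np.ndarray, y: np.ndarray, X: np.ndarray, K: int
                     ) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient of the cumulative-logit model
    P(Y <= k | x) = logistic(alpha_k - x beta), with the ordered cutpoints
    reparameterized as alpha_0 = t_0, alpha_k = alpha_{k-1} + exp(t_k)."""
    from scipy.special import expit as _expit

    nc = K - 1
    alpha = np.empty(nc)
    alpha[0] = t[0]
    if nc > 1:
        alpha[1:] = t[0] + np.cumsum(np.exp(t[1:nc]))
    beta = t[nc:]
    xb = X @ beta
    eta = alpha[None, :] - xb[:, None]  # (n, K-1)
    F = _expit(eta)
    Fup = np.where(y[:, None] == np.arange(nc)[None, :], F, 0.0).sum(axis=1)
    Fup[y == nc] = 1.0
    Flo = np.where((y[:, None] - 1) == np.arange(nc)[None, :], F, 0.0).sum(axis=1)
    Flo[y == 0] = 0.0
    P = np.clip(Fup - Flo, 1e-300, None)
    ll = float(np.sum(np.log(P)))

    f = F * (1.0 - F)  # logistic density at each cutpoint
    inv = 1.0 / P
    # dll/dalpha_k = sum over obs of (1[y=k] f(eta_k) - 1[y=k+1] f(eta_k)) / P
    g_alpha = np.zeros(nc)
    for k in range(nc):
        up = (y == k)
        lo = (y == k + 1)
        g_alpha[k] = float(np.sum(f[up, k] * inv[up]) - np.sum(f[lo, k] * inv[lo]))
    fu = np.zeros(len(y))
    m = y < nc
    fu[m] = f[m, y[m]]
    fl = np.zeros(len(y))
    m = y > 0
    fl[m] = f[m, y[m] - 1]
    g_beta = -X.T @ ((fu - fl) * inv)

    g = np.empty_like(t)
    g[0] = g_alpha.sum()
    if nc > 1:
        tail = np.cumsum(g_alpha[::-1])[::-1]
        g[1:nc] = np.exp(t[1:nc]) * tail[1:]
    g[nc:] = g_beta
    return -ll, -g


def _fit_ordinal(y: np.ndarray, X: np.ndarray) -> float:
    """ML log-likelihood of a proportional-odds logit fit (quasi-Newton
    with analytic gradients, gradient-norm convergence 1e-8)."""
    from scipy.optimize import minimize as _minimize

    K = int(y.max()) + 1
    counts = np.bincount(y, minlength=K).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    alpha0 = np.log(cum / (1.0 - cum))
    t0 = np.empty(K - 1 + X.shape[1])
    t0[0] = alpha0[0]
    if K > 2:
        t0[1:K - 1] = np.log(np.clip(np.diff(alpha0), 1e-3, None))
    t0[K - 1:] = 0.0
    res = _minimize(_polr_negll_grad, t0, args=(y, X, K), jac=True,
                    method="L-BFGS-B",
                    options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-8})
    if not np.isfinite(res.fun):
        raise RuntimeError("ordinal regression did not converge")
    return -float(res.fun)


def _item_r2s(y: np.ndarray, theta: np.ndarray, grp: np.ndarray) -> tuple[float, float, float]:
    """McFadden R^2 of M1/M2/M3 for one item (recoded to dense categories)."""
    uniq = np.unique(y)
    y = np.searchsorted(uniq, y)
    ll0 = _null_loglik(y)
    x1 = theta[:, None]
    x2 = np.column_stack([theta, grp])
    x3 = np.column_stack([theta, grp, theta * grp])
    ll1 = _fit_ordinal(y, x1)
    ll2 = max(_fit_ordinal(y, x2), ll1)  # nested: never below
    ll3 = max(_fit_ordinal(y, x3), ll2)
    r2 = [1.0 - ll / ll0 for ll in (ll1, ll2, ll3)]
    return r2[1] - r2[0], r2[2] - r2[1], r2[2] - r2[0]


class DIFDetector(BaseEstimator):
    """Uniform/non-uniform DIF screening between two groups.

    Parameters
    ----------
    criterion : McFadden R^2 change that flags an item (default 0.02).
    purify : iterate with anchor-only matching scores until stable.
    max_purify_iter : iteration cap; non-convergence is reported.
    bank : optional pre-calibrated ItemBank used for matching scores; when
        None a pooled GRM calibration is run on the data.
    min_group_n : warn when either group is smaller than this.

    fit(X) expects a ResponseMatrix with a two-level group column (or
    ``groups`` passed explicitly).  Results in ``result_``.
    """

    def __init__(self, criterion: float = 0.02, purify: bool = True,
                 max_purify_iter: int = 10, bank: ItemBank | None = None,
                 min_group_n: int = 50, calibration_tol: float = 1e-3):
        self.criterion = criterion
        self.purify = purify
        self.max_purify_iter = max_purify_iter
        self.bank = bank
        self.min_group_n = min_group_n
        self.calibration_tol = calibration_tol

    def fit(self, X, groups=None) -> "DIFDetector":
        if isinstance(X, ResponseMatrix):
            df = X.data
            if groups is None:
                groups = X.group
        else:
            df = pd.DataFrame(X)
        if groups is None:
            raise ValueError("two-group DIF needs group labels")
        groups = pd.Series(groups).reset_index(drop=True)
        levels = sorted(groups.unique())
        if len(levels) != 2:
            raise ValueError(
                f"DIF detection requires exactly two groups, got {len(levels)}: {levels}"
            )
        grp = (groups == levels[1]).to_numpy().astype(float)
        for lv in levels:
            n_g = int((groups == lv).sum())
            if n_g < self.min_group_n:
                warnings.warn(f"group {lv!r} has only {n_g} respondents")

        codes, ids = _as_codes(df)
        if np.any(codes < 0):
            raise ValueError("DIF screening requires complete responses")

        if self.bank is not None:
            bank = self.bank
        else:
            bank = GradedResponseModel(
                tol=self.calibration_tol, max_iter=300
            ).fit(df).bank_
        self.bank_ = bank
        if bank.category_maps:
            # score and regress on the fitted (collapsed) category scale
            df = bank.apply_category_maps(df)
            codes, ids = _as_codes(df)

        def matching_theta(anchor_ids: list[str]) -> np.ndarray:
            sub = bank.subset(anchor_ids)
            return eap_scores(sub, df[anchor_ids]).theta.to_numpy()

        flagged: set[str] = set()
        results: dict[str, DIFItemResult] = {}
        n_iter = 0
        converged = True
        while True:
            n_iter += 1
            anchors = [i for i in ids if i not in flagged] or list(ids)
            theta = matching_theta(anchors)
            results = {}
            new_flagged: set[str] = set()
            for j, item_id in enumerate(ids):
                y = codes[:, j]
                for g, lv in ((0.0, levels[0]), (1.0, levels[1])):
                    if len(np.unique(y[grp == g])) < 2:
                        results[item_id] = DIFItemResult(
                            item_id, None, None, None, None, "unevaluable",
                            note=f"group {lv!r} has a single observed category",
                        )
                        break
                else:
                    try:
                        r2u, r2n, r2t = _item_r2s(y, theta, grp)
                    except Exception as exc:  # noqa: BLE001 - reported per item
                        results[item_id] = DIFItemResult(
                            item_id, None, None, None, None, "unevaluable",
                            note=f"ordinal regression failed: {exc}",
                        )
                        continue
                    flag = r2t >= self.criterion
                    if flag:
                        dif_type = "non-uniform" if r2n >= self.criterion else "uniform"
                        new_flagged.add(item_id)
                    else:
                        dif_type = "none"
                    results[item_id] = DIFItemResult(item_id, r2u, r2n, r2t, flag, dif_type)
            if not self.purify or new_flagged == flagged:
                flagged = new_flagged
                break
            if n_iter >= self.max_purify_iter:
                flagged = new_flagged
                converged = False
                warnings.warn(
                    f"DIF purification did not stabilize in {self.max_purify_iter} iterations"
                )
                break
            flagged = new_flagged

        anchor_set = [i for i in ids if i not in flagged]
        self.result_ = DIFResult(
            items=[results[i] for i in ids],
            anchor_set=anchor_set,
            criterion=self.criterion,
            n_purify_iter=n_iter,
            purify_converged=converged,
        )
        return self


def detect_dif(responses, bank: ItemBank | None = None, criterion: float = 0.02,
               purify: bool = True, max_purify_iter: int = 10) -> DIFResult:
    """Functional wrapper over :class:`DIFDetector`."""
    det = DIFDetector(criterion=criterion, purify=purify,
                      max_purify_iter=max_purify_iter, bank=bank)
    det.fit(responses)
    return det.result_


# ---------------------------------------------------------------------------
# Anchored recalibration
# ---------------------------------------------------------------------------

def anchored_recalibration(responses: ResponseMatrix, anchor_ids: list[str],
                           grid: QuadratureGrid | None = None,
                           max_iter: int = 300, tol: float = 1e-4,
                           ) -> dict:
    """Group-specific item parameters on a common scale through anchors.

    Group A (first level) is calibrated fully with a standard-normal
    prior.  Group B is then calibrated with the anchor items' parameters
    held fixed at the group-A estimates while the non-anchor items and the
    group-B latent mean and SD are free: the anchors carry the metric
    across groups.

    Returns dict with keys ``bank_a``, ``bank_b``, ``group_b_latent``
    (mean, sd) and ``anchor_ids``.
    """
    if not anchor_ids:
        raise ValueError("anchor set must be non-empty")
    if responses.group is None:
        raise ValueError("anchored recalibration needs group labels")
    levels = sorted(responses.group.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    ids = responses.item_ids
    unknown = set(anchor_ids) - set(ids)
    if unknown:
        raise ValueError(f"unknown anchor items: {sorted(unknown)}")

    grid = grid or DEFAULT_CALIBRATION_GRID
    mask_a = (responses.group == levels[0]).to_numpy()
    df_a = responses.data.loc[mask_a]
    df_b = responses.data.loc[~mask_a]

    bank_a = GradedResponseModel(calibration_grid=grid, tol=tol,
                                 max_iter=max_iter).fit(df_a).bank_
    if bank_a.category_maps:
        # group B data must live on group A's fitted category scale
        df_b = bank_a.apply_category_maps(df_b)
        if df_b.isna().any().any():
            bad = df_b.columns[df_b.isna().any()][0]
            raise ValueError(
                f"group B uses categories of item {bad!r} never observed in "
                "group A; collapse the data jointly before anchoring"
            )

    # group B: fixed anchors, free non-anchors, free latent N(mu, sigma^2)
    codes, _ = _as_codes(df_b, ids)
    if np.any(codes < 0):
        raise ValueError("anchored recalibration requires complete responses")
    nodes = grid.nodes
    anchors = set(anchor_ids)
    a_cur = {i: bank_a[i].a for i in ids}
    b_cur = {i: np.array(bank_a[i].b) for i in ids}
    mu, sd = 0.0, 1.0
    from scipy.stats import norm as _norm

    prev = None
    for _ in range(max_iter):
        w = _norm.pdf(nodes, loc=mu, scale=sd)
        w = w / w.sum()
        bank_cur = ItemBank(Item(id=i, a=a_cur[i], b=tuple(b_cur[i])) for i in ids)
        prob_list = _bank_probs(bank_cur, nodes)
        L = _loglik_matrix(prob_list, codes)
        lj = L + np.log(w)[None, :]
        post = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))

        max_change = 0.0
        for j, item_id in enumerate(ids):
            if item_id in anchors:
                continue
            K = len(b_cur[item_id]) + 1
            xj = codes[:, j]
            r = np.zeros((len(nodes), K))
            for k in range(K):
                m = xj == k
                if m.any():
                    r[:, k] = post[m].sum(axis=0)
            a_new, b_new = _mstep_item(r, nodes, a_cur[item_id], b_cur[item_id])
            max_change = max(max_change, abs(a_new - a_cur[item_id]),
                             float(np.max(np.abs(b_new - b_cur[item_id]))))
            a_cur[item_id], b_cur[item_id] = a_new, b_new

        # latent-distribution update from posterior moments
        pm = post @ nodes
        pv = post @ nodes**2 - pm**2
        mu_new = float(pm.mean())
        sd_new = float(np.sqrt(np.clip(np.mean(pv + pm**2) - mu_new**2, 1e-6, None)))
        max_change = max(max_change, abs(mu_new - mu), abs(sd_new - sd))
        mu, sd = mu_new, sd_new
        if prev is not None and max_change < tol:
            break
        prev = max_change

    bank_b = ItemBank(Item(id=i, a=a_cur[i], b=tuple(b_cur[i])) for i in ids)
    return {"bank_a": bank_a, "bank_b": bank_b,
            "group_b_latent": (mu, sd), "anchor_ids": list(anchor_ids)}
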