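"""Mokken scalability coefficients for polytomous items.

H_ij is the ratio of the observed covariance of an item pair to its
maximum attainable covariance given the marginals (the comonotone,
Guttman-consistent coupling).  This equals 1 - F_ij / E_ij, the weighted
Guttman-error formulation over category steps.  Item coefficients H_i and
the scale coefficient H aggregate pairwise numerators and denominators.
Monotone scales should show all H_i >= 0.30 and H >= 0.50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .banks import ResponseMatrix


def max_covariance(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum covariance of two discrete variables given their margins:
    E[XY] under the comonotone (sorted) coupling minus the product of means."""
    xs = np.sort(x)
    ys = np.sort(y)
    return float(np.mean(xs * ys) - xs.mean() * ys.mean())


@dataclass
class MokkenResult:
    pairwise_h: pd.DataFrame
    item_h: pd.Series
    scale_h: float
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)

    def meets_criteria(self, item_min: float = 0.30, scale_min: float = 0.50) -> dict[str, bool]:
        return {
            "items": bool((self.item_h >= item_min).all()),
            "scale": self.scale_h >= scale_min,
        }


class MokkenScale(BaseEstimator):
    """Mokken scalability analysis.  fit(X) computes ``pairwise_h_``,
    ``item_h_`` and ``scale_h_``; degenerate pairs (zero maximum
    covariance) are excluded and reported."""

    def fit(self, X, y=None) -> "MokkenScale":
        df = X.data if isinstance(X, ResponseMatrix) else pd.DataFrame(X)
        if df.isna().any().any():
            raise ValueError("Mokken analysis requires complete data")
        ids = list(df.columns)
        p = len(ids)
        if p < 2:
            raise ValueError("need at least two items")
        arr = df.to_numpy(dtype=float)

        cov = np.zeros((p, p))
        cmax = np.zeros((p, p))
        excluded = []
        H = np.full((p, p), np.nan)
        for i in range(p):
            for j in range(i + 1, p):
                c = float(np.cov(arr[:, i], arr[:, j], bias=True)[0, 1])
                cm = max_covariance(arr[:, i], arr[:, j])
                if cm <= 1e-12:
                    excluded.append((ids[i], ids[j]))
                    continue
                cov[i, j] = cov[j, i] = c
                cmax[i, j] = cmax[j, i] = cm
                H[i, j] = H[j, i] = c / cm

        item_h = np.array([
            cov[i].sum() / cmax[i].sum() if cmax[i].sum() > 0 else np.nan
            for i in range(p)
        ])
        total_cmax = cmax[np.triu_indices(p, 1)].sum()
        scale_h = cov[np.triu_indices(p, 1)].sum() / total_cmax if total_cmax > 0 else np.nan

        self.item_ids_ = ids
        self.result_ = MokkenResult(
            pairwise_h=pd.DataFrame(H, index=ids, columns=ids),
            item_h=pd.Series(item_h, index=ids),
            scale_h=float(scale_h),
            excluded_pairs=excluded,
        )
        self.pairwise_h_ = self.result_.pairwise_h
        self.item_h_ = self.result_.item_h
        self.scale_h_ = self.result_.scale_h
        return self


def mokken_h(responses) -> MokkenResult:
    """Pairwise, item, and scale scalability coefficients."""
    return MokkenScale().fit(responses).result_
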