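"""Item banks, response matrices, quadrature grids, and trait estimates.

The graded response model (GRM) is parameterized in slope/threshold form:
an item with discrimination ``a > 0`` and strictly increasing thresholds
``b_1 < ... < b_{K-1}`` has cumulative response curves
``P(X >= k | theta) = logistic(a * (theta - b_{k-1}))``.

Trait estimates live on the standardized theta metric; the reporting
metric is the T-score, ``T = 50 + 10 * theta`` (reference population mean
50, SD 10).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Item:
    """One graded-response item: discrimination ``a`` and ordered thresholds ``b``."""

    id: str
    a: float
    b: tuple[float, ...]
    label: str = ""
    reverse_worded: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("item id must be non-empty")
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"item {self.id!r}: discrimination must be positive, got {self.a}")
        b = tuple(float(x) for x in self.b)
        if len(b) < 1:
            raise ValueError(f"item {self.id!r}: needs at least one threshold (K >= 2)")
        if not all(np.isfinite(b)):
            raise ValueError(f"item {self.id!r}: thresholds must be finite")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"item {self.id!r}: thresholds must be strictly increasing, got {b}")
        object.__setattr__(self, "b", b)

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


class ItemBank:
    """Ordered collection of :class:`Item` with unique ids.

    ``category_maps`` records, per item, how declared response categories
    map onto the fitted ones when unobserved categories were collapsed
    during calibration (e.g. ``{"item": {1: 1, 2: 1, 3: 2, ...}}``); it is
    carried through serialization so a saved bank can score raw data.
    """

    def __init__(self, items: Iterable[Item],
                 category_maps: Mapping[str, Mapping[int, int]] | None = None):
        self.items: list[Item] = list(items)
        if not self.items:
            raise ValueError("item bank must contain at least one item")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        self.category_maps: dict[str, dict[int, int]] = {
            k: {int(a): int(b) for a, b in v.items()}
            for k, v in (category_maps or {}).items()
        }
        unknown = set(self.category_maps) - set(ids)
        if unknown:
            raise ValueError(f"category_maps reference unknown items: {sorted(unknown)}")

    def apply_category_maps(self, df: pd.DataFrame) -> pd.DataFrame:
        """Map declared categories onto the fitted (collapsed) scale.

        Identity when the bank has no recorded collapses.
        """
        if not self.category_maps:
            return df
        df = df.copy()
        for item_id, mapping in self.category_maps.items():
            if item_id in df.columns:
                df[item_id] = df[item_id].map(
                    lambda v: mapping.get(int(v), np.nan) if pd.notna(v) else np.nan
                )
        return df

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, key: int | str) -> Item:
        if isinstance(key, str):
            for it in self.items:
                if it.id == key:
                    return it
            raise KeyError(key)
        return self.items[key]

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def n_categories(self) -> list[int]:
        return [it.n_categories for it in self.items]

    def subset(self, ids: Sequence[str]) -> "ItemBank":
        maps = {i: self.category_maps[i] for i in ids if i in self.category_maps}
        return ItemBank([self[i] for i in ids], category_maps=maps or None)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "items": [
                {
                    "id": it.id,
                    "label": it.label,
                    "reverse_worded": it.reverse_worded,
                    "a": it.a,
                    "b": list(it.b),
                    "K": it.n_categories,
                }
                for it in self.items
            ]
        }
        if self.category_maps:
            d["category_maps"] = {
                k: {str(a): b for a, b in v.items()}
                for k, v in self.category_maps.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemBank":
        items = []
        for rec in d["items"]:
            items.append(
                Item(
                    id=rec["id"],
                    label=rec.get("label", ""),
                    reverse_worded=bool(rec.get("reverse_worded", False)),
                    a=float(rec["a"]),
                    b=tuple(rec["b"]),
                )
            )
        return cls(items, category_maps=d.get("category_maps"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemBank":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per item, threshold columns b1..b{K-1}."""
        kmax = max(self.n_categories)
        rows = []
        for it in self.items:
            row = {
                "id": it.id,
                "label": it.label,
                "reverse_worded": it.reverse_worded,
                "K": it.n_categories,
                "a": it.a,
            }
            for j in range(kmax - 1):
                row[f"b{j + 1}"] = it.b[j] if j < len(it.b) else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        bcols = sorted([c for c in df.columns if c.startswith("b") and c[1:].isdigit()],
                       key=lambda c: int(c[1:]))
        items = []
        for _, row in df.iterrows():
            b = tuple(float(row[c]) for c in bcols if pd.notna(row[c]))
            items.append(
                Item(
                    id=str(row["id"]),
                    label=str(row.get("label", "") or ""),
                    reverse_worded=bool(row.get("reverse_worded", False)),
                    a=float(row["a"]),
                    b=b,
                )
            )
        return cls(items)

    def __repr__(self) -> str:
        return f"ItemBank({len(self.items)} items, K={self.n_categories})"


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed latent-trait grid with prior-weighted quadrature weights.

    Weights incorporate the latent prior and are normalized to sum to one,
    so posterior expectations are plain weighted sums.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-D arrays of equal length")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        total = weights.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / total)

    @classmethod
    def normal_prior(cls, n_points: int = 49, lo: float = -6.0, hi: float = 6.0,
                     mean: float = 0.0, sd: float = 1.0) -> "QuadratureGrid":
        """Equally spaced nodes on [lo, hi] weighted by a Normal(mean, sd^2) prior."""
        nodes = np.linspace(lo, hi, n_points)
        weights = stats.norm.pdf(nodes, loc=mean, scale=sd)
        return cls(nodes=nodes, weights=weights)

    def __len__(self) -> int:
        return len(self.nodes)


# Default grids: a coarse one for EM calibration (parameter stability well
# below the convergence tolerance) and a finer, wider one for scoring.
# Scoring needs the wider range because all-maximum responders have
# posteriors centered ~3 with prior-like tails: truncating at +/-6 leaves
# a ~1e-6 boundary error, while +/-8 is exact to ~1e-12.
DEFAULT_CALIBRATION_GRID = QuadratureGrid.normal_prior(49)
DEFAULT_SCORING_GRID = QuadratureGrid.normal_prior(201, -8.0, 8.0)


@dataclass(frozen=True)
class ThetaEstimate:
    """EAP trait estimate with its posterior SD and the T-score mapping."""

    theta: float
    se: float
    n_items_used: int

    @property
    def t_score(self) -> float:
        return 50.0 + 10.0 * self.theta

    @property
    def t_se(self) -> float:
        return 10.0 * self.se


class ResponseMatrix:
    """Respondents x items integer category data (1..K), with optional
    group labels and retained true latent values from simulation.

    Missing responses are represented as NaN in :attr:`data` and excluded
    item-wise from likelihood computations.
    """

    RESERVED = ("group", "true_theta")

    def __init__(self, data: pd.DataFrame, group: pd.Series | None = None,
                 true_theta: pd.Series | None = None):
        data = data.copy()
        for col in self.RESERVED:
            if col in data.columns:
                raise ValueError(f"column {col!r} is reserved; pass it separately")
        self.data = data
        self.group = None if group is None else pd.Series(group, index=data.index)
        self.true_theta = None if true_theta is None else pd.Series(
            np.asarray(true_theta, dtype=float), index=data.index)

    # ---- basic properties ---------------------------------------------
    @property
    def n_respondents(self) -> int:
        return len(self.data)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        """Responses as float array (NaN = missing)."""
        return self.data.to_numpy(dtype=float)

    def subset_items(self, ids: Sequence[str]) -> "ResponseMatrix":
        return ResponseMatrix(self.data[list(ids)], self.group, self.true_theta)

    def subset_rows(self, mask) -> "ResponseMatrix":
        mask = np.asarray(mask)
        return ResponseMatrix(
            self.data.loc[mask],
            None if self.group is None else self.group.loc[mask],
            None if self.true_theta is None else self.true_theta.loc[mask],
        )

    # ---- validation and recoding --------------------------------------
    def validate_against_bank(self, bank: ItemBank) -> None:
        """Raise with row/column coordinates on any out-of-range category."""
        for it in bank:
            if it.id not in self.data.columns:
                raise ValueError(f"item {it.id!r} missing from response matrix")
            col = self.data[it.id]
            vals = col.dropna()
            bad = vals[(vals < 1) | (vals > it.n_categories) | (vals != np.round(vals))]
            if len(bad):
                idx = bad.index[0]
                val = bad.iloc[0]
                val = int(val) if float(val).is_integer() else float(val)
                raise ValueError(
                    f"invalid category {val} for item {it.id!r} "
                    f"(row {int(idx)}): expected integer in 1..{it.n_categories}"
                )

    def recoded(self, bank: ItemBank) -> "ResponseMatrix":
        """Reverse-score items the bank marks reverse-worded: x -> K + 1 - x.

        The recode is an involution: applying it twice restores the input.
        """
        data = self.data.copy()
        for it in bank:
            if it.reverse_worded and it.id in data.columns:
                data[it.id] = it.n_categories + 1 - data[it.id]
        return ResponseMatrix(data, self.group, self.true_theta)

    # ---- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        if self.group is not None:
            out["group"] = self.group
        if self.true_theta is not None:
            out["true_theta"] = self.true_theta
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResponseMatrix":
        df = pd.read_csv(path)
        group = df.pop("group") if "group" in df.columns else None
        true_theta = df.pop("true_theta") if "true_theta" in df.columns else None
        return cls(df, group=group, true_theta=true_theta)

    def __repr__(self) -> str:
        g = "" if self.group is None else ", grouped"
        return f"ResponseMatrix({self.n_respondents} x {len(self.item_ids)}{g})"


# ---------------------------------------------------------------------------
# Reference banks used throughout the package and its tests.
# ---------------------------------------------------------------------------

_PEER_BANK_TABLE = [
    # (id, label, reverse, a, b1, b2, b3, b4)
    # discriminations 0.78-3.7, thresholds spanning -3.8 to 2.0, so the
    # bank measures from well below the population mean to about +2 SD
    ("peer01", "spends time with friends", False, 2.8, -3.4, -2.4, -1.2, 0.3),
    ("peer02", "feels accepted by peers", False, 3.2, -3.0, -2.0, -0.8, 0.6),
    ("peer03", "other kids want to be around them", False, 2.4, -3.6, -2.6, -1.4, 0.1),
    ("peer04", "able to count on friends", False, 3.5, -2.9, -1.8, -0.6, 1.0),
    ("peer05", "shares experiences with friends", False, 2.0, -3.8, -2.8, -1.6, -0.2),
    ("peer06", "friends help out when needed", False, 3.0, -3.1, -2.1, -0.9, 0.8),
    ("peer07", "gets along with other kids", False, 2.6, -3.3, -2.3, -1.1, 0.4),
    ("peer08", "makes friends easily", False, 3.7, -2.8, -1.7, -0.4, 1.4),
    ("peer09", "invited to join activities", False, 2.2, -3.5, -2.5, -1.3, 0.0),
    ("peer10", "liked by classmates", False, 3.1, -3.0, -1.9, -0.7, 1.2),
    ("peer11", "has close friends to talk to", False, 2.9, -3.2, -2.2, -1.0, 0.5),
    ("peer12", "does things with other kids", False, 3.3, -2.7, -1.6, -0.3, 1.7),
    ("peer13", "feels good about friendships", False, 2.5, -3.4, -2.4, -1.2, 0.2),
    ("peer14", "others pick them for their team", False, 3.4, -2.9, -1.8, -0.5, 2.0),
    ("peer15", "keeps to themselves (reverse-worded)", True, 0.78, -3.8, -2.9, -1.9, -0.9),
]

#: The fixed 8-item short form drawn from the peer-relationships style bank.
SHORT_FORM_IDS = ["peer01", "peer02", "peer04", "peer06", "peer08", "peer10",
                  "peer12", "peer14"]


def peer_bank() -> ItemBank:
    """A 15-item, 5-category peer-relationships style reference bank.

    Discriminations span 0.78-3.7 and thresholds -3.8 to 0.5, emulating a
    well-targeted pediatric social-health item bank calibrated on a general
    population (mostly negative thresholds => ceiling-prone data). Exactly
    one item is reverse-worded with low discrimination.
    """
    return ItemBank(
        Item(id=i, label=lab, reverse_worded=rev, a=a, b=(b1, b2, b3, b4))
        for i, lab, rev, a, b1, b2, b3, b4 in _PEER_BANK_TABLE
    )


_LEGACY_SUBSCALES = {
    "physical": 8,
    "emotional": 5,
    "social": 5,
    "school": 5,
}


def legacy_subscale_assignment() -> dict[str, list[str]]:
    """Item-id layout of the 23-item legacy instrument (8/5/5/5 subscales)."""
    out: dict[str, list[str]] = {}
    for name, n in _LEGACY_SUBSCALES.items():
        out[name] = [f"{name}{j + 1:02d}" for j in range(n)]
    return out


def onefactor_bank() -> ItemBank:
    """The 14 positively worded peer-bank items: a cleanly unidimensional,
    strongly scalable bank (population Mokken H ~ 0.67) used for the
    clean-assumptions scenario.  The reverse-worded low-discrimination item
    is the bank's known problem child and is exercised separately by the
    item-fit diagnostics."""
    return ItemBank([it for it in peer_bank() if not it.reverse_worded])


def recovery_bank() -> ItemBank:
    """A 15-item K=5 bank with well-interior thresholds for parameter-recovery
    simulations: a spans [0.8, 3.5], thresholds within [-2.2, 2.2]."""
    items = []
    for i in range(15):
        a = 0.8 + 2.7 * i / 14
        shift = -0.4 + 0.8 * ((i * 7) % 15) / 14
        b = tuple(np.array([-1.8, -0.6, 0.6, 1.8]) + shift)
        items.append(Item(id=f"it{i + 1:02d}", a=float(a), b=b))
    return ItemBank(items)
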