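"""Reliability, efficiency, norm statistics, construct validity, and
legacy-instrument scoring.

On the standardized theta metric, an EAP standard error maps to marginal
reliability ``1 - se^2``; the conventional cut SE(theta) < 0.32
corresponds to reliability 0.90.  Measurement efficiency per respondent
is ``(1 - se^2) / n_items`` (items actually administered, which for a CAT
varies per respondent); relative efficiency between two instruments is
the ratio of their mean efficiencies over the same respondents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .banks import legacy_subscale_assignment

RELIABLE_SE = 0.32


def response_rate(completed: int, invited: int) -> float:
    """Survey response rate as a percentage."""
    if invited <= 0 or completed < 0 or completed > invited:
        raise ValueError("need 0 <= completed <= invited with invited > 0")
    return 100.0 * completed / invited


def reliability_from_se(se: float) -> float:
    """Marginal reliability ``1 - se^2`` of a theta estimate.

    ``se`` must be on the standardized (SD = 1) theta metric; values
    above 3 look like T-metric standard errors and trigger a warning.
    """
    se = float(se)
    if se <= 0:
        raise ValueError("se must be positive")
    if se > 3:
        warnings.warn(
            f"se={se} is implausibly large for the standardized metric; "
            "did you pass a T-score standard error (10x too big)?"
        )
    return 1.0 - se**2


def efficiency(se, n_items) -> np.ndarray | float:
    """Per-respondent measurement efficiency ``(1 - se^2) / n_items``."""
    se_arr = np.asarray(se, dtype=float)
    n_arr = np.asarray(n_items, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("n_items must be >= 1")
    out = (1.0 - se_arr**2) / n_arr
    return float(out) if out.ndim == 0 else out


def relative_efficiency(se_a, n_items_a, se_b, n_items_b) -> float:
    """Mean efficiency of instrument A over mean efficiency of B, on
    paired per-respondent estimates.  Values < 1 mean A is less efficient."""
    ea = np.asarray(efficiency(se_a, n_items_a), dtype=float)
    eb = np.asarray(efficiency(se_b, n_items_b), dtype=float)
    if ea.shape != eb.shape:
        raise ValueError("paired estimates required: lengths differ")
    return float(np.mean(ea) / np.mean(eb))


def percent_reliable(se, threshold: float = RELIABLE_SE) -> float:
    """Percentage of respondents measured reliably: se strictly below the
    threshold (default 0.32; a respondent exactly at 0.32 does not count)."""
    se_arr = np.asarray(se, dtype=float)
    if se_arr.size == 0:
        raise ValueError("no estimates supplied")
    return float(100.0 * np.mean(se_arr < threshold))


@dataclass
class NormTable:
    """Reference-population summary of T-scores with the three-band
    functioning cut-offs: poor (bottom 5%), fair (6th-25th percentile),
    good (above the 25th percentile)."""

    mean_t: float
    sd_t: float
    poor_max: float   # T at the empirical 5th percentile (poor: T <= this)
    good_min: float   # T just above the empirical 25th percentile (good: T >= this)
    n: int

    def classify(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.where(t <= self.poor_max, "poor",
                       np.where(t > self.good_min, "good", "fair"))
        return out

    def to_dict(self) -> dict:
        return {
            "mean_t": self.mean_t,
            "sd_t": self.sd_t,
            "poor_max": self.poor_max,
            "good_min": self.good_min,
            "n": self.n,
        }


def norm_statistics(t_scores) -> NormTable:
    """Empirical norms: mean/SD of T and the percentile band boundaries
    (linear-interpolation quantiles).  Bands are half-open and exhaustive:
    poor T <= q05 < fair T <= q25 < good."""
    t = np.asarray(t_scores, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    if t.size < 100:
        warnings.warn(f"norm statistics from only {t.size} scores")
    q05, q25 = np.quantile(t, [0.05, 0.25])
    return NormTable(
        mean_t=float(t.mean()),
        sd_t=float(t.std(ddof=1)) if t.size > 1 else 0.0,
        poor_max=float(q05),
        good_min=float(q25),
        n=int(t.size),
    )


# ---------------------------------------------------------------------------
# Construct validity
# ---------------------------------------------------------------------------

@dataclass
class ConstructValidityResult:
    correlations: dict[str, float]
    hypotheses: dict[str, bool]
    fraction_met: float
    sufficient: bool  # >= 75% of hypotheses met


def construct_validity(t_scores, subscale_scores: pd.DataFrame,
                       target_subscale: str = "social",
                       r_expected: float = 0.50,
                       delta_expected: float = 0.10,
                       sufficient_fraction: float = 0.75) -> ConstructValidityResult:
    """Correlation hypotheses against a multi-subscale legacy instrument.

    Hypothesis 1: Pearson r with the target subscale strictly exceeds
    ``r_expected`` (r = 0.50 exactly does not satisfy "> 0.50").
    Hypotheses 2..m: the target correlation exceeds each other subscale's
    correlation by more than ``delta_expected``.
    """
    t = np.asarray(t_scores, dtype=float)
    if len(t) != len(subscale_scores):
        raise ValueError("paired complete observations required")
    corrs: dict[str, float] = {}
    for col in subscale_scores.columns:
        y = subscale_scores[col].to_numpy(dtype=float)
        if np.std(y) == 0 or np.std(t) == 0:
            raise ValueError(f"zero variance in {col!r} or in the T-scores")
        corrs[col] = float(np.corrcoef(t, y)[0, 1])
    if target_subscale not in corrs:
        raise ValueError(f"target subscale {target_subscale!r} not present")
    r_t = corrs[target_subscale]
    hyps: dict[str, bool] = {f"r_{target_subscale}_gt_{r_expected}": r_t > r_expected}
    for col, r in corrs.items():
        if col == target_subscale:
            continue
        hyps[f"delta_vs_{col}_gt_{delta_expected}"] = (r_t - r) > delta_expected
    frac = sum(hyps.values()) / len(hyps)
    return ConstructValidityResult(
        correlations=corrs,
        hypotheses=hyps,
        fraction_met=frac,
        sufficient=frac >= sufficient_fraction,
    )


# ---------------------------------------------------------------------------
# Legacy (0-100) scoring
# ---------------------------------------------------------------------------

def score_legacy(responses, assignment: dict[str, list[str]] | None = None
                 ) -> pd.DataFrame:
    """Standard 0-100 scoring of the 23-item legacy instrument.

    Item categories 1..5 are problem frequencies (1 = never a problem);
    the linear transform ``(5 - c) * 25`` maps them to 100/75/50/25/0 so
    that higher scores mean better functioning.  Subscale scores are item
    means; the total score is the mean over all items (equivalently the
    item-count-weighted mean of the subscales).
    """
    from .banks import ResponseMatrix

    df = responses.data if isinstance(responses, ResponseMatrix) else pd.DataFrame(responses)
    assignment = assignment or legacy_subscale_assignment()
    vals = df.to_numpy(dtype=float)
    if np.any((vals < 1) | (vals > 5) | (vals != np.round(vals))):
        bad = np.argwhere((vals < 1) | (vals > 5) | (vals != np.round(vals)))[0]
        raise ValueError(
            f"legacy categories must be integers 1..5; offending cell "
            f"row {bad[0]}, column {df.columns[bad[1]]!r}"
        )
    transformed = (5.0 - df) * 25.0
    out = pd.DataFrame(index=df.index)
    for name, ids in assignment.items():
        missing = set(ids) - set(df.columns)
        if missing:
            raise ValueError(f"subscale {name!r}: missing items {sorted(missing)}")
        out[name] = transformed[ids].mean(axis=1)
    all_items = [i for ids in assignment.values() for i in ids]
    out["total"] = transformed[all_items].mean(axis=1)
    return out


@dataclass
class ReliabilityReport:
    """Per-instrument reliability/efficiency summary (one row per
    instrument in :meth:`to_frame`)."""

    instrument: str
    n_items: float  # mean items administered (fixed count for static forms)
    mean_se: float
    pct_reliable: float
    mean_efficiency: float
    mean_t: float
    sd_t: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def reliability_report(instrument: str, se, n_items, t_scores) -> ReliabilityReport:
    """Assemble the per-instrument summary from per-respondent estimates."""
    se_arr = np.asarray(se, dtype=float)
    n_arr = np.broadcast_to(np.asarray(n_items, dtype=float), se_arr.shape)
    t = np.asarray(t_scores, dtype=float)
    return ReliabilityReport(
        instrument=instrument,
        n_items=float(n_arr.mean()),
        mean_se=float(se_arr.mean()),
        pct_reliable=percent_reliable(se_arr),
        mean_efficiency=float(np.mean(efficiency(se_arr, n_arr))),
        mean_t=float(t.mean()),
        sd_t=float(t.std(ddof=1)),
    )
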