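"""Synthetic ordinal response data with the structure the validation
pipeline assumes.

The generator emulates a general-population survey of a well-targeted
5-category item bank: latent traits drawn from a normal population, item
responses from the graded response model, an acquiescent "ceiling"
subgroup that marks the maximum raw category on every item (including the
reverse-worded one, which after reverse-scoring lands at the minimum), a
two-population design with parameter-level DIF, and a 23-item legacy
instrument (8/5/5/5 subscales) driven by correlated constructs.

Responses are stored as administered (raw orientation); analyses recode
reverse-worded items via ``ResponseMatrix.recoded(bank)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .banks import (
    Item,
    ItemBank,
    ResponseMatrix,
    legacy_subscale_assignment,
    peer_bank,
)
from .grm import category_probabilities

#: Study-scale defaults: the survey conditions the pipeline emulates.
#: 527 of the 1327 invited to the battery containing this item bank
#: completed it; 1098 of 2654 invited overall completed either battery.
STUDY_N = 527
STUDY_INVITED = 1327
STUDY_TOTAL_COMPLETED = 1098
STUDY_TOTAL_INVITED = 2654
STUDY_CEILING_FRACTION = 0.063


@dataclass(frozen=True)
class DIFSpec:
    """Per-item parameter modification applied to group B before sampling.

    ``threshold_shift`` adds a constant to every threshold (uniform DIF);
    ``discrimination_ratio`` multiplies the discrimination (non-uniform DIF).
    """

    threshold_shift: Mapping[str, float] = field(default_factory=dict)
    discrimination_ratio: Mapping[str, float] = field(default_factory=dict)

    def apply(self, bank: ItemBank) -> ItemBank:
        items = []
        for it in bank:
            a = it.a * float(self.discrimination_ratio.get(it.id, 1.0))
            shift = float(self.threshold_shift.get(it.id, 0.0))
            b = tuple(x + shift for x in it.b)
            items.append(replace(it, a=a, b=b))
        return ItemBank(items)

    def item_ids(self) -> set[str]:
        return set(self.threshold_shift) | set(self.discrimination_ratio)


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated sample.

    Defaults are the study conditions: n=527 respondents, theta ~ N(0, 1),
    and a 6.3% ceiling subgroup, on the 15-item peer-relationships style
    reference bank.
    """

    n_respondents: int = STUDY_N
    item_bank: ItemBank = field(default_factory=peer_bank)
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    ceiling_fraction: float = STUDY_CEILING_FRACTION
    dif_spec: DIFSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents <= 0:
            raise ValueError("n_respondents must be positive")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        if not 0.0 <= self.ceiling_fraction <= 1.0:
            raise ValueError("ceiling_fraction must be in [0, 1]")
        if self.dif_spec is not None:
            unknown = self.dif_spec.item_ids() - set(self.item_bank.item_ids)
            if unknown:
                raise ValueError(f"dif_spec references unknown items: {sorted(unknown)}")

    def to_json(self, path) -> None:
        d = {
            "n_respondents": self.n_respondents,
            "theta_mean": self.theta_mean,
            "theta_sd": self.theta_sd,
            "ceiling_fraction": self.ceiling_fraction,
            "seed": self.seed,
            "item_bank": self.item_bank.to_dict(),
            "dif_spec": None
            if self.dif_spec is None
            else {
                "threshold_shift": dict(self.dif_spec.threshold_shift),
                "discrimination_ratio": dict(self.dif_spec.discrimination_ratio),
            },
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        dif = d.get("dif_spec")
        return cls(
            n_respondents=d["n_respondents"],
            item_bank=ItemBank.from_dict(d["item_bank"]),
            theta_mean=d["theta_mean"],
            theta_sd=d["theta_sd"],
            ceiling_fraction=d["ceiling_fraction"],
            dif_spec=None if dif is None else DIFSpec(
                threshold_shift=dif.get("threshold_shift", {}),
                discrimination_ratio=dif.get("discrimination_ratio", {}),
            ),
            seed=d["seed"],
        )


def _sample_grm(bank: ItemBank, thetas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw 1-based categories from the GRM at each theta, raw orientation
    (reverse-worded items are flipped back to as-administered coding)."""
    n = len(thetas)
    out = np.empty((n, len(bank)), dtype=int)
    u = rng.random((n, len(bank)))
    for j, it in enumerate(bank):
        P = category_probabilities(it, thetas)  # (n, K)
        cum = np.cumsum(P, axis=1)
        cat = (u[:, j][:, None] > cum[:, :-1]).sum(axis=1)  # 0-based on model scale
        if it.reverse_worded:
            cat = (it.n_categories - 1) - cat
        out[:, j] = cat + 1
    return out


def generate_responses(config: SimulationConfig) -> ResponseMatrix:
    """Simulate a respondent-by-item matrix under ``config``.

    Each respondent draws theta ~ Normal(theta_mean, theta_sd^2) and
    responds per the GRM; a seeded random subset of size
    ``round(ceiling_fraction * n)`` is then overwritten with the maximum
    raw category on every item (acquiescent responding, not extreme true
    theta).  True thetas are retained for recovery tests.
    """
    bank = config.item_bank
    if config.dif_spec is not None:
        bank = config.dif_spec.apply(bank)
    rng = np.random.default_rng(config.seed)
    thetas = rng.normal(config.theta_mean, config.theta_sd, config.n_respondents)
    raw = _sample_grm(bank, thetas, rng)

    n_ceiling = int(round(config.ceiling_fraction * config.n_respondents))
    if n_ceiling > 0:
        ceil_idx = rng.choice(config.n_respondents, size=n_ceiling, replace=False)
        for j, it in enumerate(bank):
            raw[ceil_idx, j] = it.n_categories

    df = pd.DataFrame(raw, columns=bank.item_ids)
    return ResponseMatrix(df, true_theta=pd.Series(thetas, index=df.index))


def generate_two_group(config_a: SimulationConfig, config_b: SimulationConfig) -> ResponseMatrix:
    """Stack two simulated samples with group labels A/B.

    Group B's item parameters are modified by its ``dif_spec`` before
    sampling (uniform DIF = threshold shift, non-uniform = discrimination
    ratio), giving known ground truth for power studies.
    """
    ids_a, ids_b = config_a.item_bank.item_ids, config_b.item_bank.item_ids
    if ids_a != ids_b:
        raise ValueError("the two configs must share the same item identifiers")
    if config_a.item_bank.n_categories != config_b.item_bank.n_categories:
        raise ValueError("the two configs must share category counts")
    if config_a.dif_spec is not None:
        raise ValueError("dif_spec belongs on config_b (group A is the reference)")

    rm_a = generate_responses(config_a)
    rm_b = generate_responses(config_b)
    data = pd.concat([rm_a.data, rm_b.data], ignore_index=True)
    group = pd.Series(["A"] * rm_a.n_respondents + ["B"] * rm_b.n_respondents,
                      index=data.index)
    theta = pd.concat([rm_a.true_theta, rm_b.true_theta], ignore_index=True)
    return ResponseMatrix(data, group=group, true_theta=theta)


# ---------------------------------------------------------------------------
# Legacy instrument
# ---------------------------------------------------------------------------

# Latent correlation of each subscale's driving construct with the item-bank
# theta, as a multiple of target_r.  The social subscale is the construct
#-validity target; the other three are deliberately weaker, emulating a
# generic HRQOL instrument whose non-social domains overlap less.
_SUBSCALE_R_FACTOR = {"social": 1.0, "physical": 0.50, "emotional": 0.65, "school": 0.60}

# Discriminations around 2 and problem-frequency thresholds (problems are
# rare in a general population, so thresholds sit mostly above the mean).
_LEGACY_A = [2.0, 2.3, 1.8, 2.5, 2.1, 1.9, 2.2, 2.4]
_LEGACY_B_BASE = np.array([-0.4, 0.5, 1.3, 2.1])


def _legacy_bank() -> ItemBank:
    items = []
    k = 0
    for name, ids in legacy_subscale_assignment().items():
        for j, item_id in enumerate(ids):
            a = _LEGACY_A[(k + j) % len(_LEGACY_A)]
            b = tuple(_LEGACY_B_BASE + 0.15 * ((j % 3) - 1))
            items.append(Item(id=item_id, a=a, b=b))
        k += 3
    return ItemBank(items)


def generate_legacy_instrument(responses: ResponseMatrix, target_r: float,
                               seed: int) -> ResponseMatrix:
    """Simulate a 23-item, 4-subscale (8/5/5/5) legacy instrument for the
    respondents in ``responses``.

    Each subscale is driven by a latent construct correlated with the
    respondents' true theta: the social subscale at ``target_r``, the
    physical/emotional/school subscales at 0.50/0.65/0.60 x ``target_r``.
    Items are worded as problem frequencies (1 = never a problem), so item
    responses *decrease* with the construct; the standard 0-100 transform
    in :func:`irtval.metrics.score_legacy` restores higher = better.
    """
    if not 0.0 < target_r < 1.0:
        raise ValueError("target_r must be in (0, 1)")
    if responses.n_respondents == 0:
        raise ValueError("responses must be non-empty")
    if responses.true_theta is None:
        raise ValueError("responses must retain true_theta to drive the legacy construct")

    rng = np.random.default_rng(seed)
    theta = responses.true_theta.to_numpy()
    theta_std = (theta - theta.mean()) / theta.std() if theta.std() > 0 else theta * 0.0

    bank = _legacy_bank()
    assignment = legacy_subscale_assignment()
    cols: dict[str, np.ndarray] = {}
    for name, ids in assignment.items():
        r = min(target_r * _SUBSCALE_R_FACTOR[name], 0.999)
        eta = r * theta_std + np.sqrt(1.0 - r**2) * rng.normal(size=len(theta_std))
        sub = ItemBank([bank[i] for i in ids])
        # responses increase with problems = decrease with functioning
        raw = _sample_grm(sub, -eta, rng)
        for j, item_id in enumerate(ids):
            cols[item_id] = raw[:, j]

    df = pd.DataFrame(cols, index=responses.data.index)
    return ResponseMatrix(df, group=responses.group, true_theta=responses.true_theta)


def study_simulation(seed: int = 0, n: int = STUDY_N,
                     ceiling_fraction: float = STUDY_CEILING_FRACTION,
                     ) -> tuple[ResponseMatrix, ResponseMatrix]:
    """One full study-like dataset: item-bank responses plus the paired
    legacy instrument (target latent correlation 0.8)."""
    cfg = SimulationConfig(n_respondents=n, ceiling_fraction=ceiling_fraction, seed=seed)
    rm = generate_responses(cfg)
    legacy = generate_legacy_instrument(rm, target_r=0.8, seed=seed + 1)
    return rm, legacy
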