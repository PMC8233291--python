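"""Shared fixtures.  Heavy simulations are session-scoped so module tests
and the acceptance suite reuse one computation."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from irtval.banks import onefactor_bank, peer_bank, recovery_bank
from irtval.datasets import (
    DIFSpec,
    SimulationConfig,
    generate_responses,
    generate_two_group,
    study_simulation,
)
from irtval.dif import detect_dif
from irtval.factor import OneFactorModel, check_local_independence
from irtval.grm import GradedResponseModel
from irtval.mokken import mokken_h


@pytest.fixture(scope="session")
def study_data():
    """One study-scale dataset: 527 respondents, 15 items, 6.3% ceiling
    subgroup, plus the paired legacy instrument."""
    rm, legacy = study_simulation(seed=1)
    return {"bank": peer_bank(), "responses": rm, "legacy": legacy}


@pytest.fixture(scope="session")
def recovery_fit():
    """EM calibration on n=2000 simulated from a known 15-item bank."""
    bank = recovery_bank()
    rm = generate_responses(
        SimulationConfig(n_respondents=2000, item_bank=bank,
                         ceiling_fraction=0.0, seed=42)
    )
    model = GradedResponseModel(n_categories=5).fit(rm)
    return {"bank": bank, "responses": rm, "model": model}


def _dif_replicates(n_reps: int, dif_spec: DIFSpec | None, base_seed: int):
    bank = onefactor_bank()
    out = []
    for rep in range(n_reps):
        cfg_a = SimulationConfig(n_respondents=1000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=base_seed + 2 * rep)
        cfg_b = SimulationConfig(n_respondents=1000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=base_seed + 2 * rep + 1,
                                 dif_spec=dif_spec)
        rm = generate_two_group(cfg_a, cfg_b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(detect_dif(rm))
    return out


@pytest.fixture(scope="session")
def dif_null_replicates():
    """20 two-group replicates with identical generating parameters."""
    return _dif_replicates(20, None, base_seed=1000)


@pytest.fixture(scope="session")
def dif_power_replicates():
    """20 replicates with a +0.6 uniform threshold shift on one item."""
    return _dif_replicates(
        20, DIFSpec(threshold_shift={"peer08": 0.6}), base_seed=2000
    )


@pytest.fixture(scope="session")
def assumption_runs():
    """Assumption checks on 20 seeds of clean one-factor data (n=2000)."""
    bank = onefactor_bank()
    runs = []
    for seed in range(20):
        rm = generate_responses(
            SimulationConfig(n_respondents=2000, item_bank=bank,
                             ceiling_fraction=0.0, seed=3000 + seed)
        )
        model = OneFactorModel().fit(rm)
        runs.append({
            "indices": model.indices_,
            "flags": check_local_independence(model.residuals_),
            "n_pairs": len(bank) * (len(bank) - 1) // 2,
            "mokken": mokken_h(rm),
        })
    return runs


@pytest.fixture(scope="session")
def sx2_type1():
    """Per-item flag rates at p<0.05 over 200 model-consistent replicates
    (n=1000, refit per replicate)."""
    bank = recovery_bank()
    reps = 200
    flags = np.zeros(len(bank))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from irtval.itemfit import s_x2

        for rep in range(reps):
            rm = generate_responses(
                SimulationConfig(n_respondents=1000, item_bank=bank,
                                 ceiling_fraction=0.0, seed=300 + rep)
            )
            model = GradedResponseModel(n_categories=5, tol=1e-3, max_iter=200).fit(rm)
            res = s_x2(model.bank_, rm)
            pv = np.array([r.p_value for r in res.items])
            flags += pv < 0.05
    return flags / reps
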