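"""End-to-end validation pipeline: assumption checks, calibration, item
fit, DIF, scoring (full bank / short form / CAT), and the reliability,
efficiency, norm, and construct-validity summaries, assembled into one
report.

Stages run in order; a stage failure is recorded and every stage that
depends on it is skipped with a reason, so a partial report is always
produced.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .banks import SHORT_FORM_IDS, ItemBank, ResponseMatrix
from .cat import CATConfig, batch_cat
from .dif import detect_dif
from .factor import BifactorModel, OneFactorModel, check_local_independence
from .grm import GradedResponseModel, eap_scores, item_information
from .itemfit import item_fit_plot_data, s_x2
from .metrics import (
    construct_validity,
    norm_statistics,
    percent_reliable,
    relative_efficiency,
    reliability_report,
    score_legacy,
)
from .mokken import mokken_h


_CONFIG_FIELDS: dict[str, tuple[type, float]] = {
    # name: (type, default) — thresholds default to the conventional
    # criteria for this family of instruments
    "se_reliable": (float, 0.32),
    "dif_criterion": (float, 0.02),
    "sx2_misfit_p": (float, 0.001),
    "residual_threshold": (float, 0.20),
    "mokken_item_min": (float, 0.30),
    "mokken_scale_min": (float, 0.50),
    "cfi_min": (float, 0.95),
    "tli_min": (float, 0.95),
    "rmsea_max": (float, 0.08),
    "srmr_max": (float, 0.10),
    "omega_h_min": (float, 0.80),
    "ecv_min": (float, 0.60),
    "construct_r": (float, 0.50),
    "construct_delta": (float, 0.10),
    "construct_fraction": (float, 0.75),
    "cat_max_items": (int, 8),
    "seed": (int, 0),
}


@dataclass
class PipelineConfig:
    """Analysis thresholds and settings; all criteria configurable,
    defaulting to the conventional values."""

    se_reliable: float = 0.32
    dif_criterion: float = 0.02
    sx2_misfit_p: float = 0.001
    residual_threshold: float = 0.20
    mokken_item_min: float = 0.30
    mokken_scale_min: float = 0.50
    cfi_min: float = 0.95
    tli_min: float = 0.95
    rmsea_max: float = 0.08
    srmr_max: float = 0.10
    omega_h_min: float = 0.80
    ecv_min: float = 0.60
    construct_r: float = 0.50
    construct_delta: float = 0.10
    construct_fraction: float = 0.75
    cat_max_items: int = 8
    seed: int = 0
    short_form_ids: list[str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "short_form_ids":
                if value is not None and (
                    not isinstance(value, list) or not all(isinstance(v, str) for v in value)
                ):
                    raise ValueError("short_form_ids must be a list of item ids")
                kwargs[key] = value
                continue
            if key not in _CONFIG_FIELDS:
                raise ValueError(f"unknown config key {key!r}; "
                                 f"valid keys: {sorted(_CONFIG_FIELDS) + ['short_form_ids']}")
            typ, _ = _CONFIG_FIELDS[key]
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"config key {key!r} must be numeric, got {value!r}")
            kwargs[key] = typ(value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in list(_CONFIG_FIELDS) + ["short_form_ids"]}

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StageResult:
    status: str  # "ok" | "failed" | "skipped"
    detail: str = ""
    payload: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"status": self.status, "detail": self.detail, **self.payload}


@dataclass
class ValidationReport:
    """Assembled pipeline output; every criterion boolean sits next to the
    threshold it was judged against (embedded config)."""

    config: PipelineConfig
    stages: dict[str, StageResult]
    frames: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "package_version": __version__,
                "seed": self.config.seed,
                "config_hash": self.config.content_hash(),
                "config": self.config.to_dict(),
            },
            "stages": {k: v.to_dict() for k, v in self.stages.items()},
        }

    def tables(self) -> dict[str, pd.DataFrame]:
        return self.frames


def _select_short_form(bank: ItemBank, config: PipelineConfig) -> list[str]:
    if config.short_form_ids:
        missing = set(config.short_form_ids) - set(bank.item_ids)
        if missing:
            raise ValueError(f"short form items not in bank: {sorted(missing)}")
        return list(config.short_form_ids)
    if set(SHORT_FORM_IDS) <= set(bank.item_ids):
        return list(SHORT_FORM_IDS)
    # fallback: the 8 most informative items at theta = 0, deterministic
    n = min(8, len(bank))
    info = [(-item_information(it, 0.0), i) for i, it in enumerate(bank)]
    chosen = sorted(i for _, i in sorted(info)[:n])
    return [bank.item_ids[i] for i in chosen]


def run_pipeline(responses: ResponseMatrix, bank: ItemBank | None = None,
                 calibrate: bool = True,
                 legacy_responses: ResponseMatrix | None = None,
                 config: PipelineConfig | None = None) -> ValidationReport:
    """Run the full validation sequence on a response matrix.

    With ``calibrate=True`` the item parameters are estimated from the
    data (a supplied bank then only provides reverse-wording flags and
    category counts); with ``calibrate=False`` a supplied bank's
    parameters are used directly for all scoring — the workflow for
    scoring with a reference country's parameters.
    """
    cfg = config or PipelineConfig()
    stages: dict[str, StageResult] = {}
    frames: dict[str, pd.DataFrame] = {}

    if bank is not None:
        if bank.category_maps:
            responses = ResponseMatrix(bank.apply_category_maps(responses.data),
                                       responses.group, responses.true_theta)
        responses.validate_against_bank(bank)
        analysis_rm = responses.recoded(bank)
    else:
        analysis_rm = responses
    if not calibrate and bank is None:
        raise ValueError("calibrate=False requires a supplied bank")

    # ---- assumptions ---------------------------------------------------
    try:
        one = OneFactorModel().fit(analysis_rm)
        flags = check_local_independence(one.residuals_, cfg.residual_threshold)
        crit = one.indices_.meets_criteria(cfg.cfi_min, cfg.tli_min,
                                           cfg.rmsea_max, cfg.srmr_max)
        mok = mokken_h(analysis_rm)
        mok_crit = mok.meets_criteria(cfg.mokken_item_min, cfg.mokken_scale_min)
        bif = BifactorModel().fit(one.polychoric_).summary_
        bif_crit = bif.meets_criteria(cfg.omega_h_min, cfg.ecv_min)
        stages["assumptions"] = StageResult("ok", payload={
            "fit_indices": vars(one.indices_),
            "cfa_criteria": crit,
            "local_dependence_pairs": [
                {"item_a": a, "item_b": b, "residual": r} for a, b, r in flags
            ],
            "mokken": {"scale_h": mok.scale_h,
                       "item_h": mok.item_h.to_dict(),
                       "criteria": mok_crit},
            "bifactor": {"omega_h": bif.omega_h, "ecv": bif.ecv,
                         "route": bif.route, "criteria": bif_crit},
        })
        frames["mokken_item_h"] = mok.item_h.rename("H_i").rename_axis("item").reset_index()
    except Exception as exc:  # noqa: BLE001 - recorded, later stages continue
        stages["assumptions"] = StageResult("failed", detail=str(exc))

    # ---- calibration ---------------------------------------------------
    scoring_bank: ItemBank | None = None
    if calibrate:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                model = GradedResponseModel(
                    n_categories=max(bank.n_categories) if bank else None
                ).fit(analysis_rm)
            scoring_bank = model.bank_
            if model.diagnostics_.collapse_map:
                # downstream stages score on the fitted category scale
                analysis_rm = ResponseMatrix(
                    model.collapse_responses(analysis_rm),
                    analysis_rm.group, analysis_rm.true_theta,
                )
            stages["calibration"] = StageResult("ok", payload={
                "converged": model.diagnostics_.converged,
                "n_iter": model.diagnostics_.n_iter,
                "loglik": model.diagnostics_.loglik,
                "collapse_map": model.diagnostics_.collapse_map,
                "warnings": [str(w.message) for w in caught],
                "bank": model.bank_.to_dict(),
            })
            frames["calibrated_bank"] = model.bank_.to_frame()
        except Exception as exc:  # noqa: BLE001
            stages["calibration"] = StageResult("failed", detail=str(exc))
    else:
        scoring_bank = bank
        stages["calibration"] = StageResult(
            "skipped", detail="scored with supplied parameters",
            payload={"bank": bank.to_dict()},
        )

    if scoring_bank is None:
        reason = "calibration failed"
        for name in ("item_fit", "dif", "scoring", "reliability", "norms",
                     "construct_validity"):
            stages[name] = StageResult("skipped", detail=reason)
        return ValidationReport(config=cfg, stages=stages, frames=frames)

    # the scoring bank never carries reverse flags (data already recoded)
    # ---- item fit ------------------------------------------------------
    try:
        sx2 = s_x2(scoring_bank, analysis_rm, misfit_criterion=cfg.sx2_misfit_p)
        plot = item_fit_plot_data(scoring_bank, analysis_rm)
        stages["item_fit"] = StageResult("ok", payload={
            "misfit_items": [r.item_id for r in sx2.items if r.misfit],
            "table": sx2.to_frame().to_dict(orient="records"),
        })
        frames["sx2"] = sx2.to_frame()
        frames["item_fit_plot"] = plot.table
    except Exception as exc:  # noqa: BLE001
        stages["item_fit"] = StageResult("failed", detail=str(exc))

    # ---- DIF -----------------------------------------------------------
    if analysis_rm.group is not None and analysis_rm.group.nunique() == 2:
        try:
            dif = detect_dif(analysis_rm, bank=scoring_bank,
                             criterion=cfg.dif_criterion)
            stages["dif"] = StageResult("ok", payload={
                "flagged": dif.flagged_items,
                "anchors": dif.anchor_set,
                "purify_converged": dif.purify_converged,
            })
            frames["dif"] = dif.to_frame()
        except Exception as exc:  # noqa: BLE001
            stages["dif"] = StageResult("failed", detail=str(exc))
    else:
        stages["dif"] = StageResult("skipped",
                                    detail="needs a two-level group column")

    # ---- scoring: full bank, short form, CAT ---------------------------
    try:
        full = eap_scores(scoring_bank, analysis_rm)
        sf_ids = _select_short_form(scoring_bank, cfg)
        sf_bank = scoring_bank.subset(sf_ids)
        short = eap_scores(sf_bank, analysis_rm.subset_items(sf_ids))
        cat = batch_cat(scoring_bank, analysis_rm,
                        CATConfig(max_items=min(cfg.cat_max_items, len(scoring_bank)),
                                  se_stop=cfg.se_reliable))
        cat_df = cat.to_frame()
        stages["scoring"] = StageResult("ok", payload={
            "short_form_items": sf_ids,
            "cat_summary": cat.summary(),
        })
        frames["scores_full"] = full.reset_index(names="respondent")
        frames["scores_short_form"] = short.reset_index(names="respondent")
        frames["scores_cat"] = cat_df
    except Exception as exc:  # noqa: BLE001
        stages["scoring"] = StageResult("failed", detail=str(exc))
        for name in ("reliability", "norms", "construct_validity"):
            stages[name] = StageResult("skipped", detail="scoring failed")
        return ValidationReport(config=cfg, stages=stages, frames=frames)

    # ---- reliability / efficiency / norms ------------------------------
    try:
        reports = [
            reliability_report("full_bank", full["se"], len(scoring_bank),
                               full["t_score"]),
            reliability_report("short_form", short["se"], len(sf_bank),
                               short["t_score"]),
            reliability_report("cat", cat_df["se"], cat_df["n_items"],
                               cat_df["t_score"]),
        ]
        rel_frame = pd.DataFrame([r.to_dict() for r in reports])
        pairs = {}
        for a in reports:
            for b in reports:
                if a.instrument != b.instrument:
                    pairs[f"{a.instrument}_vs_{b.instrument}"] = (
                        a.mean_efficiency / b.mean_efficiency
                    )
        stages["reliability"] = StageResult("ok", payload={
            "instruments": [r.to_dict() for r in reports],
            "relative_efficiency": pairs,
            "se_threshold": cfg.se_reliable,
        })
        frames["reliability"] = rel_frame
    except Exception as exc:  # noqa: BLE001
        stages["reliability"] = StageResult("failed", detail=str(exc))

    try:
        norm = norm_statistics(full["t_score"].to_numpy())
        stages["norms"] = StageResult("ok", payload=norm.to_dict())
    except Exception as exc:  # noqa: BLE001
        stages["norms"] = StageResult("failed", detail=str(exc))

    # ---- construct validity against the legacy instrument --------------
    if legacy_responses is not None:
        try:
            legacy_scores = score_legacy(legacy_responses)
            cv = construct_validity(
                full["t_score"].to_numpy(),
                legacy_scores[[c for c in legacy_scores.columns if c != "total"]],
                r_expected=cfg.construct_r,
                delta_expected=cfg.construct_delta,
                sufficient_fraction=cfg.construct_fraction,
            )
            stages["construct_validity"] = StageResult("ok", payload={
                "correlations": cv.correlations,
                "hypotheses": cv.hypotheses,
                "fraction_met": cv.fraction_met,
                "sufficient": cv.sufficient,
            })
            frames["legacy_scores"] = legacy_scores.reset_index(names="respondent")
        except Exception as exc:  # noqa: BLE001
            stages["construct_validity"] = StageResult("failed", detail=str(exc))
    else:
        stages["construct_validity"] = StageResult(
            "skipped", detail="no legacy instrument supplied")

    return ValidationReport(config=cfg, stages=stages, frames=frames)
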