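"""End-to-end orchestration of the two analyses.

``run_baseline_analysis`` discriminates late vs early CKD at baseline with
three two-covariate logistic models (ht-TKV + age, radiomic feature + age,
radiomic feature + ht-TKV); ``run_progression_analysis`` discriminates
rapid from non-rapid eGFR decline with a radiomic-only model against an
ht-TKV-only reference. Both run the selection cascade first and then the
full validation battery; every stage is logged with counts and the
effective configuration is embedded in the report for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import texture
from .endpoints import derive_endpoints
from .imaging import extract_roi, union_masks
from .phantom import Cohort, generate_phantom
from .selection import SelectionReport, epv_limit, select_feature
from .validation import (
    auc_ci_bootstrap,
    bootstrap_average_model,
    calibration_test,
    classification_report,
    delong_compare,
    fit_logistic,
    repeated_cv,
    roc_auc,
    youden_threshold,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "cohort_feature_table",
    "run_baseline_analysis",
    "run_progression_analysis",
    "write_report",
    "validate_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis constants in one place.

    The defaults are the study constants: eGFR cut-off 60 mL/min/1.73 m^2,
    rapid-decline threshold 3 mL/min/1.73 m^2/year, significance level
    0.05, Pearson threshold 0.4, 2000 bootstrap iterations for AUC CIs,
    1000 replicates for the average-model validation and 3-fold CV
    repeated 5 times.
    """

    discretization: str = "none"
    disc_param: float | None = None
    modes: tuple[str, ...] = texture.AGGREGATION_MODES
    egfr_equation: str = "2009"
    baseline_cutoff: float = 60.0
    rapid_threshold: float = 3.0
    alpha: float = 0.05
    r_threshold: float = 0.4
    B_auc: int = 2000
    B_boot: int = 1000
    cv_k: int = 3
    cv_repeats: int = 5
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("baseline_cutoff", "rapid_threshold", "alpha", "r_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["modes"] = list(d["modes"])
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        return cls(**raw)


def cohort_feature_table(cohort: Cohort, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Generate every patient's phantom and extract the raw feature table."""
    cfg = config or PipelineConfig()
    rows = {}
    for pid, pp in cohort.phantom_params.items():
        vol, left, right = generate_phantom(pp)
        mask = union_masks(left, right)
        roi = extract_roi(vol, mask)
        rows[pid] = texture.extract_all_features(
            roi, mask, cfg.discretization, cfg.disc_param, cfg.modes
        )
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "patient_id"
    return table


def _selection_to_dict(rep: SelectionReport) -> dict:
    return {
        "status": rep.status,
        "selected": rep.selected,
        "n_features_tested": int(len(rep.p_raw)),
        "n_significant": len(rep.significant),
        "candidates": rep.candidates,
        "candidate_p_raw": {c: float(rep.p_raw[c]) for c in rep.candidates},
        "candidate_p_adjusted": {c: float(rep.p_adjusted[c]) for c in rep.candidates},
        "mean_abs_correlation": (
            None
            if rep.mean_abs_correlation is None
            else {c: float(v) for c, v in rep.mean_abs_correlation.items()}
        ),
        "r_threshold": rep.r_threshold,
        "epv_max_covariates": rep.epv_max_covariates,
        "notes": rep.notes,
    }


def _patient_covariates(visits: pd.DataFrame) -> pd.DataFrame:
    first = visits.sort_values("visit_month").groupby("patient_id").first()
    return first[["age", "ht_tkv_ml_per_m", "height_m", "sex"]].rename(
        columns={"ht_tkv_ml_per_m": "ht_tkv"}
    )


def _evaluate_model(name, X, y, cfg: PipelineConfig, seed: int, cv: bool = True) -> dict:
    model = fit_logistic(X, y)
    scores = model.predict_proba(X)
    auc = roc_auc(scores, y)
    ci = auc_ci_bootstrap(scores, y, B=cfg.B_auc, seed=seed)
    thr, j = youden_threshold(scores, y)
    report = {
        "name": name,
        "covariates": list(X.columns),
        "coefficients": {"intercept": model.intercept, **dict(zip(X.columns, map(float, model.coefficients)))},
        "converged": model.converged,
        "separation": model.separation,
        "calibration_p": calibration_test(model, X, y),
        "auc": auc,
        "auc_ci": list(ci),
        "youden_threshold": thr,
        "youden_j": j,
        "metrics": classification_report(scores, y, thr),
    }
    if cv:
        report["cv"] = repeated_cv(X, y, k=cfg.cv_k, repeats=cfg.cv_repeats, seed=seed + 1)
    n_events = int(np.sum(y))
    limit = epv_limit(n_events, len(y) - n_events)
    if X.shape[1] > limit:
        msg = f"model {name} uses {X.shape[1]} covariates; EPV rule allows {limit}"
        logger.warning(msg)
        report["epv_warning"] = msg
    return report, model, scores


def run_baseline_analysis(
    features_raw: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Late-vs-early CKD classification from baseline eGFR.

    ``features_raw`` is the per-patient raw feature table (patients in the
    index); ``clinical`` is the long visit-level table. Returns the
    consolidated report (also written, with figures, when ``out_dir`` is
    given).
    """
    cfg = config or PipelineConfig()
    stage = "endpoints"
    try:
        endpoints = derive_endpoints(
            clinical, cfg.egfr_equation, cfg.baseline_cutoff, cfg.rapid_threshold
        )
        pids = features_raw.index.intersection(endpoints.index)
        endpoints = endpoints.loc[pids]
        logger.info("baseline analysis: %d patients with features and endpoints", len(pids))
        y = (endpoints["baseline_class"] == "late").astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("single baseline class in the cohort")

        stage = "zscore"
        z = texture.zscore_table(features_raw.loc[pids])

        stage = "selection"
        sel = select_feature(z, y, alpha=cfg.alpha, r_threshold=cfg.r_threshold)
        if sel.status != "selected":
            raise ValueError("no feature survived the screening cascade")
        feat = sel.selected
        logger.info("selected feature: %s", feat)

        stage = "models"
        cov = _patient_covariates(clinical).loc[pids]
        designs = {
            "ht-TKV-age": pd.DataFrame({"ht_tkv": cov["ht_tkv"], "age": cov["age"]}, index=pids),
            "radiomic-age": pd.DataFrame({feat: z.loc[pids, feat], "age": cov["age"]}, index=pids),
            "radiomic-ht-TKV": pd.DataFrame({feat: z.loc[pids, feat], "ht_tkv": cov["ht_tkv"]}, index=pids),
        }
        models = {}
        scores = {}
        for i, (name, X) in enumerate(designs.items()):
            rep, model, sc = _evaluate_model(name, X, y, cfg, seed=cfg.seed + 10 * i)
            models[name] = rep
            scores[name] = sc

        stage = "delong"
        pairs = [("radiomic-age", "ht-TKV-age"), ("radiomic-age", "radiomic-ht-TKV"), ("ht-TKV-age", "radiomic-ht-TKV")]
        delong = []
        for a, b in pairs:
            dauc, zstat, p = delong_compare(scores[a], scores[b], y)
            delong.append({"model_a": a, "model_b": b, "delta_auc": dauc, "z": zstat, "p": p})

        report = {
            "analysis": "baseline",
            "config": cfg.to_dict(),
            "n_patients": int(len(pids)),
            "n_late": int(y.sum()),
            "n_early": int(len(y) - y.sum()),
            "selection": _selection_to_dict(sel),
            "models": models,
            "delong": delong,
        }
    except Exception as exc:
        logger.error("baseline analysis failed at stage %r: %s", stage, exc)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            (Path(out_dir) / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise

    if out_dir is not None:
        _write_outputs(report, scores, y, Path(out_dir), "baseline")
    return report


def run_progression_analysis(
    features_raw: pd.DataFrame,
    clinical: pd.DataFrame,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Rapid vs non-rapid eGFR-decline classification.

    Applies the eligibility filter (at least three creatinine values over
    at least six months) before slope estimation; excluded patients are
    listed with their reasons.
    """
    cfg = config or PipelineConfig()
    stage = "endpoints"
    try:
        endpoints = derive_endpoints(
            clinical, cfg.egfr_equation, cfg.baseline_cutoff, cfg.rapid_threshold
        )
        pids_all = features_raw.index.intersection(endpoints.index)
        endpoints = endpoints.loc[pids_all]
        eligible = endpoints[endpoints["progression_class"].notna()]
        excluded = endpoints[endpoints["progression_class"].isna()]
        logger.info(
            "progression analysis: %d of %d patients eligible for slope estimation",
            len(eligible),
            len(pids_all),
        )
        pids = eligible.index
        y = (eligible["progression_class"] == "rapid").astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("single progression class among eligible patients")

        stage = "zscore"
        z = texture.zscore_table(features_raw.loc[pids_all]).loc[pids]

        stage = "selection"
        sel = select_feature(z, y, alpha=cfg.alpha, r_threshold=cfg.r_threshold)
        if sel.status != "selected":
            raise ValueError("no feature survived the screening cascade")
        feat = sel.selected
        logger.info("selected feature: %s", feat)

        stage = "models"
        cov = _patient_covariates(clinical).loc[pids]
        designs = {
            "radiomic": pd.DataFrame({feat: z[feat]}, index=pids),
            "ht-TKV": pd.DataFrame({"ht_tkv": cov["ht_tkv"]}, index=pids),
        }
        models = {}
        scores = {}
        for i, (name, X) in enumerate(designs.items()):
            rep, model, sc = _evaluate_model(name, X, y, cfg, seed=cfg.seed + 10 * i, cv=False)
            models[name] = rep
            scores[name] = sc

        stage = "bootstrap_average_model"
        _, avg_metrics = bootstrap_average_model(
            designs["radiomic"], y, B=cfg.B_boot, seed=cfg.seed + 100
        )
        models["radiomic"]["bootstrap_average"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in avg_metrics.items()
        }

        report = {
            "analysis": "progression",
            "config": cfg.to_dict(),
            "n_patients_total": int(len(pids_all)),
            "n_analyzed": int(len(pids)),
            "n_rapid": int(y.sum()),
            "n_non_rapid": int(len(y) - y.sum()),
            "excluded": [
                {"patient_id": str(pid), "reason": str(row["exclusion_reason"])}
                for pid, row in excluded.iterrows()
            ],
            "selection": _selection_to_dict(sel),
            "models": models,
        }
    except Exception as exc:
        logger.error("progression analysis failed at stage %r: %s", stage, exc)
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            (Path(out_dir) / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise

    if out_dir is not None:
        _write_outputs(report, scores, y, Path(out_dir), "progression")
    return report


# --- report I/O ---------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a run report deterministically (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


_REQUIRED_KEYS = {
    "baseline": {"analysis", "config", "n_patients", "selection", "models", "delong"},
    "progression": {"analysis", "config", "n_analyzed", "excluded", "selection", "models"},
}

_REQUIRED_MODEL_KEYS = {"auc", "auc_ci", "youden_threshold", "metrics", "coefficients"}


def validate_report(report: dict) -> None:
    """Structural check of a run report; raises on missing keys."""
    kind = report.get("analysis")
    if kind not in _REQUIRED_KEYS:
        raise ValueError(f"unknown analysis kind {kind!r}")
    missing = _REQUIRED_KEYS[kind] - set(report)
    if missing:
        raise ValueError(f"report is missing keys: {sorted(missing)}")
    for name, model in report["models"].items():
        mmissing = _REQUIRED_MODEL_KEYS - set(model)
        if mmissing:
            raise ValueError(f"model {name} is missing keys: {sorted(mmissing)}")


def _write_outputs(report: dict, scores: dict, y: np.ndarray, out_dir: Path, kind: str) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(report, out_dir / f"{kind}_report.json")
    # ROC coordinates and figure
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    rows = []
    for name, sc in scores.items():
        fpr, tpr = _roc_curve(sc, y)
        rows.extend({"model": name, "fpr": f, "tpr": t} for f, t in zip(fpr, tpr))
        auc = report["models"][name]["auc"]
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.2f})")
    pd.DataFrame(rows).to_csv(out_dir / f"{kind}_roc.csv", index=False)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / f"{kind}_roc.png", dpi=150)
    plt.close(fig)


def _roc_curve(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-np.asarray(scores), kind="stable")
    ys = np.asarray(y)[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    tpr = np.concatenate([[0], tps / max(ys.sum(), 1)])
    fpr = np.concatenate([[0], fps / max((1 - ys).sum(), 1)])
    return fpr, tpr
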