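"""End-to-end driver: simulate/load -> preprocess -> contrast -> background
-> fit -> validate -> compare, with a YAML-configurable run description."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io, lur_model, model_comparison, preprocessing, regional_background
from . import spatial_contrast, synthetic_data, validation
from .metrics import METRICS, METRIC_UNITS

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``input_dir`` points at sites.csv / measurements.csv /
    reference.csv / predictors.csv (+ predictor_meta.json), or
    ``simulate`` is true and a synthetic campaign is generated with
    ``seed``.
    """

    input_dir: str | None = None
    simulate: bool = True
    metrics: tuple[str, ...] = METRICS
    delta: float = 0.01
    alpha: float = 0.10
    vif_threshold: float = 3.0
    zero_screen_fraction: float = 0.75
    n_splits: int = 10
    train_fraction: float = 0.5
    n_receptors: int = 40
    seed: int = 0
    out_dir: str = "oplur_out"

    def __post_init__(self) -> None:
        for nm in ("delta", "alpha", "vif_threshold", "zero_screen_fraction",
                   "train_fraction"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        for m in self.metrics:
            if m not in METRICS:
                raise ValueError(f"unrecognized metric {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "metrics" in raw:
            raw["metrics"] = tuple(raw["metrics"])
        return cls(**raw)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        camp = synthetic_data.generate_campaign(
            synthetic_data.CampaignConfig(seed=cfg.seed)
        )
        blanks = camp.config.blank_mean
        return camp.sites, camp.measurements, camp.reference, camp.predictors, blanks
    d = Path(cfg.input_dir)
    sites = io.read_sites(d / "sites.csv")
    meas = io.read_measurements(d / "measurements.csv", sites)
    ref = io.read_reference(d / "reference.csv")
    meta_path = d / "predictor_meta.json"
    table = io.read_predictors(
        d / "predictors.csv", meta_path if meta_path.exists() else None, sites
    )
    return sites, meas, ref, table, None  # external inputs assumed blank-corrected


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis chain and write all artifacts to
    ``cfg.out_dir``.  Returns the in-memory report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        sites, measurements, reference, table, blanks = _load_inputs(cfg)

        stage = "preprocess"
        annual = preprocessing.adjusted_annual_averages(
            measurements, reference, blank_means=blanks
        )
        io.write_annual_averages(annual, out / "annual_averages.csv")

        stage = "contrast"
        contrast = spatial_contrast.contrast_report(annual, sites)
        wide = annual.pivot(index="site_id", columns="metric", values="value")
        correlations = spatial_contrast.squared_pearson_matrix(wide)
        correlations.to_csv(out / "correlations.csv")
        _write_contrast_csv(contrast, out / "contrast_report.csv")

        coords_by_site = sites.set_index("site_id")[["x", "y"]]
        bundle: dict = {
            "annual": annual,
            "contrast": contrast,
            "correlations": correlations,
            "models": {},
            "validation": {},
        }

        for metric in cfg.metrics:
            stage = f"background[{metric}]"
            est = regional_background.regional_estimates(sites, annual, metric)
            est.to_csv(out / f"regional_background_{metric}.csv")
            aug = regional_background.add_regional_predictor(table, sites, annual, metric)

            stage = f"fit[{metric}]"
            y = (
                annual[annual["metric"] == metric]
                .set_index("site_id")["value"]
                .loc[aug.values.index]
            )
            max_zero = math.ceil(cfg.zero_screen_fraction * len(y))
            coords = coords_by_site.loc[y.index].to_numpy(dtype=float)
            model = lur_model.develop_model(
                y, aug, metric=metric, delta=cfg.delta, alpha=cfg.alpha,
                vif_threshold=cfg.vif_threshold, max_zero_sites=max_zero,
                coords=coords,
            )
            model.to_json(out / f"model_{metric}.json")
            bundle["models"][metric] = (model, aug, y)

            stage = f"validate[{metric}]"
            report = validation.validate_model(
                y, model, aug, sites,
                n_splits=cfg.n_splits, train_fraction=cfg.train_fraction,
                seed=cfg.seed, delta=cfg.delta, alpha=cfg.alpha,
                vif_threshold=cfg.vif_threshold, max_zero_sites=max_zero,
            )
            io.write_json(report.to_dict(), out / f"validation_{metric}.json")
            bundle["validation"][metric] = report

        stage = "compare"
        if len(bundle["models"]) >= 2:
            camp_cfg = synthetic_data.CampaignConfig(seed=cfg.seed)
            rec_sites, rec_pred = synthetic_data.generate_receptors(
                camp_cfg, cfg.n_receptors, seed=cfg.seed + 104729
            )
            rec_xy = rec_sites.set_index("site_id").loc[rec_pred.index, ["x", "y"]]
            for metric in cfg.metrics:
                rec_pred[regional_background.regional_predictor_name(metric)] = (
                    regional_background.interpolate_at(rec_xy, sites, annual, metric)
                )
            models = [bundle["models"][m][0] for m in cfg.metrics]
            comparison = model_comparison.compare_predictions(models, rec_pred)
            comparison.to_csv(out / "model_comparison.csv")
            bundle["comparison"] = comparison

        stage = "summary"
        summary = format_summary(bundle, cfg)
        (out / "summary.txt").write_text(summary)
        bundle["summary"] = summary
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_contrast_csv(contrast: dict, path) -> None:
    rows = []
    for metric, rep in contrast.items():
        row = {
            "metric": metric,
            "range_percent": rep["range_percent"],
            "anova_F": rep["anova_F"],
            "anova_p": rep["anova_p"],
        }
        for name, r in rep["ratios"].items():
            row[f"ratio_{name}"] = r["ratio"]
            row[f"p_{name}"] = r["p"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def format_summary(bundle: dict, cfg: RunConfig) -> str:
    """Human-readable report mirroring the standard table shapes."""
    lines = ["oplur pipeline summary", "=" * 40, ""]
    for metric, rep in bundle["contrast"].items():
        lines.append(f"[{metric}] ({METRIC_UNITS[metric]})")
        lines.append(f"  spatial contrast (range % of mean): {rep['range_percent']:.0f}%")
        lines.append(
            f"  ANOVA across site types: F = {rep['anova_F']:.2f}, p = {rep['anova_p']:.3g}"
        )
        for name, r in rep["ratios"].items():
            star = "**" if r["p"] < 0.01 else ("*" if r["p"] < 0.05 else "")
            lines.append(f"  ratio {name}: {r['ratio']:.2f}{star} (p = {r['p']:.3f})")
        lines.append("")
    if isinstance(bundle.get("correlations"), pd.DataFrame):
        lines.append("Squared Pearson correlations between metrics (annual averages):")
        lines.append(bundle["correlations"].round(2).to_string())
        lines.append("")
    for metric, (model, aug, y) in bundle.get("models", {}).items():
        lines.append(f"LUR model for {metric}:")
        lines.append(
            f"  {'predictor':<32}{'coef (P10-P90)':>16}{'SE':>10}{'p':>8}{'cum adj R2':>12}"
        )
        lines.append(f"  {'intercept':<32}{model.intercept:>16.3g}"
                     f"{model.intercept_se:>10.2g}{model.intercept_p:>8.2f}{'':>12}")
        for sc in model.std_coefficients:
            lines.append(
                f"  {sc['name']:<32}{sc['std_coefficient']:>16.3g}"
                f"{sc['std_se']:>10.2g}{sc['pvalue']:>8.2f}{sc['cum_adj_r2']:>12.2f}"
            )
        diag = model.diagnostics
        moran = diag.get("morans_i")
        moran_txt = (
            f"I = {moran['I']:.3f} (p = {moran['p']:.2f})" if moran else "n/a"
        )
        lines.append(
            f"  Model R2 = {model.model_r2:.2f}; adjusted R2 = {model.adjusted_r2:.2f}; "
            f"RMSE = {model.rmse:.3g} ({METRIC_UNITS[metric]})"
        )
        lines.append(
            f"  max VIF = {diag.get('max_vif', float('nan')):.2f}; "
            f"max Cook's D = {diag.get('max_cooks_d', float('nan')):.2f}; "
            f"Moran's I: {moran_txt}"
        )
        rep = bundle["validation"].get(metric)
        if rep is not None:
            lines.append(
                f"  LOOCV R2 = {rep.loocv.r2:.2f}; LOOCV RMSE = {rep.loocv.rmse:.3g}; "
                f"HV R2 = {rep.holdout.hv_mean:.2f} +/- {rep.holdout.hv_se:.2f} (mean +/- SE)"
            )
        lines.append("")
    if isinstance(bundle.get("comparison"), pd.DataFrame):
        lines.append("Squared Pearson correlations of model predictions at receptors:")
        lines.append(bundle["comparison"].round(2).to_string())
        lines.append("")
    return "\n".join(lines)
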