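"""End-to-end analysis runner and map-ready exports.

Mirrors the study workflow on any cohort table: descriptive summaries,
univariate screening at P < 0.25, multiple logistic and auto-logistic fits,
AIC/AUC comparison, residual Moran diagnostics for both models, and a
GeoJSON export of the per-unit autocovariate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .describe import DescriptiveTable, descriptive_table
from .diagnostics import residual_moran_check
from .exceptions import AutologitError, ValidationError
from .metrics import ModelComparison, compare_models
from .models import Covariate, DesignSpec, FitResult, fit_autologistic, fit_logistic
from .moran import MoranResult
from .selection import ScreenResult, univariate_screen
from .spatial import autocovariate, build_weights
from .io import points_to_geojson

__all__ = [
    "DEFAULT_CANDIDATES",
    "PipelineConfig",
    "AnalysisReport",
    "run_pipeline",
    "export_autocovariate_map",
]

log = logging.getLogger("autologit")

# candidate covariates offered to the univariate screen; revealed_access is
# excluded by default because it is the exact sum of response and transport
# times (perfectly collinear once both are selected)
DEFAULT_CANDIDATES = [
    Covariate("sex", "binary", reference="female"),
    Covariate("age", "continuous"),
    Covariate("hypertension", "binary", reference="no"),
    Covariate("residency", "binary", reference="urban"),
    Covariate("accessibility_rate", "continuous"),
    Covariate("delay_time", "continuous"),
    Covariate("response_time", "continuous"),
    Covariate("transport_time", "continuous"),
    Covariate("screening_time", "continuous"),
    Covariate("distance_to_hospital", "continuous"),
    Covariate("los", "continuous"),
    Covariate("triage", "binary", reference="levels12"),
    Covariate("final_dx", "binary", reference="no"),
]


@dataclass
class PipelineConfig:
    radius: float | None = None  # None -> max nearest-neighbour distance
    screen_threshold: float = 0.25
    n_permutations: int = 999
    alpha: float = 0.05
    residual_type: str = "deviance"
    moran_alternative: str = "greater"
    seed: int = 0
    candidates: list = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    outcome: str = "death"


@dataclass
class AnalysisReport:
    """Everything the pipeline computes, internally consistent by design."""

    descriptive: DescriptiveTable
    screen: ScreenResult
    fit_logistic: FitResult
    fit_autologistic: FitResult
    comparison: ModelComparison
    moran_logistic: MoranResult
    moran_autologistic: MoranResult
    radius_used: float
    autocovariate_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.fit_logistic.n,
            "radius_used": self.radius_used,
            "screened": self.screen.selected_names,
            "logistic": self.fit_logistic.model_card(
                auc=self.comparison.auc_a,
                residual_moran_p=self.moran_logistic.p_value,
                residual_moran_I=self.moran_logistic.statistic,
                odds_ratios=self.fit_logistic.table["OR"].to_dict(),
            ),
            "autologistic": self.fit_autologistic.model_card(
                auc=self.comparison.auc_b,
                residual_moran_p=self.moran_autologistic.p_value,
                residual_moran_I=self.moran_autologistic.statistic,
                odds_ratios=self.fit_autologistic.table["OR"].to_dict(),
            ),
            "comparison": self.comparison.to_dict(),
            "autocovariate_path": self.autocovariate_path,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def run_pipeline(
    cohort: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> AnalysisReport:
    """Descriptive -> screen -> logistic -> auto-logistic -> diagnostics.

    Every stochastic step (Moran permutations) derives its seed from
    ``config.seed``, so (cohort, config) determines the report exactly.
    With ``outdir`` set, each stage's output is written as it completes, so
    partial results survive a failing later stage.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        log.info("pipeline stage: %s", name)

    try:
        _stage("descriptive")
        desc = descriptive_table(cohort, outcome=cfg.outcome)
        if out is not None:
            desc.to_csv(out / "descriptive.csv")

        _stage("screen")
        screen = univariate_screen(
            cfg.candidates, cohort, outcome=cfg.outcome, threshold=cfg.screen_threshold
        )
        if not screen.selected:
            raise ValidationError("no covariate passed the univariate screen")
        if out is not None:
            screen.table.to_csv(out / "screening.csv", index=False)

        _stage("weights")
        design = DesignSpec(screen.selected, outcome=cfg.outcome)
        _, _, idx = design.build(cohort)
        modelled = cohort.loc[idx]
        weights = build_weights(modelled[["unit_id", "x", "y"]], cfg.radius)

        _stage("logistic")
        fit_log = fit_logistic(design, cohort)
        if out is not None:
            fit_log.to_csv(out / "fit_logistic.csv")

        _stage("autologistic")
        fit_auto = fit_autologistic(design, cohort, weights)
        if out is not None:
            fit_auto.to_csv(out / "fit_autologistic.csv")

        _stage("comparison")
        comp = compare_models(fit_log, fit_auto)

        _stage("residual moran")
        m_log = residual_moran_check(
            fit_log,
            weights,
            residual_type=cfg.residual_type,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed,
            alternative=cfg.moran_alternative,
        )
        m_auto = residual_moran_check(
            fit_auto,
            weights,
            residual_type=cfg.residual_type,
            n_permutations=cfg.n_permutations,
            seed=cfg.seed + 1,
            alternative=cfg.moran_alternative,
        )

        _stage("export")
        ac_path = None
        if out is not None:
            ac_path = str(out / "autocovariate.geojson")
            export_autocovariate_map(
                modelled, weights, modelled[cfg.outcome].to_numpy(), ac_path
            )
    except AutologitError:
        raise
    except Exception as err:  # pragma: no cover - defensive
        raise AutologitError(f"pipeline failed: {err}") from err

    report = AnalysisReport(
        descriptive=desc,
        screen=screen,
        fit_logistic=fit_log,
        fit_autologistic=fit_auto,
        comparison=comp,
        moran_logistic=m_log,
        moran_autologistic=m_auto,
        radius_used=weights.radius,
        autocovariate_path=ac_path,
    )
    if out is not None:
        report.to_json(out / "report.json")
        (out / "model_cards.json").write_text(
            json.dumps(
                {
                    "logistic": fit_log.model_card(auc=comp.auc_a),
                    "autologistic": fit_auto.model_card(auc=comp.auc_b),
                },
                indent=2,
            )
        )
    return report


def export_autocovariate_map(
    cohort: pd.DataFrame,
    weights,
    outcome,
    path,
    zones_path=None,
) -> dict:
    """Write per-unit autocovariate values as a GeoJSON FeatureCollection.

    With ``zones_path`` (a GeoJSON file of Polygon/MultiPolygon features),
    the per-unit values are additionally aggregated to each zone by the
    mean over the points it contains, and the zone FeatureCollection (with
    ``autocovariate_mean`` and ``n_points`` properties) is returned and
    written alongside as ``<path>.zones.geojson``.
    """
    ac = autocovariate(weights, np.asarray(outcome, dtype=float))
    fc = points_to_geojson(cohort, {"autocovariate": ac}, path)
    if zones_path is None:
        return fc

    from shapely.geometry import Point, shape

    try:
        zones = json.loads(Path(zones_path).read_text())
        geoms = [shape(f["geometry"]) for f in zones["features"]]
    except (KeyError, ValueError, AttributeError, TypeError) as err:
        raise ValidationError(f"invalid zone polygon file {zones_path}: {err}")
    pts = [Point(xy) for xy in cohort[["x", "y"]].to_numpy()]
    out_feats = []
    for feat, geom in zip(zones["features"], geoms):
        mask = np.array([geom.covers(p) for p in pts])
        props = dict(feat.get("properties") or {})
        props["n_points"] = int(mask.sum())
        props["autocovariate_mean"] = float(ac[mask].mean()) if mask.any() else None
        out_feats.append(
            {"type": "Feature", "geometry": feat["geometry"], "properties": props}
        )
    zfc = {"type": "FeatureCollection", "features": out_feats}
    Path(str(path) + ".zones.geojson").write_text(json.dumps(zfc))
    return zfc
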