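"""End-to-end orchestration: simulate -> prep -> fit/search -> trends.

A :class:`RunConfig` (YAML, with JSON fallback) drives the stages; the
run emits one JSON report embedding all stage outputs, the package
version and a hash of the resolved configuration, and is idempotent for
a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .model import UsemModel, build_usem
from .panel import TimeSeriesPanel
from .prep import build_lagged, censor_spikes, cohort_covariances, standardize
from .search import SearchSettings, explore
from .simulate import default_dmn_scenario, simulate_panel
from .trends import decade_trends, edge_overlap_probability, pair_by_receiver
from .fit import fit_ml

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, report: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "usem_run"
    panel: str | None = None  # existing panel directory; None => simulate
    model: str | None = None  # prior model JSON; None => exploratory search
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # subjects_per_cohort, timepoints...
    prep: dict = field(default_factory=dict)  # censor (bool), censor_mode
    fit: dict = field(default_factory=dict)  # grouping, ...
    search: dict = field(default_factory=dict)  # SearchSettings fields
    trends: dict = field(default_factory=dict)  # cohort_axis, alpha

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} did not parse to a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "panel": self.panel,
            "model": self.model,
            "seed": self.seed,
            "simulate": self.simulate,
            "prep": self.prep,
            "fit": self.fit,
            "search": self.search,
            "trends": self.trends,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write ``report.json``.

    Stage order: simulate (unless a panel path is given) -> censor +
    standardize -> prior-model fit or exploratory search -> decade
    trends.  Any stage error raises :class:`PipelineError` with the
    partial report preserved on disk.
    """
    out = Path(config.out_dir)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "stages": {},
    }

    def fail(stage: str, exc: Exception):
        out.mkdir(parents=True, exist_ok=True)
        report["error"] = {"stage": stage, "message": str(exc)}
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        raise PipelineError(stage, exc, report) from exc

    # -- input / simulate ------------------------------------------------
    try:
        if config.panel is not None:
            src = Path(config.panel)
            if not src.exists():
                raise FileNotFoundError(f"panel directory {src} does not exist")
            panel = TimeSeriesPanel.from_dir(src)
            report["stages"]["input"] = {"panel": str(src), "subjects": len(panel.subjects)}
        else:
            sim_kw = dict(config.simulate)
            scenario = default_dmn_scenario(seed=config.seed, **sim_kw)
            panel = simulate_panel(scenario)
            out.mkdir(parents=True, exist_ok=True)
            panel.to_dir(out / "panel")
            report["stages"]["simulate"] = {
                "panel": str(out / "panel"),
                "subjects": len(panel.subjects),
                "timepoints": scenario.timepoints_per_subject,
                "cohorts": scenario.cohort_labels,
            }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - surfaced with stage context
        fail("input", exc)

    # -- prep -------------------------------------------------------------
    try:
        if config.prep.get("censor", True):
            panel = censor_spikes(panel, mode=config.prep.get("censor_mode", "difference"))
        panel = standardize(panel)
        lagged = build_lagged(panel)
        covs = cohort_covariances(lagged)
        counts = lagged.counts()
        report["stages"]["prep"] = {
            "n_uncensored_timepoints": panel.n_uncensored,
            "lagged_pairs_per_cohort": counts,
            "n_total_pairs": lagged.n_total,
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("prep", exc)

    # -- fit / search ------------------------------------------------------
    try:
        if config.model is not None:
            model = UsemModel.from_json(config.model)
            fit = fit_ml(model, covs, seed=config.seed, **config.fit)
            report["stages"]["fit"] = fit.to_dict()
        else:
            settings = SearchSettings(seed=config.seed, **config.search)
            model, trace, fit = explore(panel.node_names, covs, settings)
            out.mkdir(parents=True, exist_ok=True)
            trace.to_tsv(out / "search_trace.tsv")
            model.to_json(out / "final_model.json")
            report["stages"]["search"] = {
                "n_edges": len(model.edges),
                "stop_reason": trace.stop_reason,
                "trace": str(out / "search_trace.tsv"),
                "model": str(out / "final_model.json"),
                "fit": fit.to_dict(),
            }
        # auditability: N^(g), q, df for the fitted model
        report["stages"]["fit_accounting"] = {
            "counts": dict(fit.counts),
            "q": fit.q,
            "df": fit.df,
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)

    # -- trends ------------------------------------------------------------
    try:
        if len(covs.cohorts) >= 3 and model.edges:
            table = decade_trends(
                fit,
                cohort_axis=config.trends.get("cohort_axis"),
                alpha=config.trends.get("alpha", 0.05),
            )
            pairing = pair_by_receiver(table, model)
            out.mkdir(parents=True, exist_ok=True)
            table.to_csv(out / "trends.tsv", sep="\t", float_format="%.6g")
            report["stages"]["trends"] = {
                "table": str(out / "trends.tsv"),
                "n_significant": int(table["significant"].sum()),
                "classes": table["class"].to_dict(),
                "pairing": pairing,
            }
        if config.model is not None and "reference_model" in config.trends:
            ref = UsemModel.from_json(config.trends["reference_model"])
            ov = edge_overlap_probability(model.edges, ref.edges, model.n_nodes)
            report["stages"]["overlap"] = ov.to_dict()
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail("trends", exc)

    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
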