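"""Config-driven end-to-end runs: simulate -> curate -> split -> (select) ->
train -> predict -> evaluate, with a JSON run manifest.

A :class:`RunConfig` collects every tunable constant in one place, pre-filled
with the study defaults: MAF rarity cutoff 0.001, 2:1 train/test split,
clinical thresholds 0.9/0.1, inner 5-fold / outer 10-fold cross-validation.
All stage outputs are pure functions of (inputs, config, seeds), so two runs
with the same config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .boost_classifier import fit_adaboost, predict_pr, save_model
from .clinical_metrics import (
    PredictiveValueRates,
    ThresholdPair,
    brier,
    confusion_summary,
    pr_auc,
    predictive_values_at_prevalence,
    roc_auc,
)
from .errors import PipelineError
from .model_selection import baseline_candidate, boosting_candidate, nested_select
from .synthetic_data import FeatureGenSpec, gen_feature_table
from .variant_data import (
    default_schema,
    filter_rare,
    read_feature_table,
    split_train_test,
    write_feature_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; defaults are the study conditions."""

    out_dir: str = "run"
    input_table: Optional[str] = None  # TSV path; None = simulate
    simulate: FeatureGenSpec = field(default_factory=FeatureGenSpec)
    n_schema_features: int = 76
    maf_cutoff: float = 0.001
    train_fraction: float = 2.0 / 3.0
    upper_threshold: float = 0.9
    lower_threshold: float = 0.1
    run_selection: bool = False
    outer_k: int = 10
    inner_k: int = 5
    selection_metric: str = "pr_auc"
    n_rounds: int = 500
    tree_depth: int = 3
    seed: int = 0
    prevalence_scenarios: tuple[float, ...] = (0.6, 0.01)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = FeatureGenSpec(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prevalence_scenarios"] = list(self.prevalence_scenarios)
        return d


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest.

    On failure the manifest still records the failing stage before a
    :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": [],
        "artifacts": {},
        "status": "running",
    }
    stage = "init"
    try:
        stage = "load"
        if config.input_table:
            schema = default_schema(config.n_schema_features)
            ds = read_feature_table(config.input_table, schema)
        else:
            ds = gen_feature_table(config.simulate)
            path = out / "simulated_variants.tsv"
            write_feature_table(ds, path)
            manifest["artifacts"]["simulated_table"] = str(path)
        manifest["stages"].append({"name": stage, "n_variants": len(ds)})

        stage = "curate"
        ds = filter_rare(ds, config.maf_cutoff)
        if ds.labels is None:
            raise PipelineError(stage, "input table has no labels")
        manifest["stages"].append({"name": stage, "n_variants": len(ds)})

        stage = "split"
        train, test = split_train_test(ds, config.train_fraction, config.seed)
        manifest["stages"].append(
            {"name": stage, "n_train": len(train), "n_test": len(test)}
        )

        if config.run_selection:
            stage = "select"
            report = nested_select(
                [boosting_candidate(), baseline_candidate()],
                train,
                outer_k=config.outer_k,
                inner_k=config.inner_k,
                metric=config.selection_metric,
                seed=config.seed,
            )
            path = out / "selection.json"
            path.write_text(report.to_json() + "\n")
            manifest["artifacts"]["selection_report"] = str(path)
            manifest["stages"].append({"name": stage, "winner": report.winner})

        stage = "train"
        model = fit_adaboost(
            train, n_rounds=config.n_rounds, tree_depth=config.tree_depth, seed=config.seed
        )
        model_path = out / "model.json"
        save_model(model, model_path)
        manifest["artifacts"]["model"] = str(model_path)
        manifest["stages"].append(
            {"name": stage, "n_rounds_fit": len(model.rounds), "stopping": model.stopping_reason}
        )

        stage = "predict"
        prs = predict_pr(model, test)
        pred_path = out / "predictions.tsv"
        with open(pred_path, "w") as fh:
            fh.write("variant_id\tlabel\tpr\n")
            for v, y, p in zip(test.variants, test.labels, prs):
                fh.write(f"{v.variant_id}\t{'pathogenic' if y else 'benign'}\t{p:.10f}\n")
        manifest["artifacts"]["predictions"] = str(pred_path)
        manifest["stages"].append({"name": stage, "n_test": len(test)})

        stage = "evaluate"
        t = ThresholdPair(upper=config.upper_threshold, lower=config.lower_threshold)
        suite = confusion_summary(test.labels, prs, t)
        metrics = {
            "clinical": suite.to_dict(),
            "roc_auc": roc_auc(test.labels, prs),
            "pr_auc": pr_auc(test.labels, prs),
            "brier": brier(test.labels, prs),
        }
        try:
            rates = PredictiveValueRates.from_suite(suite)
            metrics["prevalence_scenarios"] = {
                str(pi): dict(
                    zip(("ppv", "npv"), predictive_values_at_prevalence(rates, pi))
                )
                for pi in config.prevalence_scenarios
            }
        except Exception as e:
            logger.warning("prevalence projection skipped: %s", e)
        metrics_path = out / "metrics.json"
        _dump_json(metrics, metrics_path)
        manifest["artifacts"]["metrics"] = str(metrics_path)
        manifest["stages"].append({"name": stage})

        manifest["status"] = "ok"
        return manifest
    except Exception as e:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        raise PipelineError(stage, str(e)) from e
    finally:
        _dump_json(manifest, out / "manifest.json")
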