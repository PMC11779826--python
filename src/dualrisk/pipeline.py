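"""End-to-end orchestration: Model/Results objects, configuration, and
report assembly.

:class:`DualUseRiskModel` is built from a :class:`~dualrisk.cohort.Cohort`
(or a generative configuration) and composes the full analysis —
baseline table, 64/16/20 split, random under-sampling, residual-network
training, metrics per split, impact/interaction scores, the
logistic-regression benchmark and, optionally, the pipeline-level
percentile bootstrap.  ``fit()`` returns a :class:`DualUseRiskResults`
carrying every table plus a ``summary()`` rendering; one global seed
fans out deterministically to all stage seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (
    ScoreResult,
    bootstrap_scores,
    score_all,
    scores_frame,
)
from .benchmark import LogisticFit, coefficient_correlation, fit_logistic
from .cohort import (
    Cohort,
    GenerativeModel,
    calibrate_intercept,
    default_scenario,
    generate_cohort,
    read_cohort,
)
from .nn import (
    MetricsReport,
    NetConfig,
    ResNetClassifier,
    SplitIndices,
    TrainConfig,
    build_network,
    evaluate,
    split_data,
    train,
    undersample,
)
from .tabulate import BaselineRow, baseline_frame, baseline_table, outcome_summary

__all__ = ["PipelineConfig", "DualUseRiskModel", "DualUseRiskResults", "run_pipeline", "render_report"]

REPORT_SCHEMA_VERSION = 1

_STAGES = ("cohort", "split", "rus", "net_init", "train", "bootstrap", "benchmark")


def _stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic fan-out of one global seed to named stage seeds."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Exactly one of ``generative``/``cohort_path`` must be set; the
    generative section defaults to the reference scenario.
    """

    generative: GenerativeModel | None = None
    cohort_path: str | None = None
    n: int = 50_000
    split_ratios: tuple[float, float, float] = (0.64, 0.16, 0.20)
    net: NetConfig | None = None  # inferred from features when None
    train: TrainConfig = field(default_factory=TrainConfig)
    anchor: str = "dual_system_use"
    scale: str = "probability"
    bootstrap_B: int = 0  # 0 disables the bootstrap
    bootstrap_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.generative is None) == (self.cohort_path is None):
            raise ValueError(
                "exactly one of a generative section or a cohort path is required"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML or JSON; unknown keys are rejected."""
        raw = Path(path).read_text()
        data = yaml.safe_load(raw)
        return cls.from_dict({**data, **overrides})

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("train"), dict):
            data["train"] = TrainConfig(**data["train"])
        if isinstance(data.get("net"), dict):
            data["net"] = NetConfig(**data["net"])
        if data.get("generative") == "default":
            data["generative"] = default_scenario()
        if "split_ratios" in data:
            data["split_ratios"] = tuple(data["split_ratios"])
        return cls(**data)


class DualUseRiskModel:
    """The full dual-system-use / outcome analysis over one cohort.

    Parameters
    ----------
    cohort : Cohort
        The analysis table (generated or loaded).
    config : PipelineConfig
        Split ratios, network and training settings, attribution anchor
        and scale, bootstrap settings, global seed.
    """

    def __init__(self, cohort: Cohort, config: PipelineConfig):
        self.cohort = cohort
        self.config = config

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_config(cls, config: PipelineConfig) -> "DualUseRiskModel":
        seeds = _stage_seeds(config.seed)
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            model = config.generative
            if not model.calibrated:
                calibrate_intercept(model, seed=seeds["cohort"])
            cohort = generate_cohort(model, config.n, seeds["cohort"])
        return cls(cohort, config)

    @classmethod
    def from_dataframe(
        cls, features: pd.DataFrame, outcome: np.ndarray, specs, config=None
    ) -> "DualUseRiskModel":
        """Build from a plain feature table and binary outcome vector."""
        y = np.asarray(outcome)
        cohort = Cohort(
            features=features.reset_index(drop=True),
            y=y,
            y_documented=y,
            y_coded=np.zeros_like(y),
            feature_specs=list(specs),
        )
        return cls(cohort, config or PipelineConfig(cohort_path="<memory>"))

    # -- the single-pass pipeline ----------------------------------------
    def _run_once(self, cohort: Cohort, seeds: dict[str, int]):
        cfg = self.config
        splits = split_data(cohort, cfg.split_ratios, seeds["split"])
        rus = undersample(cohort.y, splits.train, seeds["rus"])
        balanced = replace(splits, train=rus)
        net = build_network(cfg.net, seeds["net_init"], cohort.feature_specs)
        net = train(net, cohort, balanced, replace(cfg.train, seed=seeds["train"]))
        return net, splits, balanced

    def _score(self, net, cohort: Cohort):
        return score_all(net, cohort, self.config.anchor, self.config.scale)

    def fit(self, progress: bool = False) -> "DualUseRiskResults":
        """Run the full pipeline and return the results object."""
        cfg = self.config
        cohort = self.cohort
        seeds = _stage_seeds(cfg.seed)
        baseline = baseline_table(cohort)
        outcomes = outcome_summary(cohort)
        net, splits, balanced = self._run_once(cohort, seeds)
        metrics = [
            evaluate(net, cohort, balanced.train,
                     cfg.train.classification_threshold, "Training"),
            evaluate(net, cohort, splits.validation,
                     cfg.train.classification_threshold, "Validation"),
            evaluate(net, cohort, splits.test,
                     cfg.train.classification_threshold, "Test"),
        ]
        impacts, interactions = self._score(net, cohort)
        if cfg.bootstrap_B >= 2:
            def pipeline_fn(resampled: Cohort, rep_seed: int):
                rep_seeds = _stage_seeds(rep_seed)
                rnet, _, _ = self._run_once(resampled, rep_seeds)
                return self._score(rnet, resampled)
            impacts, interactions = bootstrap_scores(
                cohort,
                pipeline_fn,
                B=cfg.bootstrap_B,
                level=cfg.bootstrap_level,
                seed=seeds["bootstrap"],
                point=(impacts, interactions),
            )
        lr_fit, _ = fit_logistic(cohort, balanced.train, eval_indices=splits.test)
        try:
            corr = coefficient_correlation(impacts, lr_fit)
        except ValueError:
            corr = None
        return DualUseRiskResults(
            model=self,
            classifier=net,
            splits=splits,
            balanced_splits=balanced,
            baseline=baseline,
            outcomes=outcomes,
            metrics=metrics,
            impacts=impacts,
            interactions=interactions,
            lr_fit=lr_fit,
            impact_lr_correlation=corr,
            seeds=seeds,
        )


@dataclass
class DualUseRiskResults:
    """Fitted-pipeline results: tables, scores, benchmark, diagnostics."""

    model: DualUseRiskModel
    classifier: ResNetClassifier
    splits: SplitIndices
    balanced_splits: SplitIndices
    baseline: list[BaselineRow]
    outcomes: dict
    metrics: list[MetricsReport]
    impacts: list[ScoreResult]
    interactions: list[ScoreResult]
    lr_fit: LogisticFit
    impact_lr_correlation: float | None
    seeds: dict[str, int]

    @property
    def test_auc(self) -> float | None:
        return self.metrics[-1].auc

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_dict() for m in self.metrics])

    def report(self) -> dict:
        """The full serialisable report bundle."""
        cfg = self.model.config
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "software_version": __version__,
            "seed": cfg.seed,
            "stage_seeds": self.seeds,
            "n": len(self.model.cohort),
            "outcome_summary": self.outcomes,
            "baseline": baseline_frame(self.baseline).to_dict(orient="records"),
            "metrics": [m.to_dict() for m in self.metrics],
            "impact_scores": scores_frame(self.impacts).to_dict(orient="records"),
            "interaction_scores": scores_frame(self.interactions).to_dict(
                orient="records"
            ),
            "logistic_benchmark": {
                "intercept": self.lr_fit.intercept,
                "coefficients": self.lr_fit.coefficients,
                "odds_ratios": {
                    k: {"or": v[0], "low": v[1], "high": v[2]}
                    for k, v in self.lr_fit.or_ci.items()
                },
                "auc": self.lr_fit.auc,
            },
            "impact_lr_correlation": self.impact_lr_correlation,
            "anchor": cfg.anchor,
            "scale": cfg.scale,
        }

    def summary(self) -> str:
        """Aligned-text summary of every section."""
        return render_report(self.report())

    def save(self, out_dir: str | Path) -> Path:
        """Write report.json, CSV tables and figures into ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep = self.report()
        (out / "report.json").write_text(json.dumps(rep, indent=1))
        baseline_frame(self.baseline).to_csv(out / "baseline.csv", index=False)
        self.metrics_frame().to_csv(out / "metrics.csv", index=False)
        scores_frame(self.impacts).to_csv(out / "impact_scores.csv", index=False)
        scores_frame(self.interactions).to_csv(
            out / "interaction_scores.csv", index=False
        )
        if self.classifier.history is not None:
            self.classifier.history.to_csv(out / "history.csv", index=False)
        (out / "summary.txt").write_text(self.summary())
        try:
            self.plot_scores(out / "impact_scores.png", which="impacts")
            self.plot_scores(out / "interaction_scores.png", which="interactions")
        except Exception:  # plotting must never sink a run
            pass
        return out

    def plot_scores(self, path: str | Path, which: str = "impacts"):
        """Forest plot of population scores with bootstrap CIs."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        results = self.impacts if which == "impacts" else self.interactions
        if not results:
            return None
        names = [r.name for r in results][::-1]
        vals = [r.population for r in results][::-1]
        fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1.5))
        ypos = np.arange(len(names))
        ax.scatter(vals, ypos, zorder=3)
        for i, r in enumerate(results[::-1]):
            if r.ci is not None:
                ax.plot([r.ci[0], r.ci[1]], [i, i], lw=2)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(ypos, names)
        ax.set_xlabel(f"{which[:-1]} score ({results[0].scale} scale)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None):
    """Build the model from config, fit, optionally save a report bundle."""
    model = DualUseRiskModel.from_config(config)
    results = model.fit()
    if out_dir is not None:
        results.save(out_dir)
    return results


def render_report(report: dict) -> str:
    """Human-readable rendering of a report bundle; missing sections are
    listed as absent rather than fatal."""
    lines: list[str] = []
    lines.append(f"dualrisk report (schema v{report.get('schema_version', '?')}, "
                 f"n={report.get('n', '?')}, seed={report.get('seed', '?')})")
    lines.append("")
    if "outcome_summary" in report:
        osum = report["outcome_summary"]
        lines.append("== Outcome summary ==")
        for key in ("y", "y_documented", "y_coded"):
            if key in osum:
                lines.append(
                    f"  {key}: {osum[key]['count']} ({osum[key]['percent']}%)"
                )
        corr = osum.get("corroboration_percent")
        lines.append(
            "  corroboration of coded by documented: "
            + ("not available" if corr is None else f"{corr}%")
        )
    else:
        lines.append("== Outcome summary == (absent)")
    lines.append("")
    if "baseline" in report and report["baseline"]:
        lines.append("== Baseline table (ASD % — >10 flags imbalance) ==")
        lines.append(pd.DataFrame(report["baseline"]).to_string(index=False))
    else:
        lines.append("== Baseline table == (absent)")
    lines.append("")
    if "metrics" in report and report["metrics"]:
        lines.append("== Classifier metrics ==")
        lines.append(pd.DataFrame(report["metrics"]).to_string(index=False))
    else:
        lines.append("== Classifier metrics == (absent)")
    lines.append("")
    for key, title in (
        ("impact_scores", "Impact scores"),
        ("interaction_scores", "Interaction scores"),
    ):
        rows = report.get(key)
        if rows:
            lines.append(f"== {title} ==")
            lines.append(pd.DataFrame(rows).to_string(index=False))
        else:
            lines.append(f"== {title} == not computed")
        lines.append("")
    bench = report.get("logistic_benchmark")
    if bench:
        lines.append("== Logistic-regression benchmark ==")
        rows = [
            {
                "feature": k,
                "coef": round(v, 4),
                "OR": round(bench["odds_ratios"][k]["or"], 3),
                "ci_low": round(bench["odds_ratios"][k]["low"], 3),
                "ci_high": round(bench["odds_ratios"][k]["high"], 3),
            }
            for k, v in bench["coefficients"].items()
        ]
        lines.append(pd.DataFrame(rows).to_string(index=False))
        lines.append(f"  benchmark AUC: {bench.get('auc')}")
        corr = report.get("impact_lr_correlation")
        if corr is not None:
            lines.append(f"  impact-score vs coefficient Pearson r: {corr:.4f}")
    else:
        lines.append("== Logistic-regression benchmark == (absent)")
    lines.append("")
    return "\n".join(lines)
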