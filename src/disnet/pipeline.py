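"""End-to-end orchestration: features -> dataset -> train -> consensus ->
evaluate -> mine, from one configuration, with reproducible seeding.

A single master seed fans out deterministically to the scenario generator,
the cross-validation folds, the bootstrap ensemble and the stability check,
so identical configuration + seed yields identical artifacts.  Every artifact
embeds the configuration hash and seed in its header or metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import adtree, candidate_miner, consensus, evaluation
from .dataset_builder import assign_labels, greedy_feature_selection
from .graph_model import read_annotations, read_edge_list
from .synthetic_data import ScenarioConfig, generate_scenario, preset_scenarios
from .topology import FEATURE_COLUMNS, build_feature_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    scenario: str | None = None
    edges: str | None = None
    annotations: str | None = None
    k_min: int = 1
    n_iterations: int = 20
    folds: int = 10
    bootstrap_b: int = 100
    min_confidence: float = 0.5
    threshold_tolerance: float = 0.25
    seed: int = 0
    outdir: str = "disnet-run"
    run_ablation: bool = True
    run_stability: bool = False
    scenario_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _tsv_header(config: PipelineConfig) -> list[str]:
    return [f"config_hash={config.config_hash()}", f"seed={config.seed}"]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact set into the run directory."""
    outdir = Path(config.outdir)
    manifest_path = outdir / "config.json"
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != config.config_hash():
            logger.warning(
                "overwriting run directory %s produced by a different configuration",
                outdir,
            )
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed, **asdict(config)}
    manifest_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    header = _tsv_header(config)

    def stage(name):
        logger.info("stage %s", name)
        return _StageTimer(name)

    # ---- inputs -----------------------------------------------------------
    try:
        with stage("inputs"):
            ground_truth = None
            if config.scenario is not None:
                base = preset_scenarios().get(config.scenario)
                if base is None:
                    raise KeyError(f"unknown scenario {config.scenario!r}")
                scenario_config = ScenarioConfig(
                    **{**asdict(base), **config.scenario_overrides, "seed": config.seed}
                )
                scenario = generate_scenario(scenario_config)
                net, annotation = scenario.net, scenario.annotation
                ground_truth = scenario.ground_truth
            elif config.edges and config.annotations:
                net = read_edge_list(config.edges)
                annotation = read_annotations(config.annotations)
            else:
                raise ValueError("config must name a scenario or edge/annotation files")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("inputs", exc) from exc

    try:
        with stage("features"):
            features = build_feature_table(net, annotation, k_min=config.k_min)
            with open(outdir / "features.csv", "w", encoding="utf-8") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                features.to_csv(fh)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("features", exc) from exc

    try:
        with stage("dataset"):
            dataset = assign_labels(features[FEATURE_COLUMNS], annotation, config.k_min)
            selection = greedy_feature_selection(dataset)
            (outdir / "dataset_summary.json").write_text(
                json.dumps(
                    {"_metadata": meta["config_hash"], **dataset.counts(),
                     "feature_selection_order": selection},
                    indent=2,
                )
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dataset", exc) from exc

    try:
        with stage("train"):
            model = adtree.train_adtree(dataset, n_iterations=config.n_iterations)
            adtree.save_model(model, outdir / "model.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("train", exc) from exc

    try:
        with stage("consensus"):
            ensemble = consensus.bootstrap_trees(
                dataset, B=config.bootstrap_b,
                n_iterations=config.n_iterations, seed=config.seed + 2,
            )
            tree = consensus.rule_conservation(
                model, ensemble,
                threshold_tolerance=config.threshold_tolerance,
                feature_iqr=dataset.feature_iqr(),
            )
            (outdir / "consensus.json").write_text(tree.to_json())
            (outdir / "consensus.dot").write_text(tree.to_dot())
            stability = None
            if config.run_stability:
                stability = consensus.stability_check(
                    dataset, seed=config.seed + 3,
                    n_iterations=config.n_iterations,
                    B=min(config.bootstrap_b, 20),
                )
                (outdir / "stability.json").write_text(json.dumps(stability, indent=2))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("consensus", exc) from exc

    try:
        with stage("evaluate"):
            cv = evaluation.cross_validate(
                dataset, folds=config.folds,
                n_iterations=config.n_iterations, seed=config.seed + 1,
            )
            roc = evaluation.roc_curve(cv["score"], cv["label"])
            evaluation.write_roc_tsv(roc, outdir / "roc.tsv", header_lines=header)
            with open(outdir / "cv_scores.tsv", "w", encoding="utf-8") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                cv.to_csv(fh, sep="\t")
            counts = evaluation.confusion_counts(cv["score"], cv["label"])
            report = {
                "_metadata": meta["config_hash"],
                "auc": roc.auc,
                "sensitivity_at_zero": counts.tpr,
                "confusion": {"tp": counts.tp, "fp": counts.fp,
                              "tn": counts.tn, "fn": counts.fn},
            }
            ablation_table = None
            if config.run_ablation:
                ablation_table = evaluation.ablation_study(
                    dataset, folds=config.folds,
                    n_iterations=config.n_iterations, seed=config.seed + 1,
                )
                with open(outdir / "ablation.tsv", "w", encoding="utf-8") as fh:
                    for line in header:
                        fh.write(f"# {line}\n")
                    ablation_table.to_csv(fh, sep="\t", index=False)
                report["ablation_baseline_sensitivity"] = ablation_table.attrs[
                    "baseline_sensitivity"
                ]
            (outdir / "evaluation.json").write_text(json.dumps(report, indent=2))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evaluate", exc) from exc

    try:
        with stage("mine"):
            full_scores = adtree.score_frame(model, dataset.training_frame()[0])
            import pandas as pd

            X, y = dataset.training_frame()
            scores = pd.Series(full_scores, index=X.index, name="score")
            labels = pd.Series(
                ["positive" if v > 0 else "negative" for v in y], index=X.index
            )
            candidates = candidate_miner.rank_false_positives(
                scores, labels, min_confidence=config.min_confidence,
                score_mode="full-model",
            )
            with open(outdir / "candidates.tsv", "w", encoding="utf-8") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                candidates.to_csv(fh, sep="\t", index=False)
            if not candidates.empty:
                dossier = candidate_miner.candidate_dossier(
                    candidates, net, annotation, features=features
                )
            else:
                dossier = "# Candidate disease proteins\n\n(no candidates above cutoff)\n"
            (outdir / "dossier.md").write_text(dossier)
            if ground_truth is not None:
                (outdir / "ground_truth.json").write_text(
                    json.dumps(ground_truth, indent=2, sort_keys=True)
                )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("mine", exc) from exc

    logger.info("pipeline complete: %s", outdir)
    return outdir


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.start = time.perf_counter()
        return self

    def __exit__(self, *exc):
        logger.info("stage %s finished in %.2fs", self.name, time.perf_counter() - self.start)
        return False
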