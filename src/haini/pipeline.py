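"""End-to-end orchestration: simulate/load -> featurize -> select ->
balance -> train -> evaluate.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so stages are independently
reproducible and changing one stage's consumption pattern does not
perturb the others.  Every stage logs its seed and the row/column counts
it produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import balancing, classifiers, data_io, evaluation, feature_selection
from .chem_features import build_pair_feature_matrix, default_provider
from .cyp_features import build_cyp_feature_matrix
from .errors import ConfigError
from .synthetic_data import SimulationConfig, generate_ddi_dataset, generate_drug_library

logger = logging.getLogger(__name__)

STAGES = ("simulate", "split", "select", "balance", "train", "evaluate")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    output_dir: str = "haini_output"
    # data source: either simulate=dict of SimulationConfig overrides,
    # or drugs/pairs paths to existing tables
    simulate: dict | None = None
    drugs_path: str | None = None
    pairs_path: str | None = None
    mode: str = "cross_product"
    min_class_count: int = 50
    train_fraction: float = 0.70
    select_k: int = feature_selection.DEFAULT_K
    forest_trees: int = 100
    oversample_method: str = "smote"
    k_neighbors: int = 5
    algorithm: str = "xgb"
    grid: dict | None = None
    cv_folds: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None and (self.drugs_path is None or self.pairs_path is None):
            raise ConfigError(
                "config must provide either 'simulate' or both "
                "'drugs_path' and 'pairs_path'")
        if self.algorithm not in classifiers.ALGORITHMS:
            raise ConfigError(f"unknown algorithm {self.algorithm!r}")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the global seed (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] & 0x7FFFFFFF)
            for name, c in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute every stage and write artifacts under ``config.output_dir``.

    Returns a dict with the trained model, the metrics report, the
    selected feature names and the output paths.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    provider = default_provider()

    # ---- data ------------------------------------------------------------
    if config.simulate is not None:
        sim = SimulationConfig(**{"seed": seeds["simulate"], **config.simulate})
        drugs = generate_drug_library(sim)
        pairs = generate_ddi_dataset(drugs, sim, provider)
        data_io.write_drug_table(drugs, out / "drugs.csv")
        data_io.write_pair_table(pairs, out / "pairs.csv")
        logger.info("simulate: seed=%d, %d drugs, %d pairs",
                    seeds["simulate"], len(drugs), len(pairs))
    else:
        drugs = data_io.read_drug_table(config.drugs_path)
        pairs = data_io.read_pair_table(
            config.pairs_path, drug_ids={d.drug_id for d in drugs})
        logger.info("load: %d drugs, %d pairs", len(drugs), len(pairs))

    pairs = data_io.filter_low_count_classes(pairs, config.min_class_count)
    train_pairs, test_pairs = data_io.stratified_split(
        pairs, config.train_fraction, seed=seeds["split"])
    logger.info("split: seed=%d, train=%d, test=%d",
                seeds["split"], len(train_pairs), len(test_pairs))

    # ---- featurize -------------------------------------------------------
    chem_train = build_pair_feature_matrix(drugs, train_pairs, config.mode, provider)
    chem_test = build_pair_feature_matrix(drugs, test_pairs, config.mode, provider)
    cyp_train = build_cyp_feature_matrix(drugs, train_pairs)
    cyp_test = build_cyp_feature_matrix(drugs, test_pairs)
    y_train = np.array([p.label for p in train_pairs])
    y_test = np.array([p.label for p in test_pairs])
    logger.info("featurize: mode=%s, chem=%d cols, cyp=%d cols",
                config.mode, chem_train.shape[1], cyp_train.shape[1])

    # ---- select (training rows only) ------------------------------------
    rankings = [
        feature_selection.rank_by_forest_importance(
            chem_train, y_train, seed=seeds["select"],
            n_estimators=config.forest_trees),
        feature_selection.rank_by_univariate_score(chem_train, y_train),
    ]
    selected = feature_selection.consensus_select(rankings, k=config.select_k)
    feature_selection.selection_report(rankings, selected).to_csv(
        out / "selection_report.csv", index=False)
    logger.info("select: seed=%d, k=%d", seeds["select"], len(selected))

    X_train = pd.concat([chem_train[selected], cyp_train], axis=1)
    X_test = pd.concat([chem_test[selected], cyp_test], axis=1)

    # ---- balance (training rows only) ------------------------------------
    X_bal, y_bal = balancing.smote_balance(
        X_train, y_train, k_neighbors=config.k_neighbors,
        seed=seeds["balance"], method=config.oversample_method)
    logger.info("balance: seed=%d, %d -> %d rows",
                seeds["balance"], len(X_train), len(X_bal))

    # ---- train ------------------------------------------------------------
    spec = classifiers.ModelSpec(config.algorithm, grid=config.grid,
                                 cv_folds=config.cv_folds)
    model = classifiers.grid_search_cv(X_bal, y_bal, spec, seed=seeds["train"])
    logger.info("train: seed=%d, best_params=%s", seeds["train"], model.best_params)

    # ---- evaluate ----------------------------------------------------------
    y_pred = model.predict(X_test)
    scores = model.predict_scores(X_test)
    report = evaluation.evaluate(y_test, y_pred, scores, classes=model.classes)
    report.write(out / "metrics.json", out / "metrics_per_class.csv")
    _write_provenance(out, config, seeds)
    logger.info("evaluate: accuracy=%.4f macro_f1=%.4f",
                report.accuracy, report.macro_f1)

    return {
        "model": model,
        "report": report,
        "selected_features": selected,
        "train_pairs": train_pairs,
        "test_pairs": test_pairs,
        "output_dir": str(out),
    }


def _write_provenance(out: Path, config: PipelineConfig, seeds: dict) -> None:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    (out / "provenance.json").write_text(json.dumps({
        "config": asdict(config),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "stage_seeds": seeds,
    }, indent=2, default=str))
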