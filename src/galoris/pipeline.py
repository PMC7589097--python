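"""End-to-end pipeline orchestration.

Wires the stages — synthetic simulation or raw-trace feature extraction,
statistical screening, interval-threshold labeling, genetic-algorithm
selection, classifier evaluation — into one reproducible run driven by a
declarative :class:`RunConfig`.  Every run writes its intermediate tables
as comma-separated text plus a JSON manifest (config, seed, input
checksums) from which it can be reconstructed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import SUBSET_RECIPES, split_column_name
from .datasets import SyntheticSpec, generate_band_features, read_features_csv, write_features_csv
from .evaluation import evaluate_all_classifiers
from .features import BandFeatureMatrix, standardize
from .ga import GaConfig
from .labeling import label_matrix
from .model import GALoRIS
from .screening import build_search_space

__all__ = ["RunConfig", "build_subset", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    out_dir: str = "galoris_run"
    input_features: str | None = None  # CSV path; None -> simulate
    subset: str | None = None  # one of the named band-subset recipes
    bands: list[str] | None = None  # or an explicit band list
    seed: int = 0
    n_samples: int = 2000
    effect_size: float = 2.0
    informative_columns: list[str] | None = None
    screen_alpha: float = 0.05
    use_threshold_labels: bool = False
    ga: GaConfig = field(default_factory=GaConfig)
    evaluate: bool = True
    eval_folds: int = 10
    eval_grid_points: int = 4
    eval_tune: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        ga = raw.pop("ga", {})
        cfg = cls(**raw)
        if isinstance(ga, dict):
            cfg.ga = GaConfig(**{**dataclasses.asdict(cfg.ga), **ga})
        return cfg

    def band_recipe(self) -> list[str] | None:
        if self.subset is not None:
            if self.subset not in SUBSET_RECIPES:
                raise ValueError(
                    f"unknown subset {self.subset!r}; known: {sorted(SUBSET_RECIPES)}"
                )
            return list(SUBSET_RECIPES[self.subset])
        return self.bands


def build_subset(matrix: BandFeatureMatrix, recipe: list[str]) -> BandFeatureMatrix:
    """Keep only the columns whose band is in ``recipe``; band-major order
    is preserved."""
    keep = [c for c in matrix.column_names if split_column_name(c)[0] in set(recipe)]
    if not keep:
        raise ValueError(f"no columns match the band recipe {recipe}")
    return matrix.select_columns(keep)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact bundle.

    Artifacts written under ``config.out_dir``: the (standardized) feature
    table with labels, the search-space listing, the threshold sidecar
    when threshold labeling is used, the best chromosome (bitstring +
    decoded features), the structured dataset, the per-generation history,
    the classifier report, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": _config_dict(config), "inputs": {}}

    # --- acquire features -------------------------------------------------
    if config.input_features is not None:
        path = Path(config.input_features)
        if not path.exists():
            raise FileNotFoundError(f"input feature table not found: {path}")
        manifest["inputs"][str(path)] = _checksum(path)
        matrix, labels = read_features_csv(path)
        logger.info("loaded %d samples x %d features from %s", matrix.n_samples,
                    len(matrix.column_names), path)
    else:
        spec = SyntheticSpec(
            n_samples=config.n_samples,
            effect_size=config.effect_size,
            informative_columns=(
                tuple(config.informative_columns)
                if config.informative_columns is not None
                else None
            ),
            seed=config.seed,
        )
        matrix, labels, _ = generate_band_features(spec)
        logger.info("simulated %d samples x %d features", matrix.n_samples,
                    len(matrix.column_names))

    recipe = config.band_recipe()
    if recipe is not None:
        matrix = build_subset(matrix, recipe)
    matrix = standardize(matrix)

    # --- labels -----------------------------------------------------------
    if config.use_threshold_labels or labels is None:
        lv = label_matrix(matrix)
        labels = lv.labels
        sidecar = {
            "boundary": lv.boundary,
            "interval_size": lv.interval_size,
            "min_value": lv.min_value,
            "max_value": lv.max_value,
            "n_low": lv.counts[0],
            "n_high": lv.counts[1],
        }
        (out / "threshold.json").write_text(json.dumps(sidecar, indent=2))
        logger.info("threshold labeling: boundary %.4g (%d low / %d high)",
                    lv.boundary, *lv.counts)
    write_features_csv(matrix, labels, out / "features.csv")

    # --- screening --------------------------------------------------------
    space = build_search_space(matrix, labels, alpha=config.screen_alpha)
    pd.DataFrame(
        {"column": space.columns, "p_value": [space.p_values[c] for c in space.columns]}
    ).to_csv(out / "search_space.csv", index=False)
    logger.info("search space: %d of %d columns at alpha=%.3g",
                len(space), len(matrix.column_names), config.screen_alpha)

    # --- selection --------------------------------------------------------
    ga_cfg = dataclasses.replace(config.ga, seed=config.seed)
    results = GALoRIS(matrix, labels, search_space=space, config=ga_cfg).fit()
    chrom_line = "".join(map(str, results.best_chromosome.genes.tolist()))
    (out / "best_chromosome.txt").write_text(
        f"# seed={config.seed} config={dataclasses.asdict(ga_cfg)}\n"
        f"{chrom_line}\n" + ",".join(results.selected_features) + "\n"
    )
    results.history.to_csv(out / "history.csv", index=False)
    structured = results.structured_dataset
    structured_df = structured.features.copy()
    structured_df["label"] = structured.labels
    structured_df.to_csv(out / "structured_dataset.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")
    logger.info("selected %d/%d features, fit accuracy %.4f",
                results.n_features_selected, results.n_features_in, results.accuracy)

    # --- evaluation -------------------------------------------------------
    report = None
    if config.evaluate:
        report = evaluate_all_classifiers(
            structured,
            k=config.eval_folds,
            seed=config.seed,
            grid_points=config.eval_grid_points,
            tune=config.eval_tune,
        )
        report.to_csv(out / "classifier_report.csv")
        logger.info("classifier test accuracies: %s",
                    report["test_accuracy"].round(2).to_dict())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {
        "matrix": matrix,
        "labels": np.asarray(labels),
        "search_space": space,
        "results": results,
        "report": report,
        "out_dir": out,
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
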