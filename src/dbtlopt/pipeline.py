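"""End-to-end reproducible runs: configuration, seed fan-out, manifest.

A :class:`RunConfig` describes one campaign -- where the library and data
come from (a table on disk or a simulation block), which dataset kinds,
model families and training strategies to use -- and
:func:`run_pipeline` executes validate -> build datasets -> evaluate ->
train -> rank -> attribute -> suggest, writing every intermediate table
as TSV plus a JSON manifest with seeds, row counts and checksums.  Reruns
with the same config produce byte-identical tables.

Every stochastic stage derives its seed from the single master seed by
stable hashing of the stage name, so adding a stage never perturbs the
random streams of earlier stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import io as dio
from .attribution import (
    permutation_importance,
    shapley_values,
    suggest_expansion,
    summarize_shapley,
)
from .datasets import StratificationScheme, assign_strata, collapse_replicates, filter_producers
from .design_space import enumerate_designs, pal_library, validate_measurements
from .landscape import ScreenConfig, simulate_screen
from .models import DEFAULT_FAMILIES_BY_KIND, evaluate_families, fit, tune_hyperparameters
from .recommend import (
    evaluate_ranking,
    predicted_improvement,
    rank_designs,
    train_one_time,
    train_recurrent,
)
from .study import campaign_landscape

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, independent across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (round-trips through YAML)."""

    out_dir: str = "results/run"
    seed: int = 0
    library_path: str | None = None  # None -> built-in reduced PAL library
    measurements_path: str | None = None
    simulate: bool = True  # simulate a screen when no measurements given
    n_colonies: int = 225
    correct_fraction: float = 0.84
    detection_limit: float = 0.05
    n_classes: int = 4
    dataset_kinds: tuple[str, ...] = ("complete", "producers")
    strategies: tuple[str, ...] = ("one_time", "recurrent")
    families: Mapping[str, tuple[str, ...]] | None = None  # kind -> families
    n_resamples: int = 100
    n_repeats: int = 10
    test_fraction: float = 0.1
    grids: Mapping[str, Mapping[str, list]] | None = None
    run_evaluation: bool = True
    attribution_family: str = "kernel_ridge"
    shap_instances: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = {k: getattr(self, k) for k in self.__dataclass_fields__}
        doc["dataset_kinds"] = list(self.dataset_kinds)
        doc["strategies"] = list(self.strategies)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full DBTL analysis described by ``config``.

    Returns (and writes) the run manifest.  Fails fast with a
    stage-tagged :class:`PipelineError` on the first stage error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "counts": {},
    }

    # -- library ----------------------------------------------------------
    stage = "library"
    try:
        if config.library_path:
            library = dio.load_library(config.library_path)
        else:
            library = pal_library(reduced=True)
        dio.save_library(library, out / "library.yaml")
        manifest["counts"]["design_space"] = library.size
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- measurements -----------------------------------------------------
    stage = "measurements"
    try:
        if config.measurements_path:
            table = dio.read_measurements(config.measurements_path, library)
        elif config.simulate:
            seed = stage_seed(config.seed, "landscape")
            landscape = campaign_landscape(seed, library)
            dio.save_landscape(landscape, out / "landscape.yaml")
            table = simulate_screen(
                landscape,
                library,
                ScreenConfig(
                    n_colonies=config.n_colonies,
                    correct_fraction=config.correct_fraction,
                    detection_limit=config.detection_limit,
                    seed=stage_seed(config.seed, "screen"),
                ),
            )
        else:
            raise ValueError("no measurements path and simulate=False")
        dio.write_measurements(table, out / "measurements.tsv")
        report = validate_measurements(table, library)
        manifest["counts"]["colonies"] = report.n_rows
        manifest["counts"]["valid_colonies"] = report.n_valid
        manifest["counts"]["unique_designs"] = report.n_unique_designs
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- datasets ---------------------------------------------------------
    stage = "datasets"
    try:
        scheme = StratificationScheme(config.n_classes)
        complete = assign_strata(
            collapse_replicates(table, library, config.detection_limit), scheme
        )
        datasets = {"complete": complete}
        if "producers" in config.dataset_kinds:
            datasets["producers"] = assign_strata(
                filter_producers(complete), scheme
            )
        for kind, ds in datasets.items():
            dio.write_dataset(ds, out / f"dataset_{kind}.tsv")
            manifest["counts"][f"designs_{kind}"] = len(ds)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    families_by_kind = {
        kind: tuple((config.families or DEFAULT_FAMILIES_BY_KIND)[kind])
        for kind in config.dataset_kinds
    }

    # -- evaluation -------------------------------------------------------
    if config.run_evaluation:
        stage = "evaluate"
        try:
            for kind in config.dataset_kinds:
                report = evaluate_families(
                    datasets[kind],
                    families=families_by_kind[kind],
                    n_repeats=config.n_repeats,
                    test_fraction=config.test_fraction,
                    seed=stage_seed(config.seed, f"evaluate:{kind}"),
                    grids=config.grids,
                )
                dio.write_table(report.frame, out / f"evaluation_{kind}.tsv")
                dio.write_table(
                    report.summary(), out / f"evaluation_{kind}_summary.tsv"
                )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # -- train + rank -----------------------------------------------------
    stage = "rank"
    rankings = {}
    try:
        space = enumerate_designs(library)
        for kind in config.dataset_kinds:
            for strategy in config.strategies:
                seed = stage_seed(config.seed, f"train:{kind}:{strategy}")
                if strategy == "one_time":
                    preds = train_one_time(
                        datasets[kind],
                        families=families_by_kind[kind],
                        seed=seed,
                        grids=config.grids,
                        space=space,
                    )
                else:
                    preds = train_recurrent(
                        datasets[kind],
                        families=families_by_kind[kind],
                        n_resamples=config.n_resamples,
                        seed=seed,
                        grids=config.grids,
                        space=space,
                    )
                ranking = rank_designs(preds)
                rankings[ranking.label] = (ranking, preds)
                dio.write_ranking(ranking, out / f"ranking_{ranking.label}.tsv")
                rep = evaluate_ranking(ranking, datasets[kind])
                imp = predicted_improvement(ranking, preds, datasets[kind])
                dio.write_table(imp, out / f"improvement_{ranking.label}.tsv")
                manifest["stages"].setdefault("rank", {})[ranking.label] = {
                    "bmp_rank": rep.bmp_rank,
                    "bmp_in_top10": rep.bmp_in_top10,
                    "nonproducer_median_rank": rep.nonproducer_median_rank,
                }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- attribution ------------------------------------------------------
    stage = "attribution"
    try:
        ds = datasets[config.dataset_kinds[0]]
        seed = stage_seed(config.seed, "attribution")
        spec = tune_hyperparameters(
            config.attribution_family, ds, library,
            grid=(config.grids or {}).get(config.attribution_family),
            seed=seed,
        )
        fitted = fit(spec, ds, library, seed=seed)
        imp = permutation_importance(fitted, ds, library, seed=seed)
        dio.write_table(imp.frame, out / "permutation_importance.tsv")
        order = list(
            ds.frame.sort_values("mean_titer", ascending=False).index
        )[: config.shap_instances]
        designs = ds.designs
        shap_results = [
            shapley_values(fitted, designs[i], ds, library) for i in order
        ]
        shap_summary = summarize_shapley(shap_results)
        dio.write_table(shap_summary, out / "shapley_summary.tsv")
        suggestion = suggest_expansion(imp, shap_summary, library)
        dio.write_table(suggestion.frame, out / "expansion_suggestions.tsv")
        (out / "expansion_suggestions.txt").write_text(suggestion.text + "\n")
        manifest["stages"]["attribution"] = {
            "most_important_factor": imp.order()[0],
            "expand_upward": suggestion.expand_upward,
        }
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- manifest ---------------------------------------------------------
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
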