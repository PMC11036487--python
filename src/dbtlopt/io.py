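"""Plain-text serialization: library specs and landscapes as YAML,
measurement tables / datasets / rankings as TSV.

All tables are tab-separated UTF-8 with a header row, ``.`` as the decimal
point and Unix newlines on write; both newline conventions parse.  Reads
are strict: an unknown column is an error naming that column, so schema
drift fails loudly instead of silently dropping data.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .datasets import DesignDataset
from .design_space import Factor, Level, LibrarySpec
from .landscape import LandscapeModel
from .recommend import Ranking

__all__ = [
    "SchemaError",
    "load_library",
    "save_library",
    "save_landscape",
    "load_landscape",
    "read_measurements",
    "write_measurements",
    "read_dataset",
    "write_dataset",
    "write_ranking",
    "write_table",
]

SEP = "\t"


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# -- library ---------------------------------------------------------------

def save_library(library: LibrarySpec, path: str | Path) -> None:
    doc = {
        "name": library.name,
        "factors": [
            {
                "id": f.id,
                "position": f.position,
                "levels": [
                    {
                        "id": lv.id,
                        "promoter": lv.promoter,
                        "orf": lv.orf,
                        "strength": lv.strength,
                    }
                    for lv in f.levels
                ],
            }
            for f in library.ordered_factors
        ],
        "excluded": sorted([list(pair) for pair in library.excluded]),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_library(path: str | Path) -> LibrarySpec:
    doc = yaml.safe_load(Path(path).read_text())
    factors = tuple(
        Factor(
            id=f["id"],
            position=int(f["position"]),
            levels=tuple(
                Level(
                    id=lv["id"],
                    promoter=lv.get("promoter", ""),
                    orf=lv.get("orf", ""),
                    strength=lv.get("strength", "unknown"),
                )
                for lv in f["levels"]
            ),
        )
        for f in doc["factors"]
    )
    excluded = frozenset(tuple(pair) for pair in doc.get("excluded", []))
    return LibrarySpec(doc["name"], factors, excluded)


# -- landscape -------------------------------------------------------------

def save_landscape(model: LandscapeModel, path: str | Path) -> None:
    doc = {
        "library": model.library.name,
        "baseline": float(model.baseline),
        "noise_sd": float(model.noise_sd),
        "additive_effects": [
            [fid, lid, float(v)]
            for (fid, lid), v in sorted(model.additive_effects.items())
        ],
        "interactions": [
            [list(a), list(b), float(v)]
            for (a, b), v in sorted(model.interactions.items())
        ],
        "nonproducer_levels": sorted(
            [list(p) for p in model.nonproducer_levels]
        ),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_landscape(path: str | Path, library: LibrarySpec) -> LandscapeModel:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("library") != library.name:
        raise SchemaError(
            f"landscape was sampled for library {doc.get('library')!r}, "
            f"not {library.name!r}"
        )
    return LandscapeModel(
        library=library,
        baseline=float(doc["baseline"]),
        additive_effects={
            (fid, lid): float(v) for fid, lid, v in doc["additive_effects"]
        },
        interactions={
            (tuple(a), tuple(b)): float(v) for a, b, v in doc["interactions"]
        },
        noise_sd=float(doc.get("noise_sd", 0.0)),
        nonproducer_levels=frozenset(
            tuple(p) for p in doc.get("nonproducer_levels", [])
        ),
    )


# -- tables ----------------------------------------------------------------

def _check_columns(
    frame: pd.DataFrame, required: list[str], optional: list[str], what: str
) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s) {missing}")
    allowed = set(required) | set(optional)
    unknown = [c for c in frame.columns if c not in allowed]
    if unknown:
        raise SchemaError(f"{what} has unknown column(s) {unknown}")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep=SEP, index=False, lineterminator="\n")


def read_measurements(path: str | Path, library: LibrarySpec) -> pd.DataFrame:
    """Colony-level table: factor columns + titer (+ colony_id and
    simulation ground-truth columns)."""
    frame = pd.read_csv(path, sep=SEP, dtype={f: str for f in library.factor_ids})
    _check_columns(
        frame,
        required=library.factor_ids + ["titer"],
        optional=["colony_id", "truth_correct", "truth_titer"],
        what="measurement table",
    )
    return frame


def write_measurements(frame: pd.DataFrame, path: str | Path) -> None:
    write_table(frame, path)


def write_dataset(ds: DesignDataset, path: str | Path) -> None:
    """Dataset TSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    header = (
        f"# kind: {ds.kind}\n"
        f"# detection_limit: {ds.detection_limit}\n"
        f"# library: {ds.library.name}\n"
        f"# source: {ds.source}\n"
    )
    body = ds.frame.to_csv(sep=SEP, index=False, lineterminator="\n")
    path.write_text(header + body)


def read_dataset(path: str | Path, library: LibrarySpec) -> DesignDataset:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    if meta.get("library", library.name) != library.name:
        raise SchemaError(
            f"dataset belongs to library {meta.get('library')!r}, "
            f"not {library.name!r}"
        )
    frame = pd.read_csv(
        path, sep=SEP, comment="#", dtype={f: str for f in library.factor_ids}
    )
    _check_columns(
        frame,
        required=library.factor_ids + ["mean_titer", "n_replicates", "producer"],
        optional=["stratum"],
        what="design dataset",
    )
    return DesignDataset(
        frame=frame,
        library=library,
        kind=meta.get("kind", "complete"),
        detection_limit=float(meta.get("detection_limit", 0.05)),
        source=meta.get("source", ""),
    )


def write_ranking(ranking: Ranking, path: str | Path) -> None:
    frame = ranking.frame.copy()
    frame.insert(0, "label", ranking.label)
    write_table(frame, path)
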