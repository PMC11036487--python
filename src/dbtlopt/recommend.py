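"""Ensemble prediction of the full design space and top-N frequency ranking.

Two training strategies feed the ranking: *one-time* training fits each
selected family once on all available data (no uncertainty), while
*recurrent* training refits each family on 100 stratified 90% resamples,
yielding per-design prediction spread.  Every (model, resample) prediction
vector nominates its top-1, top-5 and top-10 designs over the whole
enumerated space; a design's score is how frequently it is nominated,
averaged within each family first and then across families, so that
families with different resample counts contribute equally.

Crossing the two datasets (complete / producers) with the two strategies
gives the four canonical rankings CO, CR, PO and PR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DesignDataset, subsample_training
from .design_space import Design, LibrarySpec, encode_designs, enumerate_designs
from .models import (
    DEFAULT_FAMILIES_BY_KIND,
    ModelSpec,
    fit,
    tune_hyperparameters,
)

__all__ = [
    "EnsemblePredictions",
    "Ranking",
    "train_one_time",
    "train_recurrent",
    "rank_designs",
    "evaluate_ranking",
    "predicted_improvement",
    "RankReport",
]

log = logging.getLogger(__name__)

TOP_NS = (1, 5, 10)


@dataclass
class EnsemblePredictions:
    """Full-space predictions from one training strategy.

    ``predictions[family]`` has shape ``(n_resamples, n_designs)``; the
    one-time strategy stores a single row per family.
    """

    strategy: str
    dataset_kind: str
    designs: list[Design]
    predictions: dict[str, np.ndarray]
    tuned: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strategy not in ("one_time", "recurrent"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        n = len(self.designs)
        for fam, mat in self.predictions.items():
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            if mat.shape[1] != n:
                raise ValueError(
                    f"{fam} predictions do not cover the design space"
                )
            self.predictions[fam] = mat

    @property
    def label(self) -> str:
        return {"complete": "C", "producers": "P"}[self.dataset_kind] + {
            "one_time": "O",
            "recurrent": "R",
        }[self.strategy]

    @property
    def families(self) -> list[str]:
        return list(self.predictions)

    def ensemble_mean(self) -> np.ndarray:
        """Per-design mean prediction: within-family mean, then across
        families."""
        fam_means = [mat.mean(axis=0) for mat in self.predictions.values()]
        return np.mean(fam_means, axis=0)

    def ensemble_sd(self) -> np.ndarray:
        """Per-design spread across resamples, pooled over families
        (zero for one-time training)."""
        stacked = np.vstack([mat for mat in self.predictions.values()])
        if stacked.shape[0] < 2:
            return np.zeros(stacked.shape[1])
        return stacked.std(axis=0, ddof=0)


def _default_families(ds: DesignDataset, families) -> list[str]:
    if families is None:
        return list(DEFAULT_FAMILIES_BY_KIND[ds.kind])
    return list(families)


def _tune_all(
    ds: DesignDataset,
    families: Sequence[str],
    grids: Mapping | None,
    seed: int,
) -> dict[str, ModelSpec]:
    grids = grids or {}
    tuned = {}
    for fam in families:
        tuned[fam] = tune_hyperparameters(
            fam, ds, ds.library, grid=grids.get(fam), seed=seed
        )
    return tuned


def train_one_time(
    ds: DesignDataset,
    families: Sequence[str] | None = None,
    seed: int = 0,
    grids: Mapping | None = None,
    space: Sequence[Design] | None = None,
) -> EnsemblePredictions:
    """Tune and fit each family once on all rows; predict the whole space.

    A family whose fit fails is dropped with a warning so the remaining
    models still produce a ranking.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    families = _default_families(ds, families)
    library = ds.library
    space = list(space) if space is not None else enumerate_designs(library)
    X_space, _ = encode_designs(space, library)
    preds: dict[str, np.ndarray] = {}
    tuned_params: dict[str, dict] = {}
    for fam in families:
        try:
            spec = _tune_all(ds, [fam], grids, seed)[fam]
            fitted = fit(spec, ds, library, seed=seed)
        except Exception as exc:  # robustness to a failing family
            log.warning("dropping family %s: %s", fam, exc)
            continue
        preds[fam] = fitted.predict(X_space)[None, :]
        tuned_params[fam] = dict(fitted.hyperparameters)
    if not preds:
        raise RuntimeError("every model family failed to fit")
    return EnsemblePredictions(
        strategy="one_time",
        dataset_kind=ds.kind,
        designs=space,
        predictions=preds,
        tuned=tuned_params,
    )


def train_recurrent(
    ds: DesignDataset,
    families: Sequence[str] | None = None,
    n_resamples: int = 100,
    keep_fraction: float = 0.9,
    seed: int = 0,
    grids: Mapping | None = None,
    retune_per_resample: bool = False,
    space: Sequence[Design] | None = None,
) -> EnsemblePredictions:
    """Refit each family on stratified ``keep_fraction`` resamples.

    By default hyperparameters are tuned once per family on the full
    dataset and reused across resamples; ``retune_per_resample=True``
    repeats the LOOCV tune inside every resample instead.
    """
    if not 0.0 < keep_fraction < 1.0:
        raise ValueError("keep_fraction must be in (0, 1)")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    families = _default_families(ds, families)
    library = ds.library
    space = list(space) if space is not None else enumerate_designs(library)
    X_space, _ = encode_designs(space, library)
    tuned = {} if retune_per_resample else _tune_all(ds, families, grids, seed)
    resample_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=n_resamples
    )
    preds: dict[str, list[np.ndarray]] = {fam: [] for fam in families}
    tuned_params: dict[str, dict] = {}
    for r_seed in resample_seeds:
        sub = subsample_training(
            ds, keep_fraction, stratified=True, seed=int(r_seed)
        )
        for fam in families:
            try:
                if retune_per_resample:
                    spec = _tune_all(sub, [fam], grids, int(r_seed))[fam]
                else:
                    spec = tuned[fam]
                fitted = fit(spec, sub, library, seed=int(r_seed))
            except Exception as exc:
                log.warning("dropping family %s resample: %s", fam, exc)
                continue
            preds[fam].append(fitted.predict(X_space))
            tuned_params.setdefault(fam, dict(fitted.hyperparameters))
    kept = {fam: np.vstack(rows) for fam, rows in preds.items() if rows}
    if not kept:
        raise RuntimeError("every model family failed to fit")
    return EnsemblePredictions(
        strategy="recurrent",
        dataset_kind=ds.kind,
        designs=space,
        predictions=kept,
        tuned=tuned_params,
    )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def topk_membership(values: np.ndarray, k: int) -> np.ndarray:
    """Boolean top-k membership of one prediction vector; exact ties are
    resolved by stable order on the enumeration index."""
    order = np.argsort(-values, kind="stable")
    mask = np.zeros(len(values), dtype=bool)
    mask[order[:k]] = True
    return mask


@dataclass
class Ranking:
    """Design-space order by top-N nomination frequency.

    ``frame`` columns: ``rank`` (1-based), ``design_index`` (enumeration
    order), ``design``, ``freq_top1/5/10``, ``mean_pred``, ``sd_pred``.
    The order is lexicographic on (freq_top1, freq_top5, freq_top10), with
    the ensemble mean prediction breaking frequency ties and the
    enumeration index as the final deterministic tie-break.
    """

    frame: pd.DataFrame
    label: str
    strategy: str
    dataset_kind: str
    designs: list[Design] = field(repr=False)

    def position_of(self, design: Design) -> int:
        """1-based rank of a design; raises KeyError if outside the space."""
        key = str(design)
        match = self.frame.loc[self.frame["design"] == key, "rank"]
        if match.empty:
            raise KeyError(f"design {key} not in ranked space")
        return int(match.iloc[0])

    def top(self, n: int) -> list[Design]:
        idx = self.frame.sort_values("rank")["design_index"].to_numpy()[:n]
        return [self.designs[i] for i in idx]


def rank_designs(preds: EnsemblePredictions, top_ns: Sequence[int] = TOP_NS) -> Ranking:
    """Rank every design by its top-N nomination frequencies.

    Frequencies are averaged within each family over its resamples, then
    across families, so each family carries equal weight regardless of how
    many fits it contributed.
    """
    n = len(preds.designs)
    freqs = {k: np.zeros(n) for k in top_ns}
    for fam, mat in preds.predictions.items():
        fam_counts = {k: np.zeros(n) for k in top_ns}
        for row in mat:
            for k in top_ns:
                fam_counts[k] += topk_membership(row, k)
        for k in top_ns:
            freqs[k] += fam_counts[k] / mat.shape[0]
    n_fam = len(preds.predictions)
    for k in top_ns:
        freqs[k] /= n_fam
    mean_pred = preds.ensemble_mean()
    sd_pred = preds.ensemble_sd()
    idx = np.arange(n)
    # np.lexsort: last key is primary
    order = np.lexsort(
        (idx, -mean_pred) + tuple(-freqs[k] for k in reversed(top_ns))
    )
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "design_index": order,
            "design": [str(preds.designs[i]) for i in order],
            **{f"freq_top{k}": freqs[k][order] for k in top_ns},
            "mean_pred": mean_pred[order],
            "sd_pred": sd_pred[order],
        }
    )
    return Ranking(
        frame=frame,
        label=preds.label,
        strategy=preds.strategy,
        dataset_kind=preds.dataset_kind,
        designs=list(preds.designs),
    )


@dataclass
class RankReport:
    """Where the measured best/worst designs land in a ranking."""

    label: str
    space_size: int
    bmp_rank: int
    bmp_in_top10: bool
    five_bmp_ranks: list[int]
    nonproducer_ranks: list[int]

    @property
    def nonproducer_median_rank(self) -> float:
        return float(np.median(self.nonproducer_ranks)) if self.nonproducer_ranks else float("nan")

    @property
    def nonproducer_max_rank(self) -> int | None:
        return max(self.nonproducer_ranks) if self.nonproducer_ranks else None


def evaluate_ranking(ranking: Ranking, ds: DesignDataset) -> RankReport:
    """Score a ranking against measured data: position of the best
    measured producer (BMP), of the five best producers, and the rank
    distribution of measured nonproducers."""
    order = np.argsort(-ds.titers, kind="stable")
    designs = ds.designs
    bmp = designs[order[0]]
    bmp_rank = ranking.position_of(bmp)  # KeyError if BMP not in space
    five = [ranking.position_of(designs[i]) for i in order[:5]]
    nonprod = [
        ranking.position_of(designs[i])
        for i in range(len(ds))
        if not bool(ds.frame["producer"].iloc[i])
    ]
    return RankReport(
        label=ranking.label,
        space_size=len(ranking.designs),
        bmp_rank=bmp_rank,
        bmp_in_top10=bmp_rank <= 10,
        five_bmp_ranks=five,
        nonproducer_ranks=nonprod,
    )


def predicted_improvement(
    ranking: Ranking,
    preds: EnsemblePredictions,
    ds: DesignDataset,
    top_n: int = 10,
    reference: str = "predicted",
) -> pd.DataFrame:
    """Relative predicted production gain of the top-ranked designs over
    the best measured producer (BMP), in percent.

    ``reference="predicted"`` compares against the ensemble's own
    prediction for the BMP design (the like-for-like like-for-like
    comparison); ``"measured"`` uses the BMP's measured mean titer.  For
    the recurrent strategy each (family, resample) vector contributes its
    own improvement, so the sd column reflects resample spread.
    """
    bmp = ds.designs[ds.best_design_index()]
    bmp_idx = None
    for i, d in enumerate(preds.designs):
        if d == bmp:
            bmp_idx = i
            break
    if bmp_idx is None:
        raise KeyError("BMP design not in predicted space")
    top = ranking.top(top_n)
    top_idx = [preds.designs.index(d) for d in top]
    vectors = np.vstack([mat for mat in preds.predictions.values()])
    if reference == "predicted":
        ref = vectors[:, bmp_idx]
    elif reference == "measured":
        ref = np.full(vectors.shape[0], float(ds.titers[ds.best_design_index()]))
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if np.any(ref <= 0):
        raise ZeroDivisionError("BMP reference titer is zero or negative")
    rows = []
    for rank_pos, (d, j) in enumerate(zip(top, top_idx), start=1):
        rel = 100.0 * (vectors[:, j] - ref) / ref
        rows.append(
            {
                "rank": rank_pos,
                "design": str(d),
                "improvement_mean_pct": float(rel.mean()),
                "improvement_sd_pct": float(rel.std(ddof=0)),
                "is_bmp": d == bmp,
            }
        )
    return pd.DataFrame(rows)
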