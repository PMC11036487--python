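"""From colony measurements to model-ready design datasets.

The screening workflow yields several colonies per design; models are
trained on *unique designs* with replicate-averaged titers.  Two datasets
are derived: the *complete* dataset (producers and nonproducers) and the
*producers* dataset (mean titer at or above the detection limit).
Production-class strata (poor / medium / good / very good by default)
support stratified splitting and subsampling, which matters for the very
small sample sizes typical of sequenced one-pot libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .design_space import Design, LibrarySpec

__all__ = [
    "DesignDataset",
    "StratificationScheme",
    "collapse_replicates",
    "filter_producers",
    "assign_strata",
    "stratified_split",
    "random_split",
    "subsample_training",
]

DEFAULT_DETECTION_LIMIT = 0.05


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DesignDataset:
    """Unique designs with replicate-averaged titers.

    ``frame`` holds one row per design: the library's factor columns
    (level ids), ``mean_titer``, ``n_replicates``, ``producer`` and, once
    assigned, ``stratum``.
    """

    frame: pd.DataFrame
    library: LibrarySpec
    kind: str = "complete"
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("complete", "producers"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        key = self.frame[self.library.factor_ids].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("dataset contains duplicate designs")
        if (self.frame["mean_titer"] < 0).any():
            raise ValueError("negative mean titer")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def designs(self) -> list[Design]:
        fids = self.library.factor_ids
        return [
            Design(tuple((f, str(row[f])) for f in fids))
            for _, row in self.frame.iterrows()
        ]

    @property
    def titers(self) -> np.ndarray:
        return self.frame["mean_titer"].to_numpy(float)

    @property
    def strata(self) -> np.ndarray:
        if "stratum" not in self.frame.columns:
            raise ValueError("strata not assigned; call assign_strata first")
        return self.frame["stratum"].to_numpy(int)

    def take(self, positions: Sequence[int]) -> "DesignDataset":
        return replace(
            self, frame=self.frame.iloc[list(positions)].reset_index(drop=True)
        )

    def best_design_index(self) -> int:
        """Row position of the best measured producer (BMP)."""
        return int(np.argmax(self.titers))


@dataclass(frozen=True)
class StratificationScheme:
    """Quantile-based production classes (default: 4 classes)."""

    n_classes: int = 4
    boundaries: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.boundaries is not None and any(
            b >= c for b, c in zip(self.boundaries, self.boundaries[1:])
        ):
            raise ValueError("boundaries must be strictly increasing")


def collapse_replicates(
    table: pd.DataFrame,
    library: LibrarySpec,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
    source: str = "",
) -> DesignDataset:
    """Average replicate colonies into one row per unique design.

    Only correct rows are used when a ``truth_correct`` column is present
    (simulated screens); real tables are expected to be pre-validated.
    """
    if len(table) == 0:
        raise ValueError("empty measurement table")
    if "truth_correct" in table.columns:
        table = table.loc[table["truth_correct"].astype(bool)]
    if len(table) == 0:
        raise ValueError("no correct rows in measurement table")
    fids = library.factor_ids
    grouped = (
        table.groupby(fids, sort=False)["titer"]
        .agg(mean_titer="mean", n_replicates="size")
        .reset_index()
    )
    grouped["producer"] = grouped["mean_titer"] >= detection_limit
    return DesignDataset(
        frame=grouped,
        library=library,
        kind="complete",
        detection_limit=detection_limit,
        source=source,
    )


def filter_producers(
    ds: DesignDataset, detection_limit: float | None = None
) -> DesignDataset:
    """Keep designs whose mean titer is at or above the detection limit.

    The threshold is inclusive: a design exactly at the limit counts as a
    producer (nonproducers are those strictly *below* the limit).
    """
    if ds.kind != "complete":
        raise ValueError("filter_producers expects a complete dataset")
    limit = ds.detection_limit if detection_limit is None else detection_limit
    frame = ds.frame.loc[ds.frame["mean_titer"] >= limit].reset_index(drop=True)
    if "stratum" in frame.columns:
        frame = frame.drop(columns="stratum")
    return replace(ds, frame=frame, kind="producers", detection_limit=limit)


def assign_strata(
    ds: DesignDataset, scheme: StratificationScheme = StratificationScheme()
) -> DesignDataset:
    """Label each design with a production-class stratum.

    For a complete dataset, nonproducers form class 0 and producers are
    split into ``n_classes - 1`` quantile bins; a producers dataset is
    split into ``n_classes`` quantile bins.  Deterministic given the data.
    """
    if len(ds) == 0:
        raise ValueError("cannot stratify an empty dataset")
    titers = ds.titers
    n = scheme.n_classes
    labels = np.zeros(len(ds), dtype=int)
    if n == 1:
        pass
    elif scheme.boundaries is not None:
        labels = np.searchsorted(np.asarray(scheme.boundaries), titers, "right")
    elif ds.kind == "complete":
        producer = ds.frame["producer"].to_numpy(bool)
        sub = titers[producer]
        if len(sub):
            labels[producer] = 1 + _quantile_bins(sub, n - 1)
    else:
        labels = _quantile_bins(titers, n)
    frame = ds.frame.copy()
    frame["stratum"] = labels
    return replace(ds, frame=frame)


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin labels in [0, n_bins); ties share a bin."""
    if n_bins == 1:
        return np.zeros(len(values), dtype=int)
    if np.ptp(values) == 0:
        raise ValueError(
            "all titers identical: quantile strata are degenerate"
        )
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, values, side="right").astype(int)


def _per_stratum_counts(
    sizes: dict[int, int], fraction: float, total: int
) -> dict[int, int]:
    """Round-half-up per stratum, then trim/extend from the largest strata
    so the counts sum to ``total``; never exceeds a stratum's size."""
    counts = {
        s: min(_round_half_up(fraction * n), n) for s, n in sizes.items()
    }
    order = sorted(sizes, key=lambda s: (-sizes[s], s))
    k = 0
    while sum(counts.values()) > total:
        s = order[k % len(order)]
        if counts[s] > 0:
            counts[s] -= 1
        k += 1
    k = 0
    while sum(counts.values()) < total:
        s = order[k % len(order)]
        if counts[s] < sizes[s]:
            counts[s] += 1
        k += 1
    return counts


def stratified_split(
    ds: DesignDataset, test_fraction: float = 0.1, seed: int = 0
) -> tuple[DesignDataset, DesignDataset]:
    """Stratified train/test partition (default 90/10).

    Per-stratum proportional allocation with round-half-up; singleton
    strata go wholly to train.  Train and test are disjoint and jointly
    cover the dataset; deterministic given ``seed``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    strata = ds.strata
    rng = np.random.default_rng(seed)
    uniq, counts = np.unique(strata, return_counts=True)
    sizes = {int(s): int(c) for s, c in zip(uniq, counts)}
    splittable = {s: n for s, n in sizes.items() if n >= 2}
    n_split = sum(splittable.values())
    total_test = max(1, _round_half_up(test_fraction * n_split))
    total_test = min(total_test, n_split - len(splittable))
    alloc = _per_stratum_counts(splittable, test_fraction, total_test)
    alloc = {s: min(k, splittable[s] - 1) for s, k in alloc.items()}
    test_idx: list[int] = []
    for s in sorted(sizes):
        members = np.flatnonzero(strata == s)
        n_test = alloc.get(s, 0)
        if n_test:
            chosen = rng.choice(members, size=n_test, replace=False)
            test_idx.extend(int(i) for i in chosen)
    test_mask = np.zeros(len(ds), dtype=bool)
    test_mask[test_idx] = True
    return ds.take(np.flatnonzero(~test_mask)), ds.take(sorted(test_idx))


def random_split(
    ds: DesignDataset, test_fraction: float = 0.1, seed: int = 0
) -> tuple[DesignDataset, DesignDataset]:
    """Uniform train/test partition ignoring strata (the no-stratification
    arm of protocol comparisons); same rounding as the stratified split."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(ds)
    n_test = min(max(1, _round_half_up(test_fraction * n)), n - 1)
    rng = np.random.default_rng(seed)
    test_idx = sorted(int(i) for i in rng.choice(n, size=n_test, replace=False))
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    return ds.take(np.flatnonzero(mask)), ds.take(test_idx)


def subsample_training(
    train: DesignDataset,
    fraction: float,
    stratified: bool = True,
    seed: int = 0,
) -> DesignDataset:
    """Reduce a training set to ``fraction`` of its rows.

    With ``stratified=True`` class proportions are preserved (round-half-up
    per stratum, adjusted from the largest strata to hit the global
    count); otherwise rows are sampled uniformly.  Deterministic given
    ``seed``; ``fraction=1.0`` is the identity.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = len(train)
    if fraction == 1.0:
        return train
    total = _round_half_up(fraction * n)
    if total < 2:
        raise ValueError(
            f"fraction {fraction} of {n} rows yields fewer than 2 rows"
        )
    rng = np.random.default_rng(seed)
    if not stratified:
        keep = sorted(int(i) for i in rng.choice(n, size=total, replace=False))
        return train.take(keep)
    strata = train.strata
    uniq, counts = np.unique(strata, return_counts=True)
    sizes = {int(s): int(c) for s, c in zip(uniq, counts)}
    alloc = _per_stratum_counts(sizes, fraction, total)
    keep = []
    for s in sorted(sizes):
        members = np.flatnonzero(strata == s)
        k = alloc.get(s, 0)
        if k:
            keep.extend(int(i) for i in rng.choice(members, size=k, replace=False))
    return train.take(sorted(keep))
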