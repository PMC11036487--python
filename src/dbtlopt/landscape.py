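"""Synthetic genotype->titer landscapes and one-pot screening simulation.

A :class:`LandscapeModel` is a ground-truth map from designs to production
titers (arbitrary units): a baseline plus additive per-level effects plus
pairwise level-level interaction terms, clipped at zero.  Designated
"nonproducer levels" force a zero titer, emulating levels that break the
pathway.  :func:`simulate_screen` then emulates the one-pot library
workflow: colonies carry designs drawn uniformly with replacement
(duplicates expected), a fraction of colonies are incorrectly assembled,
and measured titers add replicate noise above a detection floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design_space import Design, LibrarySpec, validate_design

__all__ = [
    "LandscapeModel",
    "ScreenConfig",
    "sample_landscape",
    "true_titer",
    "true_titers",
    "simulate_screen",
    "screening_summary",
]

PairKey = tuple[tuple[str, str], tuple[str, str]]


def _pair_key(a: tuple[str, str], b: tuple[str, str]) -> PairKey:
    """Canonical unordered key for an interaction between two factor levels."""
    if a[0] == b[0]:
        raise ValueError("interaction terms must couple two distinct factors")
    return (a, b) if a[0] < b[0] else (b, a)


@dataclass(frozen=True)
class LandscapeModel:
    """Ground-truth additive + pairwise-interaction production landscape."""

    library: LibrarySpec
    baseline: float
    additive_effects: Mapping[tuple[str, str], float]
    interactions: Mapping[PairKey, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    nonproducer_levels: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(
            self, "additive_effects", dict(self.additive_effects)
        )
        canon = {}
        for (a, b), val in dict(self.interactions).items():
            canon[_pair_key(tuple(a), tuple(b))] = val
        object.__setattr__(self, "interactions", canon)
        object.__setattr__(
            self, "nonproducer_levels", frozenset(self.nonproducer_levels)
        )


def true_titer(model: LandscapeModel, design: Design) -> float:
    """Noiseless titer of one design: baseline + additive + interactions,
    clipped at 0; exactly 0 if any nonproducer level is present."""
    pairs = design.assignment
    if any(p in model.nonproducer_levels for p in pairs):
        return 0.0
    t = model.baseline
    for p in pairs:
        t += model.additive_effects.get(p, 0.0)
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            t += model.interactions.get(_pair_key(pairs[i], pairs[j]), 0.0)
    return max(t, 0.0)


def true_titers(model: LandscapeModel, designs: Sequence[Design]) -> np.ndarray:
    return np.array([true_titer(model, d) for d in designs])


def sample_landscape(
    library: LibrarySpec,
    *,
    baseline: float = 0.09,
    effect_range: tuple[float, float] = (-0.05, 0.05),
    effect_scale: Mapping[str, float] | None = None,
    interaction_density: float = 0.05,
    interaction_range: tuple[float, float] = (-0.02, 0.02),
    noise_sd: float = 0.01,
    nonproducer_levels: Iterable[tuple[str, str]] = (),
    favor_strength: Mapping[str, str] | None = None,
    center_effects: bool = True,
    seed: int = 0,
) -> LandscapeModel:
    """Draw a random landscape over ``library``; deterministic given ``seed``.

    Additive per-level effects are uniform on ``effect_range``, optionally
    scaled per factor via ``effect_scale`` (factor id -> multiplier).
    With ``center_effects`` (the default) each factor's effects are shifted
    to zero mean, so ``baseline`` is the additive space-mean titer and the
    nonproducer fraction is comparable across seeds.
    ``interaction_density`` is the fraction of all cross-factor level pairs
    receiving a nonzero interaction term drawn from ``interaction_range``.
    ``favor_strength`` (factor id -> promoter strength) moves the factor's
    largest drawn effect onto its first active level of that strength, for
    constructing landscapes whose optimum sits at a known expression
    boundary.
    """
    for rng_check in (effect_range, interaction_range):
        if rng_check[0] > rng_check[1]:
            raise ValueError(f"invalid range {rng_check}")
    if not 0.0 <= interaction_density <= 1.0:
        raise ValueError("interaction_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    effects: dict[tuple[str, str], float] = {}
    for f in library.ordered_factors:
        active = library.active_levels(f.id)
        scale = 1.0 if effect_scale is None else effect_scale.get(f.id, 1.0)
        vals = rng.uniform(effect_range[0], effect_range[1], size=len(active))
        if center_effects and len(active) > 1:
            vals -= vals.mean()
        vals *= scale
        if favor_strength and f.id in favor_strength:
            want = favor_strength[f.id]
            targets = [k for k, lv in enumerate(active) if lv.strength == want]
            if not targets:
                raise ValueError(
                    f"factor {f.id!r} has no active level of strength {want!r}"
                )
            k_max = int(np.argmax(vals))
            k_tgt = targets[0]
            vals[k_max], vals[k_tgt] = vals[k_tgt], vals[k_max]
        for lv, val in zip(active, vals):
            effects[(f.id, lv.id)] = float(val)

    interactions: dict[PairKey, float] = {}
    factors = library.ordered_factors
    for i in range(len(factors)):
        for j in range(i + 1, len(factors)):
            for la in library.active_levels(factors[i].id):
                for lb in library.active_levels(factors[j].id):
                    if rng.random() < interaction_density:
                        key = _pair_key(
                            (factors[i].id, la.id), (factors[j].id, lb.id)
                        )
                        interactions[key] = float(
                            rng.uniform(*interaction_range)
                        )
    return LandscapeModel(
        library=library,
        baseline=baseline,
        additive_effects=effects,
        interactions=interactions,
        noise_sd=noise_sd,
        nonproducer_levels=frozenset(nonproducer_levels),
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of a simulated one-pot screen.

    ``correct_fraction`` is the probability that a colony carries a valid,
    complete gene cluster; ``replicate_noise_sd`` defaults to the
    landscape's own noise when ``None``.
    """

    n_colonies: int = 440
    correct_fraction: float = 0.84
    replicate_noise_sd: float | None = None
    detection_limit: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correct_fraction <= 1.0:
            raise ValueError("correct_fraction must be in [0, 1]")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")


def simulate_screen(
    model: LandscapeModel, library: LibrarySpec, screen: ScreenConfig
) -> pd.DataFrame:
    """Simulate colony screening; returns one row per colony.

    Columns: ``colony_id``, one column per factor (the colony's intended
    design), ``titer`` (measured), plus ground-truth columns
    ``truth_correct`` and ``truth_titer`` for evaluation only.  Designs are
    sampled uniformly with replacement; incorrect colonies report only
    background noise near zero.  Titers are clipped at 0.
    """
    from .design_space import enumerate_designs

    rng = np.random.default_rng(screen.seed)
    space = enumerate_designs(library)
    noise_sd = (
        model.noise_sd
        if screen.replicate_noise_sd is None
        else screen.replicate_noise_sd
    )
    idx = rng.integers(0, len(space), size=screen.n_colonies)
    correct = rng.random(screen.n_colonies) < screen.correct_fraction
    rows = []
    for c, (i, ok) in enumerate(zip(idx, correct)):
        d = space[i]
        truth = true_titer(model, d)
        if ok:
            measured = truth + rng.normal(0.0, noise_sd) if noise_sd else truth
        else:
            measured = abs(rng.normal(0.0, noise_sd)) if noise_sd else 0.0
        rows.append(
            {
                "colony_id": f"c{c:04d}",
                **d.as_dict(),
                "titer": max(float(measured), 0.0),
                "truth_correct": bool(ok),
                "truth_titer": truth,
            }
        )
    return pd.DataFrame(rows)


def screening_summary(
    table: pd.DataFrame,
    detection_limit: float = 0.05,
    correct: Sequence[bool] | None = None,
    factor_ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """Bookkeeping counts for a screen: colonies screened, correct strains,
    unique designs among correct strains, and producers (unique designs
    whose mean titer is at or above the detection limit)."""
    if correct is None:
        if "truth_correct" in table.columns:
            correct = table["truth_correct"].to_numpy(bool)
        else:
            correct = np.ones(len(table), dtype=bool)
    correct = np.asarray(correct, dtype=bool)
    if factor_ids is None:
        reserved = {"colony_id", "titer", "truth_correct", "truth_titer"}
        factor_ids = [c for c in table.columns if c not in reserved]
    ok = table.loc[correct]
    n_unique = 0
    n_producers = 0
    if len(ok):
        grouped = ok.groupby(list(factor_ids), sort=False)["titer"].mean()
        n_unique = len(grouped)
        n_producers = int((grouped >= detection_limit).sum())
    n = len(table)
    n_correct = int(correct.sum())
    return {
        "screened": n,
        "correct": n_correct,
        "unique": n_unique,
        "producers": n_producers,
        "correct_percent": round(100.0 * n_correct / n, 1) if n else float("nan"),
    }
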