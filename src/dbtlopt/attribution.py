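"""Model explanation at factor granularity, and design-space expansion advice.

Both explanation tools operate on whole factors, not on individual one-hot
columns: shuffling or toggling a single indicator column would fabricate
genotypes with zero or two active levels for a factor.  Permutation
importance therefore permutes a factor's entire level assignment across
samples and reports the drop in R^2; Shapley values treat the factors as
players in a cooperative game whose value function replaces a coalition's
levels with the instance's levels on top of a background population, and
are computed exactly by enumerating all 2^F coalitions.

The resulting per-level attribution summary drives
:func:`suggest_expansion`: a factor that matters strongly and whose most
beneficial level already sits at the boundary of tested expression (the
strongest available promoter) is a candidate for expansion beyond the
current library (stronger promoters, additional gene copies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .datasets import DesignDataset
from .design_space import (
    Design,
    LibrarySpec,
    STRENGTH_ORDER,
    encode_designs,
    encoding_columns,
)
from .models import ModelSpec

__all__ = [
    "PermutationImportance",
    "ShapleyAttribution",
    "permutation_importance",
    "shapley_values",
    "shapley_values_sampled",
    "summarize_shapley",
    "suggest_expansion",
    "ExpansionReport",
]

MAX_EXACT_FACTORS = 16


def _predictor(model) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, ModelSpec):
        if not model.fitted:
            raise ValueError("model is not fitted")
        return model.predict
    if callable(model):
        return lambda X: np.asarray(model(X), dtype=float)
    raise TypeError("model must be a fitted ModelSpec or a callable on X")


def _factor_blocks(library: LibrarySpec) -> dict[str, np.ndarray]:
    cols = encoding_columns(library)
    return {
        f.id: np.array([j for j, (fid, _) in enumerate(cols) if fid == f.id])
        for f in library.ordered_factors
    }


@dataclass
class PermutationImportance:
    """R^2 drop per factor when its level assignment is shuffled."""

    kind = "permutation_importance"
    frame: pd.DataFrame  # factor, importance_mean, importance_sd
    baseline_r2: float
    n_repeats: int

    def importance(self, factor_id: str) -> float:
        row = self.frame.loc[self.frame["factor"] == factor_id]
        if row.empty:
            raise KeyError(factor_id)
        return float(row["importance_mean"].iloc[0])

    def order(self) -> list[str]:
        """Factors from most to least important."""
        return list(
            self.frame.sort_values(
                "importance_mean", ascending=False, kind="stable"
            )["factor"]
        )


def permutation_importance(
    model,
    ds: DesignDataset,
    library: LibrarySpec | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> PermutationImportance:
    """Factor-level permutation importance on a dataset.

    For each factor the rows of its whole one-hot block are permuted
    together (i.e. the factor's level assignment is shuffled across
    samples while every other factor stays in place), and the importance
    is the decrease in R^2 relative to the unshuffled baseline, averaged
    over ``n_repeats`` permutations.  A single-level factor is constant,
    so its importance is exactly zero.
    """
    library = library or ds.library
    predict = _predictor(model)
    X, _ = encode_designs(ds.designs, library)
    y = ds.titers
    baseline = r2_score(y, predict(X))
    blocks = _factor_blocks(library)
    rng = np.random.default_rng(seed)
    rows = []
    for fid, block in blocks.items():
        if len(block) <= 1:
            rows.append(
                {"factor": fid, "importance_mean": 0.0, "importance_sd": 0.0}
            )
            continue
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            Xp = X.copy()
            Xp[:, block] = X[perm][:, block]
            drops.append(baseline - r2_score(y, predict(Xp)))
        rows.append(
            {
                "factor": fid,
                "importance_mean": float(np.mean(drops)),
                "importance_sd": float(np.std(drops, ddof=0)),
            }
        )
    return PermutationImportance(
        frame=pd.DataFrame(rows), baseline_r2=float(baseline), n_repeats=n_repeats
    )


# ---------------------------------------------------------------------------
# Shapley values
# ---------------------------------------------------------------------------

@dataclass
class ShapleyAttribution:
    """Exact per-factor Shapley attribution of one design's prediction.

    Efficiency holds by construction:
    ``sum(phi.values()) == prediction - background_value``.
    """

    kind = "shapley"
    instance: Design
    phi: dict[str, float]
    background_value: float
    prediction: float
    standard_error: dict[str, float] | None = None

    @property
    def efficiency_gap(self) -> float:
        return abs(sum(self.phi.values()) - (self.prediction - self.background_value))


def _background_designs(background, library: LibrarySpec) -> list[Design]:
    if isinstance(background, DesignDataset):
        return background.designs
    return list(background)


def _coalition_values(
    predict, instance: Design, background: list[Design], library: LibrarySpec
) -> np.ndarray:
    """v(S) for every coalition bitmask S over the library's factors."""
    fids = library.factor_ids
    F = len(fids)
    blocks = _factor_blocks(library)
    E_bg, _ = encode_designs(background, library)
    e_inst, _ = encode_designs([instance], library)
    e_inst = e_inst[0]
    v = np.empty(1 << F)
    for mask in range(1 << F):
        E = E_bg.copy()
        for k in range(F):
            if mask >> k & 1:
                E[:, blocks[fids[k]]] = e_inst[blocks[fids[k]]]
        v[mask] = float(np.mean(predict(E)))
    return v


def shapley_values(
    model,
    instance: Design,
    background,
    library: LibrarySpec | None = None,
) -> ShapleyAttribution:
    """Exact model-agnostic Shapley values over factors.

    The value of a coalition S is the mean model prediction over the
    background designs with the instance's levels substituted on the
    factors in S.  phi_f is the usual weighted sum of marginal
    contributions, ``sum_S |S|!(F-|S|-1)!/F! (v(S+f) - v(S))``, over all
    2^F coalitions, so the enumeration is limited to F <= 16 factors
    (use :func:`shapley_values_sampled` beyond that).
    """
    if library is None:
        if isinstance(background, DesignDataset):
            library = background.library
        else:
            raise ValueError("library required when background is a design list")
    fids = library.factor_ids
    F = len(fids)
    if F > MAX_EXACT_FACTORS:
        raise ValueError(
            f"{F} factors exceed the exact enumeration bound "
            f"({MAX_EXACT_FACTORS}); use shapley_values_sampled instead"
        )
    predict = _predictor(model)
    bg = _background_designs(background, library)
    v = _coalition_values(predict, instance, bg, library)
    weights = [
        factorial(s) * factorial(F - s - 1) / factorial(F) for s in range(F)
    ]
    phi = dict.fromkeys(fids, 0.0)
    for mask in range(1 << F):
        s = bin(mask).count("1")
        if s == F:
            continue
        w = weights[s]
        for k in range(F):
            if not mask >> k & 1:
                phi[fids[k]] += w * (v[mask | (1 << k)] - v[mask])
    return ShapleyAttribution(
        instance=instance,
        phi=phi,
        background_value=float(v[0]),
        prediction=float(v[(1 << F) - 1]),
    )


def shapley_values_sampled(
    model,
    instance: Design,
    background,
    library: LibrarySpec | None = None,
    n_permutations: int = 200,
    seed: int = 0,
) -> ShapleyAttribution:
    """Monte-Carlo Shapley estimate by sampling factor permutations.

    Reports a per-factor standard error of the estimate; agrees with the
    exact enumeration in expectation and is the fallback for libraries
    with more factors than the exact bound allows.
    """
    if library is None and isinstance(background, DesignDataset):
        library = background.library
    fids = library.factor_ids
    F = len(fids)
    blocks = _factor_blocks(library)
    predict = _predictor(model)
    bg = _background_designs(background, library)
    E_bg, _ = encode_designs(bg, library)
    e_inst, _ = encode_designs([instance], library)
    e_inst = e_inst[0]
    rng = np.random.default_rng(seed)
    contrib = {fid: [] for fid in fids}
    for _ in range(n_permutations):
        order = rng.permutation(F)
        E = E_bg.copy()
        prev = float(np.mean(predict(E)))
        for k in order:
            E[:, blocks[fids[k]]] = e_inst[blocks[fids[k]]]
            cur = float(np.mean(predict(E)))
            contrib[fids[k]].append(cur - prev)
            prev = cur
    phi = {fid: float(np.mean(c)) for fid, c in contrib.items()}
    se = {
        fid: float(np.std(c, ddof=1) / np.sqrt(len(c)))
        for fid, c in contrib.items()
    }
    E_full = E_bg.copy()
    for fid in fids:
        E_full[:, blocks[fid]] = e_inst[blocks[fid]]
    return ShapleyAttribution(
        instance=instance,
        phi=phi,
        background_value=float(np.mean(predict(E_bg))),
        prediction=float(np.mean(predict(E_full))),
        standard_error=se,
    )


def summarize_shapley(
    results: Sequence[ShapleyAttribution],
) -> pd.DataFrame:
    """Aggregate per-instance Shapley values to (factor, level) impact.

    For every level actually carried by at least one instance: the number
    of carrying instances, the mean / quartiles of phi among them, and the
    fraction of positive attributions.
    """
    if not results:
        raise ValueError("no Shapley results to summarize")
    records: dict[tuple[str, str], list[float]] = {}
    for res in results:
        for fid, lid in res.instance.assignment:
            records.setdefault((fid, lid), []).append(res.phi[fid])
    rows = []
    for (fid, lid), vals in sorted(records.items()):
        arr = np.asarray(vals)
        rows.append(
            {
                "factor": fid,
                "level": lid,
                "n": len(arr),
                "mean_phi": float(arr.mean()),
                "q25_phi": float(np.quantile(arr, 0.25)),
                "q75_phi": float(np.quantile(arr, 0.75)),
                "positive_fraction": float((arr > 0).mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expansion advice
# ---------------------------------------------------------------------------

@dataclass
class ExpansionReport:
    """Advisory table on where to expand the design space."""

    frame: pd.DataFrame
    text: str

    @property
    def expand_upward(self) -> list[str]:
        return list(self.frame.loc[self.frame["suggestion"] == "expand_upward", "factor"])


def suggest_expansion(
    importance: PermutationImportance,
    shap_summary: pd.DataFrame,
    library: LibrarySpec,
    rel_threshold: float = 0.5,
) -> ExpansionReport:
    """Turn attributions into expansion suggestions.

    A factor is flagged ``expand_upward`` when (a) its permutation
    importance is positive and at least ``rel_threshold`` of the largest
    importance, and (b) its most positive mean-Shapley level uses the
    strongest promoter available for that factor, i.e. the observed
    optimum sits at the boundary of tested expression.  Other
    high-importance factors are ``keep`` (their optimum is interior);
    low-importance factors are ``neutral`` for expansion purposes.
    """
    max_imp = max(
        (importance.importance(f.id) for f in library.ordered_factors),
        default=0.0,
    )
    rows = []
    lines = []
    for f in library.ordered_factors:
        imp = importance.importance(f.id)
        if "factor" in shap_summary.columns:
            sub = shap_summary.loc[shap_summary["factor"] == f.id]
        else:  # empty summary without columns
            sub = shap_summary

        best_level = ""
        best_strength = "unknown"
        at_boundary = False
        if not sub.empty:
            best = sub.loc[sub["mean_phi"].idxmax()]
            best_level = str(best["level"])
            best_strength = f.level(best_level).strength
            active = library.active_levels(f.id)
            top_rank = max(STRENGTH_ORDER[lv.strength] for lv in active)
            at_boundary = STRENGTH_ORDER[best_strength] == top_rank
        high = max_imp > 0 and imp > 0 and imp >= rel_threshold * max_imp
        if high and at_boundary:
            suggestion = "expand_upward"
            lines.append(
                f"{f.id}: high importance ({imp:.3f}) and best level "
                f"{best_level!r} already uses the strongest tested promoter; "
                "consider stronger expression or an additional gene copy."
            )
        elif high:
            suggestion = "keep"
            lines.append(
                f"{f.id}: high importance ({imp:.3f}) with an interior "
                f"optimum ({best_level!r}); current levels suffice."
            )
        else:
            suggestion = "neutral"
        rows.append(
            {
                "factor": f.id,
                "importance": imp,
                "best_level": best_level,
                "best_level_strength": best_strength,
                "at_boundary": at_boundary,
                "suggestion": suggestion,
            }
        )
    if not lines:
        lines = ["No factor shows a positive attribution signal; no expansion suggested."]
    return ExpansionReport(frame=pd.DataFrame(rows), text="\n".join(lines))
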