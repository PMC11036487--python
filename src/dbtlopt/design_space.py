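"""Combinatorial pathway-library design spaces.

A library is a set of *factors* (positions in an integrated gene cluster),
each taking one of several *levels* (a promoter + ORF choice).  A *design*
assigns one level to every factor; the library size is the product of the
per-factor level counts.  Levels that could not be built experimentally are
recorded as exclusions and removed from the effective space.

Levels are categorical throughout: the promoter-strength annotation on a
:class:`Level` is metadata for reporting and expansion suggestions and is
never consumed numerically by models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "Factor",
    "LibrarySpec",
    "Design",
    "LibraryError",
    "EmptyFactorError",
    "UnknownLevelError",
    "enumerate_designs",
    "encoding_columns",
    "encode_designs",
    "decode_designs",
    "validate_measurements",
    "ValidationReport",
    "pal_library",
]

STRENGTH_ORDER = {"strong": 3, "medium": 2, "weak": 1, "unknown": 0}


class LibraryError(ValueError):
    """Invalid library construction."""


class EmptyFactorError(LibraryError):
    """A factor has no non-excluded level left."""


class UnknownLevelError(KeyError):
    """A design references a level that is missing or excluded."""


@dataclass(frozen=True)
class Level:
    """One choice for a factor: a promoter driving an ORF."""

    id: str
    promoter: str = ""
    orf: str = ""
    strength: str = "unknown"

    def __post_init__(self) -> None:
        if self.strength not in STRENGTH_ORDER:
            raise LibraryError(f"unknown promoter strength {self.strength!r}")


@dataclass(frozen=True)
class Factor:
    """One cassette slot in the gene cluster, with its candidate levels."""

    id: str
    position: int
    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        ids = [lv.id for lv in self.levels]
        if len(set(ids)) != len(ids):
            raise LibraryError(f"duplicate level ids in factor {self.id!r}")

    def level(self, level_id: str) -> Level:
        for lv in self.levels:
            if lv.id == level_id:
                return lv
        raise UnknownLevelError(f"factor {self.id!r} has no level {level_id!r}")


@dataclass(frozen=True)
class LibrarySpec:
    """A named factor/level design space with experimental exclusions."""

    name: str
    factors: tuple[Factor, ...]
    excluded: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        fids = [f.id for f in self.factors]
        if len(set(fids)) != len(fids):
            raise LibraryError("duplicate factor ids")
        positions = [f.position for f in self.factors]
        if len(set(positions)) != len(positions):
            raise LibraryError("duplicate factor positions")
        by_id = {f.id: f for f in self.factors}
        for fid, lid in self.excluded:
            if fid not in by_id:
                raise LibraryError(f"exclusion names unknown factor {fid!r}")
            by_id[fid].level(lid)  # raises if the level does not exist
        for f in self.factors:
            if not self._active(f):
                raise EmptyFactorError(
                    f"factor {f.id!r} has all levels excluded"
                )

    # -- accessors ---------------------------------------------------------
    def _active(self, factor: Factor) -> list[Level]:
        return [
            lv
            for lv in factor.levels
            if (factor.id, lv.id) not in self.excluded
        ]

    @property
    def ordered_factors(self) -> list[Factor]:
        return sorted(self.factors, key=lambda f: f.position)

    @property
    def factor_ids(self) -> list[str]:
        return [f.id for f in self.ordered_factors]

    def factor(self, factor_id: str) -> Factor:
        for f in self.factors:
            if f.id == factor_id:
                return f
        raise UnknownLevelError(f"no factor {factor_id!r}")

    def active_levels(self, factor_id: str) -> list[Level]:
        return self._active(self.factor(factor_id))

    @property
    def full_size(self) -> int:
        out = 1
        for f in self.factors:
            out *= len(f.levels)
        return out

    @property
    def size(self) -> int:
        """Effective design-space size: product of non-excluded counts."""
        out = 1
        for f in self.factors:
            out *= len(self._active(f))
        return out

    def is_excluded(self, factor_id: str, level_id: str) -> bool:
        return (factor_id, level_id) in self.excluded

    def without_exclusions(self) -> "LibrarySpec":
        return LibrarySpec(self.name, self.factors, frozenset())


@dataclass(frozen=True)
class Design:
    """A complete assignment of one level to every factor.

    ``assignment`` is stored as ``((factor_id, level_id), ...)`` in library
    factor order; equality and hashing use only this tuple, so two designs
    are equal iff their assignments are equal.
    """

    assignment: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", tuple(map(tuple, self.assignment)))

    @classmethod
    def from_dict(
        cls, mapping: Mapping[str, str], library: LibrarySpec
    ) -> "Design":
        missing = [f for f in library.factor_ids if f not in mapping]
        if missing:
            raise UnknownLevelError(f"design missing factors {missing}")
        d = cls(tuple((fid, mapping[fid]) for fid in library.factor_ids))
        validate_design(d, library)
        return d

    def level(self, factor_id: str) -> str:
        for fid, lid in self.assignment:
            if fid == factor_id:
                return lid
        raise UnknownLevelError(f"design has no factor {factor_id!r}")

    def as_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    def __str__(self) -> str:
        return ";".join(f"{fid}={lid}" for fid, lid in self.assignment)


def validate_design(design: Design, library: LibrarySpec) -> None:
    """Raise :class:`UnknownLevelError` unless every assigned level exists
    and is non-excluded and every factor is assigned exactly once."""
    seen = set()
    for fid, lid in design.assignment:
        factor = library.factor(fid)
        factor.level(lid)
        if library.is_excluded(fid, lid):
            raise UnknownLevelError(
                f"level {lid!r} of factor {fid!r} is excluded from "
                f"library {library.name!r}"
            )
        seen.add(fid)
    if seen != set(library.factor_ids):
        raise UnknownLevelError("design does not cover every factor exactly once")


# ---------------------------------------------------------------------------
# enumeration and encoding
# ---------------------------------------------------------------------------

def enumerate_designs(library: LibrarySpec) -> list[Design]:
    """Cartesian product over non-excluded levels.

    Deterministic order: factors by position, levels in declared order,
    rightmost factor varying fastest (:func:`itertools.product` order).
    """
    factors = library.ordered_factors
    pools = []
    for f in factors:
        active = library.active_levels(f.id)
        if not active:
            raise EmptyFactorError(f"factor {f.id!r} has all levels excluded")
        pools.append([(f.id, lv.id) for lv in active])
    return [Design(combo) for combo in itertools.product(*pools)]


def encoding_columns(library: LibrarySpec) -> list[tuple[str, str]]:
    """Ordered one-hot column key: one column per non-excluded (factor, level)."""
    cols = []
    for f in library.ordered_factors:
        for lv in library.active_levels(f.id):
            cols.append((f.id, lv.id))
    return cols


def encode_designs(
    designs: Sequence[Design], library: LibrarySpec
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """One-hot encode designs over the library's non-excluded levels.

    All levels are kept (no reference-level drop): each row sums to the
    number of factors and each per-factor block sums to one.  Raises
    :class:`UnknownLevelError` for designs touching excluded or unknown
    levels.
    """
    cols = encoding_columns(library)
    index = {pair: j for j, pair in enumerate(cols)}
    X = np.zeros((len(designs), len(cols)))
    for i, d in enumerate(designs):
        validate_design(d, library)
        for pair in d.assignment:
            X[i, index[pair]] = 1.0
    return X, cols


def decode_designs(
    X: np.ndarray, columns: Sequence[tuple[str, str]], library: LibrarySpec
) -> list[Design]:
    """Inverse of :func:`encode_designs` for valid one-hot matrices."""
    X = np.asarray(X)
    out = []
    for row in X:
        mapping: dict[str, str] = {}
        for val, (fid, lid) in zip(row, columns):
            if val == 1.0:
                if fid in mapping:
                    raise UnknownLevelError(
                        f"row activates two levels of factor {fid!r}"
                    )
                mapping[fid] = lid
        out.append(Design.from_dict(mapping, library))
    return out


# ---------------------------------------------------------------------------
# measurement validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Row-level validity audit of a colony measurement table."""

    n_rows: int
    n_valid: int
    n_unique_designs: int
    flags: pd.DataFrame = field(repr=False)  # columns: row, problem

    @property
    def valid_fraction(self) -> float:
        return self.n_valid / self.n_rows if self.n_rows else float("nan")


def validate_measurements(
    table: pd.DataFrame, library: LibrarySpec, titer_col: str = "titer"
) -> ValidationReport:
    """Flag rows with unknown factors/levels, missing assignments or negative
    titers; report total / valid / unique-design counts.  Report-only: never
    raises on bad rows."""
    flags: list[tuple[int, str]] = []
    fids = library.factor_ids
    valid_designs = []
    for i, row in table.iterrows():
        problems = []
        mapping = {}
        for fid in fids:
            if fid not in table.columns or pd.isna(row.get(fid)):
                problems.append(f"missing factor {fid}")
                continue
            lid = str(row[fid])
            try:
                library.factor(fid).level(lid)
            except KeyError:
                problems.append(f"unknown level {fid}={lid}")
                continue
            if library.is_excluded(fid, lid):
                problems.append(f"excluded level {fid}={lid}")
                continue
            mapping[fid] = lid
        if titer_col in table.columns:
            titer = row[titer_col]
            if pd.isna(titer):
                problems.append("missing titer")
            elif titer < 0:
                problems.append("negative titer")
        else:
            problems.append(f"missing column {titer_col}")
        for p in problems:
            flags.append((i, p))
        if not problems:
            valid_designs.append(tuple(sorted(mapping.items())))
    flag_frame = pd.DataFrame(flags, columns=["row", "problem"])
    return ValidationReport(
        n_rows=len(table),
        n_valid=len(valid_designs),
        n_unique_designs=len(set(valid_designs)),
        flags=flag_frame,
    )


# ---------------------------------------------------------------------------
# the p-coumaric acid (PAL route) library
# ---------------------------------------------------------------------------

def pal_library(reduced: bool = True) -> LibrarySpec:
    """The six-factor PAL-route library for p-coumaric acid in yeast.

    Seven ORF/promoter choices feed the shikimate pathway at factor 1;
    factors 2-3 tune AROL/ARO1 and ARO7/PHEA expression; factors 4-6 tune
    the heterologous PAL, C4H and CPR genes each under strong/medium/weak
    promoters.  The full space holds 7*4*4*3*3*3 = 3024 designs.

    With ``reduced=True`` the three cassettes that failed construction
    (strong promoter of factor 5; strong and medium promoters of factor 6)
    are excluded, leaving 672 buildable designs.
    """
    f = [
        Factor("f1", 1, (
            Level("TDH3-ENO2", "TDH3", "ENO2", "strong"),
            Level("TDH3-RKI1", "TDH3", "RKI1", "strong"),
            Level("TDH3-TKL1", "TDH3", "TKL1", "strong"),
            Level("TDH3-ARO2", "TDH3", "ARO2", "strong"),
            Level("TDH3-ARO4", "TDH3", "ARO4", "strong"),
            Level("RPL8A-ARO4", "RPL8A", "ARO4", "medium"),
            Level("MYO4-ARO4", "MYO4", "ARO4", "weak"),
        )),
        Factor("f2", 2, (
            Level("TEF1-ARO1", "TEF1", "ARO1", "strong"),
            Level("TEF1-AROL", "TEF1", "AROL", "strong"),
            Level("RPL28-AROL", "RPL28", "AROL", "medium"),
            Level("UREA3-AROL", "UREA3", "AROL", "weak"),
        )),
        Factor("f3", 3, (
            Level("PRE3-PHEA", "PRE3", "PHEA", "strong"),
            Level("PRE3-ARO7", "PRE3", "ARO7", "strong"),
            Level("ACT1-ARO7", "ACT1", "ARO7", "medium"),
            Level("PFY1-ARO7", "PFY1", "ARO7", "weak"),
        )),
        Factor("f4", 4, (
            Level("ENO2-PAL", "ENO2", "PAL", "strong"),
            Level("RPS9A-PAL", "RPS9A", "PAL", "medium"),
            Level("VMA6-PAL", "VMA6", "PAL", "weak"),
        )),
        Factor("f5", 5, (
            Level("KI_OLE1-C4H", "KI_OLE1", "C4H", "strong"),
            Level("CHO1-C4H", "CHO1", "C4H", "medium"),
            Level("PXR1-C4H", "PXR1", "C4H", "weak"),
        )),
        Factor("f6", 6, (
            Level("PGK1-CPR", "PGK1", "CPR", "strong"),
            Level("RPS3-CPR", "RPS3", "CPR", "medium"),
            Level("CCW12-CPR", "CCW12", "CPR", "weak"),
        )),
    ]
    excluded: frozenset[tuple[str, str]] = frozenset()
    if reduced:
        excluded = frozenset({
            ("f5", "KI_OLE1-C4H"),
            ("f6", "PGK1-CPR"),
            ("f6", "RPS3-CPR"),
        })
    return LibrarySpec("PAL", tuple(f), excluded)
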