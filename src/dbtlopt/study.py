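"""The canonical simulated study: a screening campaign over the reduced
PAL library shaped like the real p-coumaric acid screen.

These helpers fix, in one place, the synthetic conditions used by the
analysis scripts, the acceptance study and the heavier tests:

* the 672-design reduced PAL library;
* a landscape with baseline 0.09 au, additive level effects uniform on
  (-0.05, 0.05), 5% pairwise interaction density with terms uniform on
  (-0.02, 0.02), and 0.01 au replicate noise -- chosen so simulated titers
  span roughly 0-0.25 au with ~30% of designs below the 0.05 au detection
  limit, matching the observed scale of the screen;
* a sequencing campaign of 225 colonies at 84% correct, thinned to 91
  unique designs (13.5% of the space) for the complete dataset, of which
  the producers subset retains the designs at or above the detection
  limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import (
    DesignDataset,
    StratificationScheme,
    assign_strata,
    collapse_replicates,
    filter_producers,
)
from .design_space import LibrarySpec, pal_library
from .landscape import (
    LandscapeModel,
    ScreenConfig,
    sample_landscape,
    simulate_screen,
)

__all__ = ["StudyData", "campaign_landscape", "simulate_study"]

N_SEQUENCED = 225
CORRECT_FRACTION = 0.84
N_UNIQUE_TARGET = 91
DETECTION_LIMIT = 0.05


def campaign_landscape(
    seed: int,
    library: LibrarySpec | None = None,
    **overrides,
) -> LandscapeModel:
    """A random additive-plus-mild-interaction landscape at study defaults."""
    library = library or pal_library(reduced=True)
    params = dict(
        baseline=0.09,
        effect_range=(-0.05, 0.05),
        interaction_density=0.05,
        interaction_range=(-0.02, 0.02),
        noise_sd=0.01,
    )
    params.update(overrides)
    return sample_landscape(library, seed=seed, **params)


@dataclass
class StudyData:
    """One simulated campaign: landscape, raw screen, and both datasets."""

    library: LibrarySpec
    landscape: LandscapeModel
    screen: "object"  # colony-level DataFrame
    complete: DesignDataset
    producers: DesignDataset


def simulate_study(
    seed: int,
    library: LibrarySpec | None = None,
    landscape: LandscapeModel | None = None,
    n_sequenced: int = N_SEQUENCED,
    correct_fraction: float = CORRECT_FRACTION,
    n_unique: int = N_UNIQUE_TARGET,
    detection_limit: float = DETECTION_LIMIT,
    scheme: StratificationScheme = StratificationScheme(4),
) -> StudyData:
    """Simulate the screening-before-sequencing campaign end to end.

    A screen of ``n_sequenced`` colonies is simulated, replicates are
    averaged over the correct colonies, and -- because uniform colony
    sampling yields more unique designs than a real one-pot library whose
    cassette abundances are skewed -- the unique designs are thinned
    uniformly (seeded) to ``n_unique`` rows.  Strata are assigned to both
    the complete and the producers dataset.
    """
    rng = np.random.default_rng(seed)
    library = library or pal_library(reduced=True)
    if landscape is None:
        landscape = campaign_landscape(int(rng.integers(2**31 - 1)), library)
    screen = simulate_screen(
        landscape,
        library,
        ScreenConfig(
            n_colonies=n_sequenced,
            correct_fraction=correct_fraction,
            detection_limit=detection_limit,
            seed=int(rng.integers(2**31 - 1)),
        ),
    )
    complete = collapse_replicates(
        screen, library, detection_limit, source=f"simulated-study-seed{seed}"
    )
    if len(complete) > n_unique:
        keep = sorted(
            int(i)
            for i in rng.choice(len(complete), size=n_unique, replace=False)
        )
        complete = complete.take(keep)
    complete = assign_strata(complete, scheme)
    producers = assign_strata(filter_producers(complete), scheme)
    return StudyData(
        library=library,
        landscape=landscape,
        screen=screen,
        complete=complete,
        producers=producers,
    )
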