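"""Persistence landscapes over a fixed 15-position asymmetry-value grid.

A landscape turns a persistence diagram into a fixed-length vector so
cohorts with different numbers of persistence pairs can be compared
position by position.  Each pair (b, d) contributes a "tent" function
peaking at half its lifespan over the midpoint of [b, d]; the level-k
landscape at position t is the k-th largest tent value.  The level-1
landscape records the single most persistent structure covering t, while
the sum over levels equals the total tent mass and tracks the *density*
of structures — the reading used for the cohort analyses.

The position grid is cohort-global by default (the min/max asymmetry
value over all images) so that "position 6" means the same contrast
value for every participant.  Positions are indexed 1..15 in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cubical import PersistenceDiagram, PersistencePair
from .grid import AsymmetryImage

DEFAULT_N_POSITIONS = 15


@dataclass(frozen=True)
class LandscapeGrid:
    """Evenly spaced evaluation positions over an asymmetry-value range."""

    t_min: float
    t_max: float
    n_positions: int = DEFAULT_N_POSITIONS

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(f"t_min {self.t_min} must be < t_max {self.t_max}")
        if self.n_positions < 2:
            raise ValueError("need at least 2 positions")

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.n_positions)


@dataclass
class Landscape:
    """Landscape values of one diagram (one dim, one ROI, one participant)."""

    dim: int
    values: np.ndarray
    grid: LandscapeGrid
    level: int = 1
    aggregate: str = "single-level"
    roi_label: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_positions,):
            raise ValueError("values length must match the grid positions")


def _tent(pair: PersistencePair, t: float) -> float:
    return max(0.0, min(t - pair.birth_value, pair.death_value - t))


def landscape_value(pairs: list[PersistencePair], t: float, k: int = 1) -> float:
    """k-th largest tent value max(0, min(t - b, d - t)) over the pairs.

    Zero if fewer than k pairs cover t.
    """
    if k < 1:
        raise ValueError(f"level k must be >= 1, got {k}")
    tents = sorted((_tent(p, t) for p in pairs), reverse=True)
    return tents[k - 1] if len(tents) >= k else 0.0


def sum_of_levels_value(pairs: list[PersistencePair], t: float) -> float:
    """Sum over all levels, equal to the total tent mass at t."""
    return float(sum(_tent(p, t) for p in pairs))


def make_landscape(diagram: PersistenceDiagram, grid: LandscapeGrid,
                   k: int = 1, aggregate: str = "single-level",
                   include_zero_persistence: bool = False) -> Landscape:
    """Evaluate a landscape at each grid position.

    ``aggregate='single-level'`` returns the level-k landscape;
    ``aggregate='sum-of-levels'`` returns the sum over all levels (the
    density reading).  The diagram must be restricted to one dimension.
    Zero-lifespan pairs contribute nothing and are skipped by default.
    """
    dims = {p.dim for p in diagram.pairs}
    if len(dims) > 1:
        raise ValueError(f"diagram mixes dimensions {sorted(dims)}; restrict first")
    if aggregate not in ("single-level", "sum-of-levels"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    pairs = diagram.pairs if include_zero_persistence else diagram.nonzero().pairs
    if aggregate == "single-level":
        vals = [landscape_value(pairs, t, k) for t in grid.positions]
    else:
        vals = [sum_of_levels_value(pairs, t) for t in grid.positions]
    dim = dims.pop() if dims else 0
    return Landscape(dim=dim, values=np.array(vals), grid=grid, level=k,
                     aggregate=aggregate, roi_label="",
                     participant_id=diagram.source_id)


def global_value_range(images: list[AsymmetryImage],
                       n_positions: int = DEFAULT_N_POSITIONS) -> LandscapeGrid:
    """Cohort-global landscape grid spanning the value range of all images.

    A common axis is required so regressions compare the same positions
    across participants.
    """
    if not images:
        raise ValueError("need at least one image")
    t_min = min(float(im.values.min()) for im in images)
    t_max = max(float(im.values.max()) for im in images)
    return LandscapeGrid(t_min, t_max, n_positions)


def density_difference(l0: Landscape, l2: Landscape) -> float:
    """Mean over positions of (0-cycle landscape - 2-cycle landscape).

    Positive values mean rightward structures are denser than leftward
    ones in the ROI.
    """
    if l0.grid != l2.grid:
        raise ValueError("landscapes evaluated on different grids")
    return float(np.mean(l0.values - l2.values))
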