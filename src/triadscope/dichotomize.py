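"""Ordinal-to-binary dichotomization of contact matrices.

The 1-5 "time spent together" ratings are cut into three nested binary
contact networks: minimum contact (rating >= 2, i.e. any contact at all),
intermediate contact (>= 3) and maximum contact (>= 4).  The missing-rating
sentinel dichotomizes to 0 at every level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import UsageError, ValidationError
from .model import BinaryNetwork, ContactMatrix

LEVELS = ("minimum", "intermediate", "maximum")


@dataclass(frozen=True)
class IntensityThresholds:
    """Rating cut-offs per intensity level: tie iff rating >= cut.

    Defaults are 2/3/4 (minimum/intermediate/maximum).  Cuts must be
    non-decreasing so the tie sets nest: maximum ⊆ intermediate ⊆ minimum.
    """

    minimum_cut: int = 2
    intermediate_cut: int = 3
    maximum_cut: int = 4

    def __post_init__(self) -> None:
        if not 2 <= self.minimum_cut <= self.intermediate_cut <= self.maximum_cut <= 5:
            raise ValidationError(
                "intensity cuts must satisfy 2 <= minimum <= intermediate <= maximum <= 5, "
                f"got {self.minimum_cut}/{self.intermediate_cut}/{self.maximum_cut}"
            )

    def cut(self, level: str) -> int:
        try:
            return {
                "minimum": self.minimum_cut,
                "intermediate": self.intermediate_cut,
                "maximum": self.maximum_cut,
            }[level]
        except KeyError:
            raise UsageError(f"unknown intensity level {level!r}; expected one of {LEVELS}") from None


class DichotomizedLayers(NamedTuple):
    minimum: BinaryNetwork
    intermediate: BinaryNetwork
    maximum: BinaryNetwork


def dichotomize(
    matrix: ContactMatrix,
    level: str,
    thresholds: IntensityThresholds = IntensityThresholds(),
) -> BinaryNetwork:
    """Binary contact network at one intensity level (tie iff rating >= cut)."""
    cut = thresholds.cut(level)
    adjacency = (matrix.values >= cut).astype(int)  # MISSING (0) always < cut
    np.fill_diagonal(adjacency, 0)
    return BinaryNetwork(
        classroom=matrix.classroom,
        actor_order=list(matrix.actor_order),
        adjacency=adjacency,
        layer=level,
    )


def dichotomize_all(
    matrix: ContactMatrix,
    thresholds: IntensityThresholds = IntensityThresholds(),
) -> DichotomizedLayers:
    """All three intensity layers; tie sets satisfy max ⊆ intermediate ⊆ min."""
    return DichotomizedLayers(
        *(dichotomize(matrix, level, thresholds) for level in LEVELS)
    )
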