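"""Single-neuron conductance inference from a spiking-pattern sequence.

A neuron tested at several stimulus intensities exhibits a sequence of
spiking patterns.  Each observed (I_stim, pattern) pair constrains the
neuron's (g_K,lt, g_K,A) to the region with that label on the map for
that intensity; the estimate is the set intersection of those regions
across intensities.  The construct is purely set-valued: an empty
intersection means no model neuron reproduces the sequence, and adding
observations can only shrink (never grow) the consistent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import PatternLabel
from .patternmap import SpikingPatternMap

__all__ = ["PatternSequence", "DensityEstimate", "infer_densities",
           "DEFAULT_TEST_INTENSITIES"]

#: conventional test set of stimulus intensities (uA/cm^2)
DEFAULT_TEST_INTENSITIES = tuple(float(I) for I in range(50, 85, 5))


@dataclass
class PatternSequence:
    """Ordered (I_stim, label) observations with unique intensities."""

    observations: list[tuple[float, PatternLabel]]

    def __post_init__(self) -> None:
        intensities = [I for I, _ in self.observations]
        if len(set(intensities)) != len(intensities):
            raise ValueError("stimulus intensities must be unique")


@dataclass
class DensityEstimate:
    """Grid points consistent with every observation.

    ``mask`` is a boolean array over the (shared) map grid;
    ``consistent_points`` the corresponding (n, 2) coordinates;
    ``region_sizes`` the per-plane region size for each observation.
    """

    mask: np.ndarray
    consistent_points: np.ndarray
    region_sizes: dict[float, int] = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[tuple[float, float], tuple[float, float]] | None:
        """Convenience summary ((g_lt_min, g_lt_max), (g_A_min, g_A_max))."""
        if self.n_points == 0:
            return None
        p = self.consistent_points
        return ((p[:, 0].min(), p[:, 0].max()), (p[:, 1].min(), p[:, 1].max()))


def infer_densities(seq: PatternSequence,
                    maps: dict[float, SpikingPatternMap]) -> DensityEstimate:
    """Intersect the per-intensity label regions over all observations.

    ``maps`` is keyed by I_stim; a missing map for a requested intensity
    raises ``KeyError`` (label interpolation between intensities is
    undefined, so maps must be built on demand instead).  All maps must
    share one grid.
    """
    if not seq.observations:
        raise ValueError("empty pattern sequence")
    first = None
    mask = None
    sizes: dict[float, int] = {}
    for I, label in seq.observations:
        if I not in maps:
            raise KeyError(f"no spiking-pattern map available for I_stim = {I}")
        pmap = maps[I]
        if first is None:
            first = pmap
        elif pmap.grid != first.grid:
            raise ValueError("all maps in a stack must share the same grid")
        region = pmap.labels == int(label)
        sizes[I] = int(region.sum())
        mask = region if mask is None else (mask & region)
    GL, GA = np.meshgrid(first.grid.g_lt_values, first.grid.g_A_values, indexing="ij")
    pts = np.column_stack([GL[mask], GA[mask]])
    return DensityEstimate(mask=mask, consistent_points=pts, region_sizes=sizes)
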