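"""Spiking-pattern maps over the (g_K,lt, g_K,A) conductance plane.

A map is built by simulating the model at every node of a regular grid of
the two potassium conductance densities under a fixed stimulus protocol
and classifying each response.  The plane splits into contiguous regions,
one per pattern; their boundaries are the loci where the spiking pattern
bifurcates.  Maps are deterministic for fixed inputs and expensive to
build, so they can be persisted (CSV label matrix + JSON header) and
reloaded losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .model import NeuronParameters, StimulusProtocol
from .classify import PatternLabel, classify_stats, LABEL_ORDER
from .sweep import sweep_spike_stats

__all__ = ["GridSpec", "SpikingPatternMap", "RegionGeometry",
           "build_map", "region_geometry", "map_stack", "load_or_build_map"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over the conductance plane (mS/cm^2).

    Defaults cover 0-20 mS/cm^2 on both axes in 0.1 mS/cm^2 increments
    (201 x 201 nodes).
    """

    g_lt_max: float = 20.0
    g_A_max: float = 20.0
    step: float = 0.1
    g_lt_min: float = 0.0
    g_A_min: float = 0.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.g_lt_max <= self.g_lt_min or self.g_A_max <= self.g_A_min:
            raise ValueError("grid extents must be positive")

    @property
    def g_lt_values(self) -> np.ndarray:
        n = int(round((self.g_lt_max - self.g_lt_min) / self.step)) + 1
        return np.round(self.g_lt_min + self.step * np.arange(n), 9)

    @property
    def g_A_values(self) -> np.ndarray:
        n = int(round((self.g_A_max - self.g_A_min) / self.step)) + 1
        return np.round(self.g_A_min + self.step * np.arange(n), 9)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.g_lt_values), len(self.g_A_values)


@dataclass
class SpikingPatternMap:
    """Grid of pattern labels; ``labels[i, j]`` is the label at
    ``(g_lt_values[i], g_A_values[j])``."""

    grid: GridSpec
    labels: np.ndarray  # int8 codes 1-5, shape (n_lt, n_A)
    protocol: StimulusProtocol
    params: NeuronParameters = field(default_factory=NeuronParameters)

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array shape does not match grid")

    def nearest_index(self, g_lt, g_A) -> tuple[np.ndarray, np.ndarray]:
        """Indices of the grid node nearest each (possibly off-grid) point.

        Points outside the domain clip to the nearest edge node.
        """
        g = self.grid
        i = np.clip(np.round((np.asarray(g_lt, dtype=float) - g.g_lt_min) / g.step),
                    0, g.shape[0] - 1).astype(int)
        j = np.clip(np.round((np.asarray(g_A, dtype=float) - g.g_A_min) / g.step),
                    0, g.shape[1] - 1).astype(int)
        return i, j

    def label_at(self, g_lt: float, g_A: float) -> PatternLabel:
        i, j = self.nearest_index(g_lt, g_A)
        return PatternLabel(int(self.labels[i, j]))

    def save(self, path: str | Path) -> None:
        """Write the label matrix (rows = g_A, columns = g_lt, codes 1-5)
        as CSV plus a JSON header; round-trips losslessly."""
        path = Path(path)
        np.savetxt(path, self.labels.T, fmt="%d", delimiter=",")
        header = {
            "grid": asdict(self.grid),
            "protocol": asdict(self.protocol),
            "params": asdict(self.params),
            "label_codes": {lab.name.lower(): int(lab) for lab in LABEL_ORDER},
            "layout": "rows = g_K,A index, columns = g_K,lt index",
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpikingPatternMap":
        path = Path(path)
        header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        labels = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2).T
        return cls(grid=GridSpec(**header["grid"]),
                   labels=labels,
                   protocol=StimulusProtocol(**header["protocol"]),
                   params=NeuronParameters(**header["params"]))

    def cache_key(self) -> str:
        payload = json.dumps(
            {"grid": asdict(self.grid), "protocol": asdict(self.protocol),
             "params": asdict(self.params)}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RegionGeometry:
    """Per-pattern point sets, counts and centroids of a map.

    ``points[label]`` is an (n_i, 2) array of (g_lt, g_A) node coordinates;
    ``centroids[label]`` is the arithmetic mean of those points, or None
    for an empty region.  The point sets partition the grid.
    """

    points: dict[PatternLabel, np.ndarray]
    centroids: dict[PatternLabel, np.ndarray | None]
    counts: dict[PatternLabel, int]


def build_map(grid: GridSpec = GridSpec(),
              protocol: StimulusProtocol = StimulusProtocol(),
              params: NeuronParameters = NeuronParameters()) -> SpikingPatternMap:
    """Simulate and classify every grid node (vectorized over the grid)."""
    glt_vals = grid.g_lt_values
    gA_vals = grid.g_A_values
    GL, GA = np.meshgrid(glt_vals, gA_vals, indexing="ij")
    stats = sweep_spike_stats(GL.ravel(), GA.ravel(), params=params, protocol=protocol)
    labels = classify_stats(stats).reshape(grid.shape)
    return SpikingPatternMap(grid=grid, labels=labels, protocol=protocol, params=params)


def region_geometry(pmap: SpikingPatternMap) -> RegionGeometry:
    """Point sets, counts and centroids (unweighted mean of node
    coordinates) for each of the five regions."""
    GL, GA = np.meshgrid(pmap.grid.g_lt_values, pmap.grid.g_A_values, indexing="ij")
    points: dict[PatternLabel, np.ndarray] = {}
    centroids: dict[PatternLabel, np.ndarray | None] = {}
    counts: dict[PatternLabel, int] = {}
    for lab in LABEL_ORDER:
        mask = pmap.labels == int(lab)
        pts = np.column_stack([GL[mask], GA[mask]])
        points[lab] = pts
        counts[lab] = int(mask.sum())
        centroids[lab] = pts.mean(axis=0) if len(pts) else None
    return RegionGeometry(points=points, centroids=centroids, counts=counts)


def map_stack(grid: GridSpec = GridSpec(),
              I_stim_values=None, I_pre_values=None,
              protocol: StimulusProtocol = StimulusProtocol(),
              params: NeuronParameters = NeuronParameters()) -> list[SpikingPatternMap]:
    """One map per condition in a sweep of stimulus intensity or pre-pulse.

    Exactly one of ``I_stim_values`` / ``I_pre_values`` must be given; the
    other protocol fields are taken from ``protocol``.
    """
    if (I_stim_values is None) == (I_pre_values is None):
        raise ValueError("give exactly one of I_stim_values or I_pre_values")
    maps = []
    if I_stim_values is not None:
        for I in I_stim_values:
            maps.append(build_map(grid, protocol.replace(I_stim=float(I)), params))
    else:
        for I in I_pre_values:
            maps.append(build_map(grid, protocol.replace(I_pre=float(I)), params))
    return maps


def load_or_build_map(cache_dir: str | Path | None,
                      grid: GridSpec = GridSpec(),
                      protocol: StimulusProtocol = StimulusProtocol(),
                      params: NeuronParameters = NeuronParameters()) -> SpikingPatternMap:
    """Build a map, reusing a cached copy keyed by (grid, protocol, params)."""
    if cache_dir is None:
        return build_map(grid, protocol, params)
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    probe = SpikingPatternMap(grid=grid,
                              labels=np.zeros(grid.shape, dtype=np.int8) + 1,
                              protocol=protocol, params=params)
    path = cache_dir / f"map-{probe.cache_key()}.csv"
    if path.exists():
        return SpikingPatternMap.load(path)
    pmap = build_map(grid, protocol, params)
    pmap.save(path)
    return pmap
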