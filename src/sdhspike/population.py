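"""Forward population model: channel-density distribution -> pattern proportions.

Across a population of neurons of one type, the two potassium conductance
densities (g_K,lt, g_K,A) are modelled as a bivariate normal distribution
(BND) with means (mu_x, mu_y), standard deviations (sigma_x, sigma_y) and
correlation rho.  The expected proportion of each spiking pattern i is
the volume V_i of the BND over the pattern's region R_i of a spiking-
pattern map, computed by two-dimensional trapezoidal integration with
region membership by nearest-node label lookup.

Because the map domain is finite (and conductances cannot be negative),
the total integrated mass ("coverage") is slightly below 1; proportions
are reported unrenormalized alongside the coverage, and sum to it
exactly.  An empirical counterpart draws a finite sample of neurons from
the BND and counts the labels of their nearest map nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classify import PatternLabel, LABEL_ORDER
from .patternmap import SpikingPatternMap

__all__ = ["BivariateNormal", "ProportionVector", "bnd_pdf",
           "proportions", "sample_population"]


@dataclass(frozen=True)
class BivariateNormal:
    """Bivariate normal over (g_K,lt, g_K,A), in mS/cm^2."""

    mu_x: float = 3.0
    mu_y: float = 4.0
    sigma_x: float = 1.0
    sigma_y: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("standard deviations must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie strictly within (-1, 1)")

    @property
    def cov(self) -> np.ndarray:
        c = self.rho * self.sigma_x * self.sigma_y
        return np.array([[self.sigma_x**2, c], [c, self.sigma_y**2]])


def bnd_pdf(dist: BivariateNormal, x, y):
    """Probability density of the BND at (x, y); accepts arrays.

    The density is
    ``exp(-Q / (2 (1 - rho^2))) / (2 pi sigma_x sigma_y sqrt(1 - rho^2))``
    with the quadratic form
    ``Q = dx^2/sx^2 - 2 rho dx dy/(sx sy) + dy^2/sy^2``.
    """
    dx = (np.asarray(x, dtype=float) - dist.mu_x) / dist.sigma_x
    dy = (np.asarray(y, dtype=float) - dist.mu_y) / dist.sigma_y
    q = dx**2 - 2.0 * dist.rho * dx * dy + dy**2
    norm = 2.0 * np.pi * dist.sigma_x * dist.sigma_y * np.sqrt(1.0 - dist.rho**2)
    return np.exp(-q / (2.0 * (1.0 - dist.rho**2))) / norm


@dataclass
class ProportionVector:
    """Spiking-pattern proportions V_i, i = 1..5 (reluctant, single,
    delayed, gap, tonic), plus the total integrated mass over the map
    domain.  ``sum(values) == coverage`` by construction."""

    values: np.ndarray  # shape (5,), ordered reluctant..tonic
    coverage: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (5,):
            raise ValueError("a proportion vector has exactly 5 entries")

    def __getitem__(self, label: PatternLabel) -> float:
        return float(self.values[int(label) - 1])

    def as_dict(self) -> dict[str, float]:
        d = {lab.name.lower(): float(self.values[int(lab) - 1]) for lab in LABEL_ORDER}
        d["coverage"] = float(self.coverage)
        return d

    def renormalized(self) -> "ProportionVector":
        return ProportionVector(values=self.values / self.coverage, coverage=1.0)


def _trapezoid_weights(values: np.ndarray) -> np.ndarray:
    """Composite-trapezoid node weights for a uniform 1-D grid."""
    step = values[1] - values[0]
    w = np.full(len(values), step)
    w[0] = w[-1] = step / 2.0
    return w


def proportions(dist: BivariateNormal, pmap: SpikingPatternMap,
                integration_step: float | None = None,
                coverage_warn: float = 0.999) -> ProportionVector:
    """Integrate the BND over each pattern region of the map (Eq. V_i).

    The integration sub-grid defaults to the map grid itself; a finer
    ``integration_step`` refines the quadrature while labels are still
    looked up at the nearest map node.  Warns when coverage (total mass
    inside the map domain) falls below ``coverage_warn``.
    """
    g = pmap.grid
    if integration_step is None:
        x = g.g_lt_values
        y = g.g_A_values
        labels = pmap.labels
    else:
        nx = int(round((g.g_lt_max - g.g_lt_min) / integration_step)) + 1
        ny = int(round((g.g_A_max - g.g_A_min) / integration_step)) + 1
        x = g.g_lt_min + integration_step * np.arange(nx)
        y = g.g_A_min + integration_step * np.arange(ny)
        i, j = pmap.nearest_index(*np.meshgrid(x, y, indexing="ij"))
        labels = pmap.labels[i, j]

    X, Y = np.meshgrid(x, y, indexing="ij")
    density = bnd_pdf(dist, X, Y) * np.outer(_trapezoid_weights(x), _trapezoid_weights(y))
    values = np.array([float(density[labels == int(lab)].sum()) for lab in LABEL_ORDER])
    coverage = float(values.sum())
    if coverage < coverage_warn:
        warnings.warn(
            f"only {coverage:.4f} of the distribution mass lies inside the "
            f"map domain; proportions are not normalized", stacklevel=2)
    return ProportionVector(values=values, coverage=coverage)


def sample_population(dist: BivariateNormal, n: int, seed,
                      pmap: SpikingPatternMap) -> tuple[ProportionVector, np.ndarray]:
    """Empirical proportions from ``n`` neurons drawn from the BND.

    Each sampled (g_K,lt, g_K,A) point is assigned the label of its
    nearest map node (points outside the domain, including negative
    conductances, take the nearest edge node, so counts always sum to
    ``n``).  Returns the proportion vector and the sampled points
    (shape ``(n, 2)``).  Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    pts = rng.multivariate_normal([dist.mu_x, dist.mu_y], dist.cov, size=n)
    i, j = pmap.nearest_index(pts[:, 0], pts[:, 1])
    codes = pmap.labels[i, j]
    counts = np.array([(codes == int(lab)).sum() for lab in LABEL_ORDER])
    return ProportionVector(values=counts / n, coverage=1.0), pts
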