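"""Inverse population model: pattern proportions -> channel-density distribution.

Estimates the parameters of the bivariate normal distribution (BND) of
(g_K,lt, g_K,A) from an observed vector of spiking-pattern proportions,
using an iterative two-step geometric algorithm:

* **Step 1 (correlation):** with the current centre fixed, the
  correlation rho is scanned over a coarse grid (-0.9..0.9 in 0.1 steps);
  when the best MaxError drops below a refinement threshold epsilon the
  scan is repeated on a fine grid (-0.99..0.99 in 0.01 steps).  MaxError
  is the largest absolute difference between target and calculated
  proportions; if it falls below the stopping threshold delta the whole
  fit terminates immediately.
* **Step 2 (means):** the centre M is displaced by the net sum of
  error-scaled unit vectors pointing from M to each region centroid
  (towards under-estimated regions, away from over-estimated ones):
  d_i = C_i - M,  e_i = E_i d_i/|d_i|,  M <- M + sum_i e_i.

The two steps alternate until MaxError < delta, the centre displacement
falls below a tolerance, or an iteration cap is reached.  The standard
deviations are not fitted directly; instead the whole two-step fit is
re-run over a grid of (sigma_x, sigma_y) values and the pair with the
lowest final MaxError wins.  The sigma grid is embarrassingly parallel
and the implementation batches all pairs through the same vectorized
integration kernel; results are independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import PatternLabel, LABEL_ORDER
from .patternmap import SpikingPatternMap, RegionGeometry, region_geometry
from .population import BivariateNormal, ProportionVector, proportions

__all__ = ["FitConfig", "FitResult", "error_terms", "optimize_rho",
           "update_centre", "fit", "fit_with_sigma_search"]


def _rho_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), 9)


@dataclass(frozen=True)
class FitConfig:
    """Tunable parameters of the inverse fit.

    ``delta`` is the stopping threshold on MaxError (0.1% error) and
    ``epsilon`` the threshold below which the rho scan switches to its
    fine grid (0.3%).  ``initial_centre`` defaults to the centre of the
    map domain.  ``sigma`` is the fixed (sigma_x, sigma_y) used by
    :func:`fit`; ``sigma_grid`` is the (lo, hi, step) search range used
    by :func:`fit_with_sigma_search`.
    """

    delta: float = 0.001
    epsilon: float = 0.003
    rho_coarse: tuple[float, float, float] = (-0.9, 0.9, 0.1)
    rho_fine: tuple[float, float, float] = (-0.99, 0.99, 0.01)
    max_iterations: int = 200
    convergence_tol: float = 1e-4    # mS/cm^2 centre displacement
    initial_centre: tuple[float, float] | None = None
    sigma: tuple[float, float] = (1.0, 1.0)
    sigma_grid: tuple[float, float, float] = (0.4, 1.6, 0.05)
    integration_step: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.delta < self.epsilon:
            raise ValueError("thresholds must satisfy 0 < delta < epsilon")


@dataclass
class FitResult:
    mu_Klt: float
    mu_KA: float
    rho: float
    sigma_Klt: float
    sigma_KA: float
    max_error: float
    fitted: ProportionVector
    iterations: int
    status: str                       # "converged_error" | "converged_centre" | "max_iterations"
    history: list[dict] = field(default_factory=list)
    sigma_error_surface: np.ndarray | None = None

    def distribution(self) -> BivariateNormal:
        return BivariateNormal(mu_x=self.mu_Klt, mu_y=self.mu_KA,
                               sigma_x=self.sigma_Klt, sigma_y=self.sigma_KA,
                               rho=self.rho)


def _target_values(target) -> np.ndarray:
    if isinstance(target, ProportionVector):
        return np.asarray(target.values, dtype=float)
    t = np.asarray(target, dtype=float)
    if t.shape != (5,):
        raise ValueError("target must have 5 entries (reluctant..tonic)")
    return t


def error_terms(target, calc) -> tuple[np.ndarray, float]:
    """Signed errors E_i = V_target,i - V_calc,i and their MaxError."""
    e = _target_values(target) - _target_values(calc)
    return e, float(np.max(np.abs(e)))


class _MapIntegrator:
    """Fast repeated BND integration over a fixed map partition.

    Precomputes flat node coordinates and a (N, 5) matrix of trapezoid
    weights split by region label, so that the five volumes for a batch
    of candidate distributions reduce to one exp() evaluation and one
    matrix product per candidate.
    """

    def __init__(self, pmap: SpikingPatternMap, integration_step: float | None = None):
        g = pmap.grid
        if integration_step is None:
            x, y = g.g_lt_values, g.g_A_values
            labels = pmap.labels
        else:
            nx = int(round((g.g_lt_max - g.g_lt_min) / integration_step)) + 1
            ny = int(round((g.g_A_max - g.g_A_min) / integration_step)) + 1
            x = g.g_lt_min + integration_step * np.arange(nx)
            y = g.g_A_min + integration_step * np.arange(ny)
            i, j = pmap.nearest_index(*np.meshgrid(x, y, indexing="ij"))
            labels = pmap.labels[i, j]

        def trap(v):
            w = np.full(len(v), v[1] - v[0])
            w[0] = w[-1] = (v[1] - v[0]) / 2.0
            return w

        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        W = np.outer(trap(self.x), trap(self.y))
        self.W_by_label = np.zeros(labels.shape + (5,))
        for lab in LABEL_ORDER:
            m = labels == int(lab)
            self.W_by_label[m, int(lab) - 1] = W[m]

    #: half-width of the evaluation window in units of sigma; the mass
    #: beyond it (~1e-9) is far below the fit's error resolution
    WINDOW_SIGMA = 6.0

    def scan(self, centre, sigma, rhos) -> np.ndarray:
        """Region volumes at one (centre, sigma) for many rho candidates.

        Evaluation is restricted to the nodes within WINDOW_SIGMA standard
        deviations of the centre.  Returns shape ``(len(rhos), 5)``.
        """
        mx, my = float(centre[0]), float(centre[1])
        sx, sy = float(sigma[0]), float(sigma[1])
        r = np.atleast_1d(np.asarray(rhos, dtype=float))
        x0 = np.searchsorted(self.x, mx - self.WINDOW_SIGMA * sx)
        x1 = max(np.searchsorted(self.x, mx + self.WINDOW_SIGMA * sx), x0 + 1)
        y0 = np.searchsorted(self.y, my - self.WINDOW_SIGMA * sy)
        y1 = max(np.searchsorted(self.y, my + self.WINDOW_SIGMA * sy), y0 + 1)
        dx = (self.x[x0:x1] - mx) / sx
        dy = (self.y[y0:y1] - my) / sy
        sq = (dx[:, None] ** 2 + dy[None, :] ** 2).ravel()
        cross = (dx[:, None] * dy[None, :]).ravel()
        rc = r[:, None]
        q = sq[None, :] - (2.0 * rc) * cross[None, :]
        q *= -0.5 / (1.0 - rc * rc)
        p = np.exp(q, out=q)
        p /= (2.0 * np.pi * sx * sy * np.sqrt(1.0 - r * r))[:, None]
        W = self.W_by_label[x0:x1, y0:y1].reshape(-1, 5)
        return p @ W

    def volumes(self, mu_x, mu_y, sigma_x, sigma_y, rho) -> np.ndarray:
        """Region volumes for a batch of BNDs; inputs broadcast to a common
        leading shape, output has shape ``leading + (5,)``."""
        mu_x, mu_y, sigma_x, sigma_y, rho = np.broadcast_arrays(
            *(np.asarray(a, dtype=float) for a in (mu_x, mu_y, sigma_x, sigma_y, rho)))
        shape = mu_x.shape
        mx, my = mu_x.ravel(), mu_y.ravel()
        sx, sy = sigma_x.ravel(), sigma_y.ravel()
        r = rho.ravel()
        out = np.empty((mx.size, 5))
        for k in range(mx.size):
            out[k] = self.scan((mx[k], my[k]), (sx[k], sy[k]), [r[k]])[0]
        return out.reshape(shape + (5,))


def _best_rho_rows(rhos: np.ndarray, maxerrs: np.ndarray,
                   incumbents: np.ndarray) -> np.ndarray:
    """Row-wise index of the minimizing rho; ties go to the candidate
    nearest the row's incumbent, then to the smaller \\|rho\\|."""
    best = maxerrs.min(axis=1, keepdims=True)
    # composite key: distance to incumbent dominates, |rho| breaks remaining
    # ties; the tie band absorbs quadrature round-off so that numerically
    # indistinguishable candidates cannot drag rho around
    key = np.abs(rhos[None, :] - incumbents[:, None]) * 10.0 + np.abs(rhos)[None, :]
    key = np.where(maxerrs <= best + 1e-12, key, np.inf)
    return np.argmin(key, axis=1)


def _best_rho(rhos: np.ndarray, maxerrs: np.ndarray, incumbent: float) -> int:
    return int(_best_rho_rows(rhos, maxerrs[None, :], np.array([incumbent]))[0])


@dataclass
class _RhoScan:
    rho: float
    max_error: float
    errors: np.ndarray
    volumes: np.ndarray
    stop: bool            # MaxError < delta: the whole fit ends here
    refined: bool         # fine grid was used


def optimize_rho(centre, sigma, target, integrator: _MapIntegrator,
                 config: FitConfig = FitConfig(), incumbent: float = 0.0) -> _RhoScan:
    """Step 1: scan rho at a fixed centre and return the best candidate."""
    t = _target_values(target)
    mx, my = centre
    sx, sy = sigma

    def scan(rhos):
        vols = integrator.scan((mx, my), (sx, sy), rhos)
        errs = t[None, :] - vols
        return vols, errs, np.abs(errs).max(axis=1)

    rhos = _rho_grid(*config.rho_coarse)
    vols, errs, maxerrs = scan(rhos)
    i = _best_rho(rhos, maxerrs, incumbent)
    refined = False
    if maxerrs[i] >= config.delta and maxerrs[i] < config.epsilon:
        rhos = _rho_grid(*config.rho_fine)
        vols, errs, maxerrs = scan(rhos)
        i = _best_rho(rhos, maxerrs, incumbent)
        refined = True
    return _RhoScan(rho=float(rhos[i]), max_error=float(maxerrs[i]),
                    errors=errs[i], volumes=vols[i],
                    stop=bool(maxerrs[i] < config.delta), refined=refined)


def update_centre(centre, errors, geometry: RegionGeometry) -> np.ndarray:
    """Step 2: displace the centre by the net error-scaled centroid vector."""
    m = np.asarray(centre, dtype=float)
    shift = np.zeros(2)
    for lab in LABEL_ORDER:
        e = float(errors[int(lab) - 1])
        if e == 0.0:
            continue
        c = geometry.centroids[lab]
        if c is None:
            warnings.warn(f"region {lab.name} is empty but has error {e:+.4f}; "
                          "its term is skipped", stacklevel=2)
            continue
        d = c - m
        norm = float(np.hypot(*d))
        if norm == 0.0:
            continue
        shift += e * d / norm
    return m + shift


def fit(target, pmap: SpikingPatternMap,
        config: FitConfig = FitConfig(),
        _integrator: _MapIntegrator | None = None,
        _geometry: RegionGeometry | None = None) -> FitResult:
    """Run the two-step fit with sigma fixed at ``config.sigma``.

    Deterministic for fixed inputs.  Non-convergence is reported through
    ``status`` and the per-iteration ``history``, not as an exception.
    """
    t = _target_values(target)
    integ = _integrator or _MapIntegrator(pmap, config.integration_step)
    geom = _geometry or region_geometry(pmap)
    g = pmap.grid
    if config.initial_centre is not None:
        centre = np.asarray(config.initial_centre, dtype=float)
    else:
        centre = np.array([(g.g_lt_min + g.g_lt_max) / 2.0,
                           (g.g_A_min + g.g_A_max) / 2.0])
    rho = 0.0
    history: list[dict] = []
    status = "max_iterations"
    scan = None
    k = 0
    finalize = False
    prev_centre = None
    for k in range(config.max_iterations):
        scan = optimize_rho(centre, config.sigma, t, integ, config, incumbent=rho)
        rho = scan.rho
        history.append({"iteration": k, "centre": centre.copy(), "rho": rho,
                        "max_error": scan.max_error, "errors": scan.errors.copy()})
        if scan.stop:
            status = "converged_error"
            break
        if finalize:
            status = "converged_centre"
            break
        new_centre = update_centre(centre, scan.errors, geom)
        displacement = float(np.hypot(*(new_centre - centre)))
        # a fixed point or a 2-cycle of the centre dynamics both mean the
        # iteration has stopped making progress
        cycled = (prev_centre is not None
                  and float(np.hypot(*(new_centre - prev_centre))) < config.convergence_tol)
        prev_centre = centre
        centre = new_centre
        if displacement < config.convergence_tol or cycled:
            finalize = True      # one last rho scan at the settled centre
    fitted = ProportionVector(values=scan.volumes.copy(),
                              coverage=float(scan.volumes.sum()))
    return FitResult(mu_Klt=float(centre[0]), mu_KA=float(centre[1]), rho=rho,
                     sigma_Klt=config.sigma[0], sigma_KA=config.sigma[1],
                     max_error=scan.max_error, fitted=fitted,
                     iterations=k + 1, status=status, history=history)


def _fit_batch_sigma(t: np.ndarray, pmap: SpikingPatternMap, config: FitConfig,
                     sigma_pairs: np.ndarray,
                     integ: _MapIntegrator, geom: RegionGeometry) -> dict:
    """Run the two-step fit for every sigma pair simultaneously.

    Functionally identical to calling :func:`fit` once per pair (the
    per-pair iterates coincide); batching only shares the integration
    kernel across pairs.  Returns per-pair final state arrays.
    """
    m = len(sigma_pairs)
    g = pmap.grid
    if config.initial_centre is not None:
        c0 = np.asarray(config.initial_centre, dtype=float)
    else:
        c0 = np.array([(g.g_lt_min + g.g_lt_max) / 2.0,
                       (g.g_A_min + g.g_A_max) / 2.0])
    centres = np.tile(c0, (m, 1))
    prev_centres = np.full((m, 2), np.inf)   # centre two iterations back
    rho = np.zeros(m)
    maxerr = np.full(m, np.inf)
    errors = np.zeros((m, 5))
    vols = np.zeros((m, 5))
    iters = np.zeros(m, dtype=int)
    status = np.full(m, "max_iterations", dtype=object)
    active = np.ones(m, dtype=bool)
    finalize = np.zeros(m, dtype=bool)

    rhos_c = _rho_grid(*config.rho_coarse)
    rhos_f = _rho_grid(*config.rho_fine)
    nc, nf = len(rhos_c), len(rhos_f)

    # region centroids as arrays for the vectorized step-2 update
    centroids = np.full((5, 2), np.nan)
    has_region = np.zeros(5, dtype=bool)
    for lab in LABEL_ORDER:
        c = geom.centroids[lab]
        if c is not None:
            centroids[int(lab) - 1] = c
            has_region[int(lab) - 1] = True

    def scan_rows(idx: np.ndarray, rhos: np.ndarray) -> tuple[np.ndarray, ...]:
        """Rho scan for each pair in ``idx``; returns best (rho, maxerr, vols)."""
        v = np.empty((idx.size, len(rhos), 5))
        for a, pair in enumerate(idx):
            v[a] = integ.scan(centres[pair], sigma_pairs[pair], rhos)
        me = np.abs(t[None, None, :] - v).max(axis=2)
        i = _best_rho_rows(rhos, me, rho[idx])
        rows = np.arange(idx.size)
        return rhos[i], me[rows, i], v[rows, i]

    for k in range(config.max_iterations):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        best_rho, best_me, best_v = scan_rows(idx, rhos_c)
        needs_fine = (best_me >= config.delta) & (best_me < config.epsilon)
        if needs_fine.any():
            f_rho, f_me, f_v = scan_rows(idx[needs_fine], rhos_f)
            best_rho[needs_fine] = f_rho
            best_me[needs_fine] = f_me
            best_v[needs_fine] = f_v
        rho[idx] = best_rho
        maxerr[idx] = best_me
        vols[idx] = best_v
        errors[idx] = t[None, :] - best_v
        iters[idx] = k + 1

        done_err = best_me < config.delta
        done_centre = finalize[idx] & ~done_err
        status[idx[done_err]] = "converged_error"
        status[idx[done_centre]] = "converged_centre"
        active[idx[done_err | done_centre]] = False

        move = idx[~(done_err | done_centre)]
        if move.size:
            d = centroids[None, :, :] - centres[move, None, :]      # (m, 5, 2)
            norm = np.linalg.norm(d, axis=2)                        # (m, 5)
            ok = has_region[None, :] & (norm > 0) & (errors[move] != 0)
            scale = np.where(ok, errors[move] / np.where(norm == 0, 1.0, norm), 0.0)
            shift = np.einsum("mi,mik->mk", scale, d)
            new_c = centres[move] + shift
            cycled = np.linalg.norm(new_c - prev_centres[move], axis=1) < config.convergence_tol
            prev_centres[move] = centres[move]
            centres[move] = new_c
            finalize[move] |= cycled | (np.linalg.norm(shift, axis=1) < config.convergence_tol)
    return {"centres": centres, "rho": rho, "max_error": maxerr,
            "errors": errors, "volumes": vols, "iterations": iters,
            "status": status}


def fit_with_sigma_search(target, pmap: SpikingPatternMap,
                          config: FitConfig = FitConfig()) -> FitResult:
    """Re-run the two-step fit over the sigma grid and keep the best pair.

    The winning pair is the one with the lowest final MaxError (ties go
    to the first pair in row-major grid order, which is deterministic
    and independent of evaluation order).  The full per-sigma MaxError
    surface is attached to the result.
    """
    t = _target_values(target)
    integ = _MapIntegrator(pmap, config.integration_step)
    geom = region_geometry(pmap)
    lo, hi, step = config.sigma_grid
    sig_vals = np.round(lo + step * np.arange(int(round((hi - lo) / step)) + 1), 9)
    SX, SY = np.meshgrid(sig_vals, sig_vals, indexing="ij")
    pairs = np.column_stack([SX.ravel(), SY.ravel()])

    batch = _fit_batch_sigma(t, pmap, config, pairs, integ, geom)
    surface = batch["max_error"].reshape(len(sig_vals), len(sig_vals))
    best = int(np.argmin(batch["max_error"]))

    sx, sy = pairs[best]
    result = fit(t, pmap, replace(config, sigma=(float(sx), float(sy))),
                 _integrator=integ, _geometry=geom)
    result.sigma_error_surface = surface
    return result
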