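"""2-D spatial model: reaction kinetics + diffusion + flux-limited chemotaxis.

Space is a rectangular cell-centered grid (optionally restricted to a
binary mask of active cells) with no-flux boundaries everywhere, so
every transport operator conserves mass on the grid.  Time stepping is
IMEX operator splitting: reactions and upwinded chemotaxis are advanced
explicitly (Heun), diffusion of the four mobile species implicitly
(backward Euler with prefactorized sparse solves).  Non-negativity is
preserved by automatic step halving, never by clamping.

The diffusing species are intraneural amyloid, extraneural amyloid,
tau and microglia; neurons and astrocytes are immobile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .inflammation import InflammationField
from .kinetics import STATE_VARS, TissueState, nft_from_tau, reaction_rhs
from .params import HealthReference, ModelParams

__all__ = [
    "Grid2D",
    "FieldSnapshot",
    "laplacian_noflux",
    "chemotaxis_divergence",
    "integrate_pde",
    "spatial_average",
]

logger = logging.getLogger(__name__)

#: species advanced by the implicit diffusion sweep, with their diffusivity name
_DIFFUSING = {"abi": "D_abi", "abo": "D_abo", "tau": "D_tau", "M": "D_M"}


@dataclass(frozen=True)
class Grid2D:
    """Cell-centered rectangular grid, optionally masked.

    ``h`` is the cell size in cm (the default domain is the unit square
    at 50x50 cells).  ``mask`` marks active cells; inactive cells take
    no part in dynamics or averages, and mask edges behave exactly like
    the outer boundary (reflecting, zero normal flux).
    """

    n_x: int = 50
    n_y: int = 50
    h: float = 0.02
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise ValueError("grid must be at least 2x2")
        if self.h <= 0:
            raise ValueError("cell size h must be positive")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (self.n_y, self.n_x):
                raise ValueError(
                    f"mask shape {m.shape} does not match grid ({self.n_y}, {self.n_x})"
                )
            if not m.any():
                raise ValueError("mask has no active cells")
            object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    def active(self) -> np.ndarray:
        """Boolean array of active cells."""
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    def check_shape(self, arr: np.ndarray, name: str = "field") -> np.ndarray:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != self.shape:
            raise ValueError(f"{name} shape {arr.shape} does not match grid {self.shape}")
        return arr


def _laplacian_matrix(grid: Grid2D) -> sparse.csr_matrix:
    """5-point no-flux Laplacian (1/cm^2) over the flattened grid.

    Missing neighbors (outer boundary or masked-off cells) contribute
    nothing, which is the reflecting ghost-cell discretization of a
    zero-normal-derivative boundary.
    """
    ny, nx = grid.shape
    act = grid.active()
    idx = np.arange(ny * nx).reshape(ny, nx)
    rows, cols, vals = [], [], []
    for dy, dx in ((0, 1), (1, 0)):
        a = act[: ny - dy, : nx - dx] & act[dy:, dx:]
        i = idx[: ny - dy, : nx - dx][a]
        j = idx[dy:, dx:][a]
        rows.extend([i, j, i, j])
        cols.extend([j, i, i, j])
        vals.extend([np.ones_like(i, dtype=float), np.ones_like(i, dtype=float),
                     -np.ones_like(i, dtype=float), -np.ones_like(i, dtype=float)])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    L = sparse.coo_matrix((vals, (rows, cols)), shape=(ny * nx, ny * nx))
    return (L / grid.h**2).tocsr()


def laplacian_noflux(field: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Apply the no-flux 5-point Laplacian to a field (units 1/cm^2).

    The grid sum of the result vanishes identically — the discrete
    statement of mass conservation under reflecting boundaries.
    """
    f = grid.check_shape(field)
    L = _laplacian_matrix(grid)
    return (L @ f.ravel()).reshape(grid.shape)


def _face_fluxes(M, abo, delta, K_grad, grid):
    """Upwind flux-limited chemotactic fluxes on x- and y-faces."""
    h = grid.h
    act = grid.active()
    Mz = np.where(act, M, 0.0)

    # cell-centered gradient components (masked central/one-sided differences)
    def cell_grad(c, axis):
        g = np.zeros_like(c)
        cz = np.where(act, c, np.nan)
        fwd = np.diff(cz, axis=axis, append=np.nan) / h
        bwd = np.diff(cz, axis=axis, prepend=np.nan) / h
        both = np.nanmean(np.stack([fwd, bwd]), axis=0)
        g = np.where(np.isfinite(both), both, 0.0)
        return g

    gx_c = cell_grad(abo, 1)
    gy_c = cell_grad(abo, 0)

    # x-faces between (i, j) and (i, j+1)
    open_x = act[:, :-1] & act[:, 1:]
    gn_x = np.where(open_x, (abo[:, 1:] - abo[:, :-1]) / h, 0.0)
    gt_x = 0.5 * (gy_c[:, :-1] + gy_c[:, 1:])
    mag_x = np.hypot(gn_x, gt_x)
    u_x = delta * gn_x / (K_grad + mag_x)
    flux_x = np.where(u_x >= 0, u_x * Mz[:, :-1], u_x * Mz[:, 1:])
    flux_x = np.where(open_x, flux_x, 0.0)

    # y-faces between (i, j) and (i+1, j)
    open_y = act[:-1, :] & act[1:, :]
    gn_y = np.where(open_y, (abo[1:, :] - abo[:-1, :]) / h, 0.0)
    gt_y = 0.5 * (gx_c[:-1, :] + gx_c[1:, :])
    mag_y = np.hypot(gn_y, gt_y)
    u_y = delta * gn_y / (K_grad + mag_y)
    flux_y = np.where(u_y >= 0, u_y * Mz[:-1, :], u_y * Mz[1:, :])
    flux_y = np.where(open_y, flux_y, 0.0)
    return flux_x, flux_y


def chemotaxis_divergence(M, abo, delta_M_abo, K_grad_abo, grid: Grid2D) -> np.ndarray:
    """Divergence of the flux-limited chemotactic flux of microglia.

    The advective flux is ``delta * M * grad(abo) / (K_grad +
    |grad(abo)|)`` evaluated with face-centered gradients and
    first-order upwinding of M; the face speed is bounded by ``delta``
    for arbitrarily steep gradients, and no flux passes through outer or
    mask boundaries, so the grid sum of the divergence is zero.
    """
    if K_grad_abo <= 0:
        raise ValueError("gradient saturation constant K_grad_abo must be positive")
    M = grid.check_shape(M, "M")
    abo = grid.check_shape(abo, "abo")
    flux_x, flux_y = _face_fluxes(M, abo, delta_M_abo, K_grad_abo, grid)
    div = np.zeros(grid.shape)
    div[:, :-1] += flux_x / grid.h
    div[:, 1:] -= flux_x / grid.h
    div[:-1, :] += flux_y / grid.h
    div[1:, :] -= flux_y / grid.h
    return div


@dataclass
class FieldSnapshot:
    """Per-cell state at one output time, with derived tangle density."""

    t: float
    state: dict[str, np.ndarray]
    fi: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __getitem__(self, var: str) -> np.ndarray:
        if var == "fi":
            return self.fi
        return self.state[var]

    def save_csv(self, outdir: str | Path, prefix: str = "") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for var in (*STATE_VARS, "fi"):
            path = outdir / f"{prefix}{var}_t{self.t:g}.csv"
            np.savetxt(path, self[var], delimiter=",")
            written.append(path)
        return written


def spatial_average(snapshot: FieldSnapshot, grid: Grid2D) -> dict[str, float]:
    """Arithmetic mean of every variable over the active cells."""
    act = grid.active()
    if not act.any():
        raise ValueError("mask has no active cells")
    out = {}
    for var in (*STATE_VARS, "fi"):
        arr = grid.check_shape(snapshot[var], var)
        out[var] = float(arr[act].mean())
    return out


def _amplitude_grids(field: InflammationField, grid: Grid2D):
    def expand(a, name):
        if np.ndim(a) == 0:
            return np.full(grid.shape, float(a))
        return grid.check_shape(a, name)

    return expand(field.R_amp, "R amplitude"), expand(field.Rbar_amp, "Rbar amplitude")


class _DiffusionSolvers:
    """Cache of LU factorizations of (I - dt D L) keyed by (dt, D)."""

    def __init__(self, grid: Grid2D):
        self.L = _laplacian_matrix(grid).tocsc()
        self.n = self.L.shape[0]
        self.eye = sparse.identity(self.n, format="csc")
        self._cache: dict[tuple[float, float], object] = {}

    def solve(self, f: np.ndarray, dt: float, D: float) -> np.ndarray:
        if D == 0.0:
            return f
        key = (round(dt, 12), D)
        lu = self._cache.get(key)
        if lu is None:
            lu = splu((self.eye - dt * D * self.L).tocsc())
            self._cache[key] = lu
        return lu.solve(f.ravel()).reshape(f.shape)


def _explicit_rates(state, t, p, ref, R_amp, Rbar_amp, mult, factors, grid, act):
    ts = TissueState(**state)
    drug = None if factors is None else factors(t)
    rates = reaction_rhs(ts, p, ref, R_amp * mult(t), Rbar_amp * mult(t), drug=drug)
    out = {v: np.asarray(getattr(rates, v)) for v in STATE_VARS}
    if p.delta_M_abo > 0:
        out["M"] = out["M"] - chemotaxis_divergence(
            state["M"], state["abo"], p.delta_M_abo, p.K_grad_abo, grid
        )
    for v in STATE_VARS:
        out[v] = np.where(act, out[v], 0.0)
    return out


def integrate_pde(
    grid: Grid2D,
    p: ModelParams,
    ref: HealthReference,
    field: InflammationField,
    t_end: float,
    snapshot_times,
    drug=None,
    dt: float = 0.25,
    max_halvings: int = 12,
) -> list[FieldSnapshot]:
    """Integrate the spatial model from health and return snapshots.

    The initial condition is the health reference in every active cell.
    Each step advances reactions and chemotaxis with a two-stage
    explicit (Heun) update and then diffuses the mobile species with
    backward Euler, reusing LU factorizations of the constant diffusion
    operators.  The step size obeys an advective CFL bound
    (``0.5 h / delta``) and is halved automatically — with a logged
    report — whenever an explicit stage would drive a density negative;
    a non-finite state aborts with diagnostics.
    """
    snapshot_times = np.atleast_1d(np.asarray(snapshot_times, dtype=float))
    if np.any(snapshot_times <= 0) or np.any(snapshot_times > t_end):
        raise ValueError("snapshot times must lie in (0, t_end]")
    snapshot_times = np.unique(snapshot_times)
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    if p.delta_M_abo > 0:
        dt = min(dt, 0.5 * grid.h / p.delta_M_abo)

    act = grid.active()
    R_amp, Rbar_amp = _amplitude_grids(field, grid)
    R_amp = np.where(act, R_amp, 0.0)
    Rbar_amp = np.where(act, Rbar_amp, 0.0)

    def mult(t):
        return (t / field.gamma) / (field.K + t)

    factors = None if drug is None else drug.factors

    state = {
        v: np.full(grid.shape, x)
        for v, x in zip(STATE_VARS, HealthReference.as_state_vector(ref))
    }
    solvers = _DiffusionSolvers(grid)
    snapshots: list[FieldSnapshot] = []
    n_halvings = 0

    def attempt_step(state, t, step, depth):
        nonlocal n_halvings
        k1 = _explicit_rates(state, t, p, ref, R_amp, Rbar_amp, mult, factors, grid, act)
        mid = {v: state[v] + step * k1[v] for v in STATE_VARS}
        bad = any(np.any(mid[v][act] < 0) for v in STATE_VARS)
        if not bad:
            k2 = _explicit_rates(
                mid, t + step, p, ref, R_amp, Rbar_amp, mult, factors, grid, act
            )
            new = {v: state[v] + 0.5 * step * (k1[v] + k2[v]) for v in STATE_VARS}
            bad = any(np.any(new[v][act] < 0) for v in STATE_VARS)
        if bad:
            if depth >= max_halvings:
                raise RuntimeError(
                    f"step size underflow at t={t:.3f} after {max_halvings} halvings"
                )
            n_halvings += 1
            logger.warning("negative density at t=%.3f; halving step to %.3g", t, step / 2)
            half = attempt_step(state, t, step / 2, depth + 1)
            return attempt_step(half, t + step / 2, step / 2, depth + 1)
        # implicit diffusion sweep
        for v, Dname in _DIFFUSING.items():
            new[v] = solvers.solve(new[v], step, getattr(p, Dname))
        for v in STATE_VARS:
            if not np.all(np.isfinite(new[v][act])):
                raise RuntimeError(
                    f"non-finite {v} at t={t + step:.3f}; the run diverged "
                    "(check parameters and step size)"
                )
        return new

    t = 0.0
    for t_snap in snapshot_times:
        while t < t_snap - 1e-9:
            step = min(dt, t_snap - t)
            state = attempt_step(state, t, step, 0)
            t += step
        snapshots.append(
            FieldSnapshot(
                t=t_snap,
                state={v: state[v].copy() for v in STATE_VARS},
                fi=nft_from_tau(state["tau"], ref.tau_ss),
            )
        )
    if n_halvings:
        logger.info("completed with %d step halvings", n_halvings)
    return snapshots
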