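"""Well-mixed (spatially uniform) integration of the network.

Integrates the reaction system from the healthy equilibrium under a
uniform, ramped inflammation field with a stiff-capable adaptive solver,
and provides threshold-crossing detection on a fixed sampling cadence
(the longitudinal "PET scan every 100 days" reading of a trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .inflammation import InflammationField
from .kinetics import STATE_VARS, TissueState, nft_from_tau, reaction_rhs
from .params import HealthReference, ModelParams

__all__ = ["Trajectory", "integrate_ode", "detect_crossing"]

#: relative tolerance for the stiff integrator
DEFAULT_RTOL = 1e-9


@dataclass
class Trajectory:
    """Sampled solution of the well-mixed system.

    ``states`` has shape (n_samples, 6) in the order (abi, abo, tau, M,
    A, N); tangles are derived on access.
    """

    t: np.ndarray
    states: np.ndarray
    ref: HealthReference

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def __getitem__(self, var: str) -> np.ndarray:
        if var == "fi":
            return nft_from_tau(self.states[:, 2], self.ref.tau_ss)
        try:
            return self.states[:, STATE_VARS.index(var)]
        except ValueError:
            raise KeyError(
                f"unknown variable {var!r}; choose from {STATE_VARS + ('fi',)}"
            ) from None

    def state_at(self, t: float) -> TissueState:
        i = int(np.argmin(np.abs(self.t - t)))
        if abs(self.t[i] - t) > 1e-6 * max(1.0, abs(t)):
            raise ValueError(f"time {t} is not a sample time")
        return TissueState.from_vector(self.states[i])

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy (time, variable, value) table."""
        rows = []
        for var in STATE_VARS + ("fi",):
            rows.append(
                pd.DataFrame({"time": self.t, "variable": var, "value": self[var]})
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rhs_vector(t, y, p, ref, field, drug_factors):
    R_val, Rbar_val = field.at(t)
    drug = None if drug_factors is None else drug_factors(t)
    state = TissueState.from_vector(y)
    return reaction_rhs(state, p, ref, R_val, Rbar_val, drug=drug).as_vector()


def integrate_ode(
    p: ModelParams,
    ref: HealthReference,
    field: InflammationField,
    t_end: float,
    sample_interval: float = 10.0,
    drug=None,
    rtol: float = DEFAULT_RTOL,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the well-mixed system from health over ``[0, t_end]``.

    Parameters
    ----------
    field
        Spatially uniform inflammation field (scalar amplitudes); a map
        field is rejected — use the PDE engine for those.
    drug
        Optional :class:`~abtau.treatment.DrugRegimen`.  The integration
        is split at the treatment start so the solver never steps across
        the kink in the drug factors.
    rtol
        Relative tolerance; absolute tolerances are scaled per variable
        from the health reference, which spans eight orders of
        magnitude across the state.
    """
    if not field.is_uniform:
        raise ValueError(
            "integrate_ode requires a spatially uniform field; "
            "use abtau.pde.integrate_pde for amplitude maps"
        )
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if sample_interval <= 0 or sample_interval > t_end:
        raise ValueError("sample_interval must lie in (0, t_end]")

    # sample at exact multiples of the interval (plus t_end), so cadence
    # grids and checkpoint times are hit exactly
    t_eval = np.arange(0.0, t_end + 0.5 * sample_interval, sample_interval)
    t_eval = t_eval[t_eval <= t_end + 1e-9]
    if t_eval[-1] < t_end - 1e-9:
        t_eval = np.append(t_eval, t_end)
    atol = rtol * 1e-3 * ref.as_state_vector()
    if y0 is None:
        y0 = ref.as_state_vector()

    factors = None
    breakpoints = [0.0, t_end]
    if drug is not None:
        factors = drug.factors
        if 0.0 < drug.t0 < t_end:
            breakpoints = [0.0, drug.t0, t_end]

    ts, ys = [], []
    y_start = np.asarray(y0, dtype=float)
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        chunk = t_eval[(t_eval >= a) & (t_eval <= b)]
        eval_pts = np.unique(np.concatenate([[a], chunk, [b]]))
        sol = solve_ivp(
            _rhs_vector,
            (a, b),
            y_start,
            method="LSODA",
            t_eval=eval_pts,
            rtol=rtol,
            atol=atol,
            args=(p, ref, field, factors),
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        keep = np.isin(sol.t, chunk)
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep].T)
        y_start = sol.y[:, -1]

    t = np.concatenate(ts)
    states = np.vstack(ys)
    t, idx = np.unique(t, return_index=True)
    return Trajectory(t=t, states=states[idx], ref=ref)


def detect_crossing(
    traj: Trajectory, variable: str, threshold: float, cadence: float = 100.0
) -> float | None:
    """First cadence-grid time at which a variable reaches a threshold.

    The trajectory is read only at multiples of ``cadence`` (the
    longitudinal imaging schedule), so crossing times are reported on
    that grid rather than by continuous interpolation.  Returns ``None``
    if the threshold is never reached at a scheduled time.
    """
    values = traj[variable]  # raises KeyError for unknown names
    if cadence <= 0:
        raise ValueError("cadence must be positive")
    n = int(np.floor(traj.t[-1] / cadence + 1e-9))
    grid = np.arange(0, n + 1) * cadence
    # the cadence grid must be a subset of the sample times
    idx = np.searchsorted(traj.t, grid)
    idx = np.clip(idx, 0, len(traj.t) - 1)
    if not np.allclose(traj.t[idx], grid, rtol=0, atol=1e-6):
        raise ValueError("cadence does not divide the trajectory sampling grid")
    on_grid = values[idx]
    hits = np.nonzero(on_grid >= threshold)[0]
    return float(grid[hits[0]]) if hits.size else None
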