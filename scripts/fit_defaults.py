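"""One-off calibration of the default rate constants.

The clinical anchor values fix the health reference densities, the
production-rate identities of the health fixed point, and the disease
endpoint values of the well-mixed scenarios, but not the individual
clearance, saturation and coupling constants.  This script fits those constants
once, by weighted least squares, against:

* the 3650-day well-mixed endpoints of the three published disease
  scenarios (baseline and the two biased-inflammation variants),
* the zero-inflammation run (which must hold the health state),
* the slow-ramp uniform trajectory checkpoints at 2000/2300/2500/3600 d,
* the slow-ramp mixture time series (the pixel-class-weighted
  combination 0.40/0.40/0.15/0.05 of per-class well-mixed runs, which
  is the zero-diffusion limit of the published domain averages),
* a local-stability margin of the health equilibrium (largest real part
  of the one-sided Jacobian must be negative, otherwise round-off
  grows and the uninflamed brain would not stay healthy).

The fitted values are frozen into abtau.params.ModelParams defaults.
Run from the repository root:

    python scripts/fit_defaults.py [--quick]
"""

from __future__ import annotations

import argparse
import time

import numpy as np
from scipy.optimize import least_squares

from abtau import (
    HealthReference,
    InflammationField,
    ModelParams,
    calibrate_health_fixed_point,
    integrate_ode,
)
from abtau.kinetics import TissueState, reaction_rhs

REF = HealthReference()
R_STAR = 1.85e-6
RBAR_STAR = 4.13e-10

# published 3650-day endpoints (abi, abo, tau, M, A, N) per scenario
ENDPOINTS = {
    (1.0, 1.0): [1.97e-6, 6.64e-6, 4.81e-10, 15.66e-3, 3.99e-2, 4.01e-2],
    (1.5, 0.5): [2.46e-6, 7.90e-6, 3.63e-10, 14.77e-3, 3.87e-2, 4.10e-2],
    (0.5, 1.5): [1.49e-6, 5.19e-6, 5.98e-10, 15.63e-3, 3.98e-2, 4.00e-2],
}

# slow-ramp uniform (non-biased) checkpoints: t -> (abo, tau)
CHECKPOINTS = {
    2000.0: (6.42e-6, 4.66e-10),
    2300.0: (6.60e-6, 4.81e-10),
    2500.0: (6.70e-6, 4.90e-10),
    3600.0: (7.10e-6, 5.24e-10),
}

# published slow-ramp domain-average series (every 100 d from 100 to 3600)
SERIES_TIMES = np.arange(100.0, 3601.0, 100.0)
SERIES_ABO = np.array(
    [2.15, 2.83, 3.33, 3.73, 4.06, 4.35, 4.59, 4.80, 4.99, 5.16, 5.30, 5.44,
     5.56, 5.67, 5.77, 5.87, 5.95, 6.03, 6.10, 6.17, 6.23, 6.29, 6.35, 6.40,
     6.45, 6.49, 6.53, 6.57, 6.61, 6.65, 6.68, 6.71, 6.74, 6.77, 6.80, 6.83]
) * 1e-6
SERIES_TAU = np.array(
    [1.79, 2.15, 2.45, 2.71, 2.93, 3.13, 3.30, 3.46, 3.59, 3.72, 3.83, 3.93,
     4.02, 4.11, 4.19, 4.26, 4.33, 4.39, 4.45, 4.50, 4.55, 4.60, 4.64, 4.68,
     4.72, 4.76, 4.80, 4.83, 4.86, 4.89, 4.92, 4.95, 4.97, 5.00, 5.02, 5.04]
) * 1e-10
MIX_WEIGHTS = {(1.5, 0.5): 0.40, (0.5, 1.5): 0.40, (1.0, 1.0): 0.15}
ZERO_WEIGHT = 0.05

SLOW_K, SLOW_GAMMA = 1000.0, 1.0 / 1.4

#: weight of the slow-ramp checkpoint residuals (raised by the polish pass)
CHECKPOINT_WEIGHT = 2.0

#: when True (the polish pass), enforce one-sided constraints: the
#: slow-ramp run must reach the AD-average thresholds at the 2500-day
#: visit but not at the 2400-day one, and the mixture series must stay
#: inside a safety band so the diffusive domain averages have headroom
HARD_BOUNDS = False
AD_ABO, AD_TAU = 6.70e-6, 4.90e-10


def _logit(p):
    return np.log(p / (1 - p))


def _expit(x):
    return 1 / (1 + np.exp(-x))


NAMES = [
    "d_abi", "d_tau", "lam_tau_abi", "d_M", "lam_M_abo", "K_abo", "lam_M_Fi",
    "K_Fi", "d_A", "sigma_AM", "K_M", "d_N_Fi", "d_N_abo", "d_abo_M", "d_abo",
    "rho_astro", "lam_abo_N",
]

X0 = np.array([
    np.log(1.8564), np.log(1.3805), np.log(6.69e-5), np.log(1.71e-2),
    np.log(5.8e-3), np.log(1e-6), np.log(6.3e-3), np.log(1e-10),
    np.log(2.17e-3), _logit(0.345), np.log(1.44e-2), np.log(9.74e-5),
    np.log(3.25e-5), np.log(0.5), np.log(6.95e-3), _logit(0.297), np.log(264.0),
])


def params_from_x(x: np.ndarray) -> ModelParams:
    v = dict(zip(NAMES, x))
    d_A = np.exp(v["d_A"])
    K_M = np.exp(v["K_M"])
    sigma = _expit(v["sigma_AM"])           # fraction of d_A balanced by activation
    m0 = REF.M0 / (K_M + REF.M0)
    lam_A_M = sigma * d_A / m0
    d_abo_M = np.exp(v["d_abo_M"])
    d_abo = np.exp(v["d_abo"])
    rho = _expit(v["rho_astro"])            # astro production / gross clearance
    lam_abo_A = rho * (d_abo_M * REF.M0 + d_abo) / REF.A0
    p = ModelParams(
        d_abi=np.exp(v["d_abi"]),
        d_tau=np.exp(v["d_tau"]),
        lam_tau_abi=np.exp(v["lam_tau_abi"]),
        d_M=np.exp(v["d_M"]),
        lam_M_abo=np.exp(v["lam_M_abo"]),
        K_abo=np.exp(v["K_abo"]),
        lam_M_Fi=np.exp(v["lam_M_Fi"]),
        K_Fi=np.exp(v["K_Fi"]),
        d_A=d_A,
        lam_A_M=lam_A_M,
        K_M=K_M,
        d_N_Fi=np.exp(v["d_N_Fi"]),
        d_N_abo=np.exp(v["d_N_abo"]),
        d_abo_M=d_abo_M,
        d_abo=d_abo,
        lam_abo_A=lam_abo_A,
        lam_abo_N=np.exp(v["lam_abo_N"]),
    )
    return calibrate_health_fixed_point(p, REF)


def _endpoint(p, r_mult, rbar_mult, K, gamma, t_end, rtol, times=None):
    fld = InflammationField.uniform(r_mult * R_STAR, rbar_mult * RBAR_STAR, K, gamma)
    traj = integrate_ode(p, REF, fld, t_end, sample_interval=100.0, rtol=rtol)
    if times is None:
        return traj.states[-1]
    idx = np.searchsorted(traj.t, times)
    return traj.states[idx]


def health_jacobian_max_eig(p: ModelParams) -> float:
    """Largest real eigenvalue of the one-sided Jacobian at health.

    The neuron direction is excluded: neurons are neutrally stable at
    health by construction (no death without protein excess) and that
    zero mode does not amplify perturbations of the other variables.
    """
    y0 = REF.as_state_vector()

    def rhs(y):
        s = TissueState.from_vector(y)
        return reaction_rhs(s, p, REF, 0.0, 0.0).as_vector()

    J = np.zeros((6, 6))
    for j in range(6):
        h = 1e-7 * y0[j]
        y = y0.copy()
        y[j] += h          # forward step: activates the positive-part terms
        J[:, j] = (rhs(y) - rhs(y0)) / h
    J5 = J[:5, :5]  # drop the neuron row/column (neutral mode)
    return float(np.max(np.real(np.linalg.eigvals(J5))))


_BEST = {"cost": np.inf, "x": None}


def residuals(x: np.ndarray, rtol: float = 1e-7) -> np.ndarray:
    out = _residuals_impl(x, rtol)
    cost = 0.5 * float(np.sum(out**2))
    if cost < _BEST["cost"]:
        _BEST["cost"] = cost
        _BEST["x"] = x.copy()
        np.save("scratch/fit_best_x.npy", x)
    return out


def _residuals_impl(x: np.ndarray, rtol: float = 1e-7) -> np.ndarray:
    try:
        p = params_from_x(x)
    except (ValueError, OverflowError):
        return np.full(320, 10.0)
    res = []
    try:
        # zero-inflammation run must hold health
        end0 = _endpoint(p, 0.0, 0.0, 100.0, 1.0, 3650.0, rtol)
        res.extend(((end0 - REF.as_state_vector()) / REF.as_state_vector()) * 2.0)
        # fast-ramp disease scenarios
        for (rm, rb), target in ENDPOINTS.items():
            end = _endpoint(p, rm, rb, 100.0, 1.0, 3650.0, rtol)
            res.extend((end - np.asarray(target)) / np.asarray(target) * 3.0)
        # slow-ramp class runs reused for checkpoints and mixture series
        times = np.unique(np.concatenate([SERIES_TIMES, list(CHECKPOINTS)]))
        cls_states = {
            mults: _endpoint(p, *mults, SLOW_K, SLOW_GAMMA, 3650.0, rtol, times)
            for mults in [(1.0, 1.0), (1.5, 0.5), (0.5, 1.5)]
        }
        uni = cls_states[(1.0, 1.0)]
        for t, (abo_t, tau_t) in CHECKPOINTS.items():
            i = int(np.searchsorted(times, t))
            res.append((uni[i, 1] - abo_t) / abo_t * CHECKPOINT_WEIGHT)
            res.append((uni[i, 2] - tau_t) / tau_t * CHECKPOINT_WEIGHT)
        t2_idx = np.searchsorted(times, SERIES_TIMES)
        mix = sum(w * cls_states[m][t2_idx] for m, w in MIX_WEIGHTS.items())
        mix_abo = mix[:, 1] + ZERO_WEIGHT * REF.abo_ss
        mix_tau = mix[:, 2] + ZERO_WEIGHT * REF.tau_ss
        res.extend((mix_abo - SERIES_ABO) / SERIES_ABO * 0.5)
        res.extend((mix_tau - SERIES_TAU) / SERIES_TAU * 0.5)
        if HARD_BOUNDS:
            i24 = int(np.searchsorted(times, 2400.0))
            i25 = int(np.searchsorted(times, 2500.0))
            # cross at the 2500-day visit, not the 2400-day one
            res.append(60.0 * max(0.0, (1.001 * AD_ABO - uni[i25, 1]) / AD_ABO))
            res.append(60.0 * max(0.0, (1.001 * AD_TAU - uni[i25, 2]) / AD_TAU))
            res.append(60.0 * max(0.0, (uni[i24, 1] - 0.999 * AD_ABO) / AD_ABO))
            res.append(60.0 * max(0.0, (uni[i24, 2] - 0.999 * AD_TAU) / AD_TAU))
            # keep the mixture series inside asymmetric bands chosen so
            # the diffusive domain averages (which sit up to ~0.3% below
            # the mixture) stay within 3% of the printed values
            for series, target, lo, hi in (
                (mix_abo, SERIES_ABO, -0.020, 0.030),
                (mix_tau, SERIES_TAU, -0.025, 0.025),
            ):
                dev = (series - target) / target
                res.extend(25.0 * np.maximum(0.0, dev - hi))
                res.extend(25.0 * np.maximum(0.0, lo - dev))
    except RuntimeError:
        return np.full(320, 10.0)
    # stability margin of the health equilibrium
    lam = health_jacobian_max_eig(p)
    res.append(1e3 * max(0.0, lam + 1e-4))
    out = np.asarray(res, dtype=float)
    return np.pad(out, (0, 320 - out.size)) if out.size < 320 else out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true", help="loose tolerances, few iters")
    args = ap.parse_args()
    rtol = 1e-6 if args.quick else 1e-8
    t0 = time.time()
    sol = least_squares(
        residuals,
        X0,
        kwargs={"rtol": rtol},
        method="trf",
        x_scale=1.0,
        diff_step=3e-3,
        ftol=1e-5,
        xtol=1e-12,
        max_nfev=60 if args.quick else 260,
        verbose=2,
    )
    p = params_from_x(sol.x)
    print(f"\nfit finished in {time.time() - t0:.0f} s, cost {sol.cost:.4e}")
    print(f"health Jacobian max eig: {health_jacobian_max_eig(p):+.3e} /d\n")
    for name in [
        "lam_abi", "d_abi", "lam_abo", "lam_abo_N", "d_abo_M", "d_abo",
        "lam_abo_A", "lam_tau", "lam_tau_abi", "d_tau", "lam_M", "lam_M_abo",
        "K_abo", "lam_M_Fi", "K_Fi", "d_M", "lam_A", "lam_A_M", "K_M", "d_A",
        "d_N_Fi", "d_N_abo",
    ]:
        print(f"    {name}: float = {getattr(p, name):.6g}")
    # report achieved endpoints
    print("\nscenario endpoints (model vs published):")
    for (rm, rb), target in ENDPOINTS.items():
        end = _endpoint(p, rm, rb, 100.0, 1.0, 3650.0, 1e-9)
        rel = (end - np.asarray(target)) / np.asarray(target)
        print(f"  R={rm}R*, Rbar={rb}Rbar*:")
        for n, e, t, r in zip(("abi", "abo", "tau", "M", "A", "N"), end, target, rel):
            print(f"    {n:>3}: {e:.3e} vs {t:.3e}  ({100 * r:+.2f}%)")


if __name__ == "__main__":
    main()
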