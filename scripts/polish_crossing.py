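"""Refinement pass of the default-constant calibration.

The weighted least-squares fit (scripts/fit_defaults.py) matches every
published anchor to well under 1%, but three of the targets are
*edges*, not values, and a symmetric fit can land a fraction of a
percent on the wrong side of them:

* the untreated slow-ramp run must reach the AD-average thresholds at
  the 2500-day imaging visit (not 2400, not 2600);
* the longitudinal domain-average amyloid series must stay within 3%
  of the printed values at *every* visit, including the steep 100-day
  point, after accounting for the small positive offset diffusion adds
  to the domain average relative to the pixel-class mixture.

Rather than re-opening all seventeen constants, this pass adjusts two
interpretable knobs on top of the fit optimum and scans them:

* ``k`` — a common factor on the extraneural-amyloid couplings
  (d_abo_M, d_abo, lam_abo_A, lam_abo_N).  Because the health
  calibration rescales lam_abo along, this speeds the amyloid
  equation uniformly without moving its quasi-steady values: it lifts
  the lagging 100-day point much more than the already-high 200-day
  one.
* ``s`` — a small extra factor on the necrosis-leak coupling
  lam_abo_N alone, which lifts the late-time amyloid level (the
  2500-day crossing edge) almost uniformly.

The scan picks the smallest (k, s) meeting all edges with margin while
keeping the endpoint tables inside their bands and the health
equilibrium stable; the result is frozen into abtau.params.ModelParams.

Run from the repository root:

    PYTHONPATH=scripts python scripts/polish_crossing.py
"""

from __future__ import annotations

import itertools

import numpy as np

import fit_defaults as fd
from abtau import ModelParams, calibrate_health_fixed_point

#: fit_defaults optimum (before refinement)
BASE = dict(
    d_abi=1.84345, lam_abo_N=670.409, d_abo_M=1.85066, d_abo=0.0332356,
    lam_abo_A=0.919778, lam_tau_abi=7.70798e-05, d_tau=1.38672,
    lam_M_abo=0.0301916, K_abo=1.2203e-06, lam_M_Fi=0.075151,
    K_Fi=3.36428e-11, d_M=0.166846, lam_A_M=0.00661158, K_M=0.0161427,
    d_A=0.00640476, d_N_Fi=9.4864e-05, d_N_abo=3.76237e-05,
)

#: measured offset of the 50x50 diffusive domain average above the
#: pixel-class mixture at the first two visits (see decomposition in
#: the methods note: diffusion-driven, chemotaxis slightly negative)
PDE_OFFSET_100, PDE_OFFSET_200 = 0.0005, 0.0021


def candidate(k: float, s: float) -> ModelParams:
    b = dict(BASE)
    for name in ("d_abo_M", "d_abo", "lam_abo_A", "lam_abo_N"):
        b[name] *= k
    b["lam_abo_N"] *= s
    return calibrate_health_fixed_point(ModelParams(**b), fd.REF)


def feasible(p: ModelParams) -> tuple[bool, str]:
    if fd.health_jacobian_max_eig(p) >= -2e-5:
        return False, "health equilibrium unstable or marginal"
    times = fd.SERIES_TIMES
    cls = {
        m: fd._endpoint(p, *m, fd.SLOW_K, fd.SLOW_GAMMA, 3650.0, 1e-9, times)
        for m in [(1.0, 1.0), (1.5, 0.5), (0.5, 1.5)]
    }
    mix_abo = sum(w * cls[m][:, 1] for m, w in fd.MIX_WEIGHTS.items())
    mix_abo = mix_abo + fd.ZERO_WEIGHT * fd.REF.abo_ss
    dev = (mix_abo - fd.SERIES_ABO) / fd.SERIES_ABO
    # require a tenth of a percent of margin inside the 3% band
    if dev[0] + PDE_OFFSET_100 < -0.029:
        return False, f"100-day average too low ({100 * dev[0]:+.2f}%)"
    if dev[1] + PDE_OFFSET_200 > 0.0295:
        return False, f"200-day average too high ({100 * dev[1]:+.2f}%)"
    uni = cls[(1.0, 1.0)]
    i24, i25 = np.searchsorted(times, [2400.0, 2500.0])
    if uni[i25, 1] < fd.AD_ABO or uni[i25, 2] < fd.AD_TAU:
        return False, "2500-day visit below threshold"
    if uni[i24, 1] >= fd.AD_ABO or uni[i24, 2] >= fd.AD_TAU:
        return False, "2400-day visit already above threshold"
    for (rm, rb), target in fd.ENDPOINTS.items():
        end = fd._endpoint(p, rm, rb, 100.0, 1.0, 3650.0, 1e-9)
        if np.max(np.abs((end - np.asarray(target)) / np.asarray(target))) > 0.015:
            return False, f"endpoint band exceeded at R={rm}, Rbar={rb}"
    return True, "ok"


def main() -> None:
    for k, s in itertools.product(
        (1.0, 1.01, 1.02, 1.03, 1.04), (1.0, 1.0022, 1.005)
    ):
        p = candidate(k, s)
        ok, why = feasible(p)
        print(f"k={k:5.3f} s={s:6.4f}: {'FEASIBLE' if ok else why}")
        if ok:
            print("\nselected constants:")
            for name in sorted(BASE):
                print(f"    {name}: float = {getattr(p, name):.6g}")
            for name in ("lam_abi", "lam_abo", "lam_tau", "lam_M", "lam_A"):
                print(f"    {name}: float = {getattr(p, name):.6g}")
            return
    print("no feasible candidate in the scanned range")


if __name__ == "__main__":
    main()
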