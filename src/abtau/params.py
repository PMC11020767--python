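"""Model constants, clinical unit conversions, and health fixed-point calibration.

All densities are in g/cm^3, all rates in 1/day (or g/(cm^3 day) for
zeroth-order production), diffusivities in cm^2/day.  Clinical
concentrations (ng/g of gray matter, pg/ml of fluid) are converted to
tissue densities at the package boundary with the convention that
tissue density is 1 g/cm^3 and 1 ml = 1 cm^3.

The production rates of every species are not free: they are pinned by
the requirement that the healthy brain is an exact equilibrium of the
reaction network when both inflammation drivers vanish.
:func:`calibrate_health_fixed_point` enforces that constraint.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

__all__ = [
    "HealthReference",
    "ModelParams",
    "CalibrationTargets",
    "default_params",
    "clinical_unit_to_density",
    "neuron_death_rate",
    "calibrate_health_fixed_point",
    "load_param_table",
    "health_residual",
]

#: accepted clinical units and their multiplicative conversion to g/cm^3
_UNIT_FACTORS = {
    "ng/g": 1e-9,     # per gram of tissue at 1 g/cm^3
    "pg/ml": 1e-12,   # per millilitre = per cm^3
    "g/cm3": 1.0,
    "g/cm^3": 1.0,
    "g/cm³": 1.0,
}


def clinical_unit_to_density(value: float, unit: str) -> float:
    """Convert a clinical concentration to a tissue density in g/cm^3.

    Parameters
    ----------
    value
        Non-negative concentration in the given unit.
    unit
        One of ``ng/g``, ``pg/ml`` or ``g/cm3``.

    Examples
    --------
    >>> clinical_unit_to_density(1000, "ng/g")
    1e-06
    >>> clinical_unit_to_density(137, "pg/ml")
    1.37e-10
    """
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    try:
        factor = _UNIT_FACTORS[unit]
    except KeyError:
        accepted = ", ".join(sorted(set(_UNIT_FACTORS) - {"g/cm^3", "g/cm³"}))
        raise ValueError(f"unknown unit {unit!r}; accepted units: {accepted}") from None
    return value * factor


def neuron_death_rate(survival_fraction: float, horizon: float) -> float:
    """Constant per-day neuron death rate implied by a survival fraction.

    A fraction ``f`` of neurons surviving after ``horizon`` days under a
    constant exponential death rate ``d`` satisfies ``f = exp(-d * horizon)``,
    so ``d = -ln(f)/horizon``.  Scaling the rate by ``c`` yields survival
    ``f**c`` at the same horizon, which is how death rates for shorter or
    longer life expectancies are derived from the 10-year reference.
    """
    if not 0.0 < survival_fraction < 1.0:
        raise ValueError(
            f"survival fraction must lie strictly in (0, 1), got {survival_fraction}"
        )
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    return -math.log(survival_fraction) / horizon


@dataclass(frozen=True)
class HealthReference:
    """Healthy-brain densities: the equilibrium of the uninflamed network.

    Neurons: ~100 billion cells of ~1e-9 g in a ~1500 cm^3 brain; the
    reference density used throughout is the rounded clinical value
    6.00e-2 g/cm^3.  Microglia are ~6% of all (~200 billion) brain
    cells, astrocytes four times as many as microglia.  The protein
    reference values are clinical gray-matter/fluid measurements
    converted with :func:`clinical_unit_to_density`.
    """

    N0: float = 6.00e-2
    M0: float = 7.20e-3
    A0: float = 2.88e-2
    abi_ss: float = 1.00e-6
    abo_ss: float = 1.00e-6
    tau_ss: float = 1.37e-10

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"health reference {f.name} must be positive, got {v}")

    def as_state_vector(self) -> np.ndarray:
        """Health state in solver order (abi, abo, tau, M, A, N)."""
        return np.array(
            [self.abi_ss, self.abo_ss, self.tau_ss, self.M0, self.A0, self.N0]
        )


@dataclass(frozen=True)
class CalibrationTargets:
    """Clinical endpoint values and ranges that anchor the disease scenario.

    ``abo_ad`` and ``tau_ad`` double as the "average AD" thresholds used
    by the longitudinal crossing analysis.
    """

    abo_ad: float = 6.70e-6
    abo_ad_range: tuple[float, float] = (1.1e-6, 2.3e-5)
    tau_ad: float = 4.90e-10
    tau_ad_range: tuple[float, float] = (3.0e-10, 1.0e-9)
    M_ad: float = 15.84e-3
    M_ad_range: tuple[float, float] = (9.8e-3, 19.8e-3)
    N_ad: float = 3.96e-2
    N_ad_range: tuple[float, float] = (2.61e-2, 4.87e-2)
    horizon: float = 3650.0
    neuron_survival: float = 0.66

    def __post_init__(self) -> None:
        ref = HealthReference()
        ok = (
            self.abo_ad > ref.abo_ss
            and self.tau_ad > ref.tau_ss
            and self.M_ad > ref.M0
            and self.N_ad < ref.N0
        )
        if not ok:
            raise ValueError("AD targets must worsen relative to health")


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

# Default rate constants.  Degradation/saturation constants that are not
# fixed by the clinical anchor arithmetic were fitted once, with
# scripts/fit_defaults.py, so that the 3650-day well-mixed endpoints
# reproduce the published disease scenarios; they are frozen here.
# Production rates (lam_*) are derived from the health fixed point and
# re-derived by calibrate_health_fixed_point whenever inputs change.


@dataclass(frozen=True)
class ModelParams:
    # intraneural amyloid-beta (production / clearance)
    lam_abi: float = 1.84345e-06
    d_abi: float = 1.84345
    # extraneural amyloid-beta
    lam_abo: float = 2.04721e-08
    lam_abo_N: float = 685.322
    d_abo_M: float = 1.88767
    d_abo: float = 0.0339003
    lam_abo_A: float = 0.938174
    # tau
    lam_tau: float = 1.89981e-10
    lam_tau_abi: float = 7.70798e-05
    d_tau: float = 1.38672
    # microglia: chemotaxis, diffusion, activation, turnover
    delta_M_abo: float = 1.0e-4
    K_grad_abo: float = 1.0e-5
    D_M: float = 1.0e-6
    lam_M: float = 0.00120129
    lam_M_abo: float = 0.0301916
    K_abo: float = 1.2203e-06
    lam_M_Fi: float = 0.075151
    K_Fi: float = 3.36428e-11
    d_M: float = 0.166846
    # astrocytes
    lam_A: float = 0.000125724
    lam_A_M: float = 0.00661158
    K_M: float = 0.0161427
    d_A: float = 0.00640476
    # neuron death
    d_N_Fi: float = 9.4864e-05
    d_N_abo: float = 3.76237e-05
    # diffusivities (cm^2/day)
    D_abi: float = 1.0e-7
    D_abo: float = 1.0e-6
    D_tau: float = 1.0e-7

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


def calibrate_health_fixed_point(
    params: ModelParams, ref: HealthReference
) -> ModelParams:
    """Derive production rates so the health state is an exact equilibrium.

    With both inflammation drivers at zero, each reaction equation must
    vanish at the health reference.  That pins every zeroth-order
    production rate in terms of the clearance and saturation constants:

    * ``lam_abi = d_abi * abi_ss``
    * ``lam_tau = d_tau * tau_ss``
    * ``lam_M   = d_M * M0`` (activation terms vanish at health)
    * ``lam_A   = d_A * A0 - lam_A_M * M0/(K_M + M0) * A0``
    * ``lam_abo = (d_abo_M * M0 + d_abo) * abo_ss - lam_abo_A * A0 * abo_ss``
      (the necrosis-leak term vanishes because neurons do not die at health)

    Raises
    ------
    ValueError
        If an implied production rate is negative, i.e. the supplied
        clearance/saturation constants are mutually inconsistent.
    """
    lam_abi = params.d_abi * ref.abi_ss
    lam_tau = params.d_tau * ref.tau_ss
    lam_M = params.d_M * ref.M0
    lam_A = params.d_A * ref.A0 - params.lam_A_M * ref.M0 / (params.K_M + ref.M0) * ref.A0
    lam_abo = (
        (params.d_abo_M * ref.M0 + params.d_abo) * ref.abo_ss
        - params.lam_abo_A * ref.A0 * ref.abo_ss
    )
    if lam_A < 0:
        raise ValueError(
            "implied astrocyte production lam_A is negative "
            f"({lam_A:.3e}); reduce lam_A_M or increase d_A"
        )
    if lam_abo < 0:
        raise ValueError(
            "implied extraneural amyloid production lam_abo is negative "
            f"({lam_abo:.3e}); reduce lam_abo_A or increase clearance"
        )
    return params.replace(
        lam_abi=lam_abi, lam_tau=lam_tau, lam_M=lam_M, lam_A=lam_A, lam_abo=lam_abo
    )


def health_residual(params: ModelParams, ref: HealthReference) -> np.ndarray:
    """Reaction right-hand side at the health state with zero inflammation."""
    from .kinetics import TissueState, reaction_rhs

    state = TissueState.from_vector(ref.as_state_vector())
    rates = reaction_rhs(state, params, ref, 0.0, 0.0)
    return rates.as_vector()


def default_params(ref: HealthReference | None = None) -> ModelParams:
    """Shipped default constants, calibrated to the health fixed point."""
    return calibrate_health_fixed_point(ModelParams(), ref or HealthReference())


# ---------------------------------------------------------------------------
# Parameter table I/O
# ---------------------------------------------------------------------------

_PARAM_NAMES = {f.name for f in fields(ModelParams)}
# production rates are derived, so a table may omit them
_DERIVED = {"lam_abi", "lam_tau", "lam_M", "lam_A", "lam_abo"}

#: sentinel: start from the shipped defaults
_SHIPPED = object()


def load_param_table(
    path: str | Path,
    base: ModelParams | None = _SHIPPED,  # type: ignore[assignment]
    ref: HealthReference | None = None,
) -> ModelParams:
    """Load constants from a delimited name/value table.

    The table has one constant per line: ``name<sep>value[<sep>unit
    [<sep>note]]`` with comma, tab or whitespace separators; ``#`` starts
    a comment.  Named constants override ``base`` (the shipped defaults
    unless another parameter set, or ``None`` to require a complete
    standalone table, is given); production rates are re-derived from
    the health fixed point after the overrides are applied, and the
    residual of the calibrated set is verified to vanish.

    Raises
    ------
    ValueError
        On unknown names, malformed numbers (with the line number), or a
        negative rate.
    """
    ref = ref or HealthReference()
    path = Path(path)
    overrides: dict[str, float] = {}
    unknown: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p for p in re.split(r"[,\t\s]+", line) if p]
        if len(parts) < 2:
            raise ValueError(
                f"{path.name}:{lineno}: expected 'name value [unit [note]]', got {raw!r}"
            )
        name = parts[0]
        try:
            value = float(parts[1])
        except ValueError:
            raise ValueError(
                f"{path.name}:{lineno}: malformed number {parts[1]!r} for {name}"
            ) from None
        if name not in _PARAM_NAMES:
            unknown.append(f"{name} (line {lineno})")
            continue
        if value < 0:
            raise ValueError(
                f"{path.name}:{lineno}: {name} must be non-negative, got {value}"
            )
        overrides[name] = value
    if unknown:
        known = ", ".join(sorted(_PARAM_NAMES))
        raise ValueError(
            f"unknown parameter name(s): {'; '.join(unknown)}. Known names: {known}"
        )
    if base is None:
        missing = sorted(_PARAM_NAMES - _DERIVED - set(overrides))
        if missing:
            raise ValueError(
                "parameter table is incomplete; missing required constants: "
                + ", ".join(missing)
            )
        base = ModelParams()
    elif base is _SHIPPED:
        base = ModelParams()
    params = calibrate_health_fixed_point(base.replace(**overrides), ref)
    resid = health_residual(params, ref)
    scale = ref.as_state_vector()
    if np.any(np.abs(resid) > 1e-12 * scale):
        raise ValueError("calibrated parameter set does not hold the health fixed point")
    return params
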