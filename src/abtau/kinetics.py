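"""Reaction kinetics of the seven-variable amyloid/tau network.

The right-hand sides here are purely local (no transport); the ODE and
PDE engines both call :func:`reaction_rhs`, the former with scalars, the
latter with per-cell arrays.  Intraneural species (amyloid-beta inside
neurons, tau) have their kinetics scaled by the surviving neuron
fraction N/N0 — the bidomain-style homogenization of intra- and
extraneural space.  Neurofibrillary tangles are an algebraic function of
tau, not an integrated state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import HealthReference, ModelParams

__all__ = [
    "NFT_FRACTION",
    "TissueState",
    "ReactionRates",
    "positive_part",
    "nft_from_tau",
    "reaction_rhs",
]

#: fraction of hyperphosphorylated tau bound in neurofibrillary tangles
NFT_FRACTION = 0.6

#: state ordering shared by the solvers
STATE_VARS = ("abi", "abo", "tau", "M", "A", "N")


def positive_part(x):
    """Elementwise ``max(x, 0)`` (the kinetic switches use excess over health)."""
    return np.maximum(x, 0.0)


def nft_from_tau(tau, tau_ss):
    """Neurofibrillary tangle density from tau excess over health.

    A fixed fraction (0.6) of hyperphosphorylated tau is bound in
    tangles; the result is floored at zero since a tau deficit cannot
    produce a negative tangle density.
    """
    return NFT_FRACTION * positive_part(np.asarray(tau) - tau_ss)


@dataclass
class TissueState:
    """Densities of the six dynamical variables, scalar or per-cell.

    Attributes are in g/cm^3: ``abi``/``abo`` amyloid-beta inside /
    outside neurons, ``tau`` tau protein, ``M`` microglia, ``A``
    astrocytes, ``N`` neurons.  Tangles (``F_i``) are derived via
    :func:`nft_from_tau`.
    """

    abi: np.ndarray | float
    abo: np.ndarray | float
    tau: np.ndarray | float
    M: np.ndarray | float
    A: np.ndarray | float
    N: np.ndarray | float

    @classmethod
    def from_vector(cls, y) -> "TissueState":
        return cls(*(np.asarray(y)[i] for i in range(6)))

    def as_vector(self) -> np.ndarray:
        return np.array([self.abi, self.abo, self.tau, self.M, self.A, self.N])

    def validate(self, ref: HealthReference) -> None:
        for name in STATE_VARS:
            v = np.asarray(getattr(self, name))
            if np.any(v < 0):
                raise ValueError(f"state variable {name} has negative entries")
        if np.any(np.asarray(self.N) > ref.N0 * (1 + 1e-12)):
            raise ValueError("neuron density exceeds the healthy reference N0")

    def fi(self, ref: HealthReference):
        return nft_from_tau(self.tau, ref.tau_ss)


@dataclass
class ReactionRates:
    """Time derivative of each variable, g/(cm^3 day)."""

    abi: np.ndarray | float
    abo: np.ndarray | float
    tau: np.ndarray | float
    M: np.ndarray | float
    A: np.ndarray | float
    N: np.ndarray | float

    def as_vector(self) -> np.ndarray:
        return np.array([self.abi, self.abo, self.tau, self.M, self.A, self.N])


def reaction_rhs(
    state: TissueState,
    p: ModelParams,
    ref: HealthReference,
    R_val,
    Rbar_val,
    drug=None,
    validate: bool = False,
) -> ReactionRates:
    """Evaluate the coupled reaction rates at one state.

    Parameters
    ----------
    state
        Current densities (scalars or arrays of a common shape).
    R_val, Rbar_val
        Local, already-ramped inflammation drivers for amyloid and tau,
        in g/(cm^3 day).
    drug
        Optional triple ``(g_leak, g_astro, g_tau)`` of multiplicative
        drug factors in (0, 1]: ``g_leak`` scales the necrosis-leak
        source of extraneural amyloid, ``g_astro`` the astrocytic
        amyloid production, ``g_tau`` the amyloid-driven tau
        hyperphosphorylation.  ``None`` is equivalent to ``(1, 1, 1)``.

    Notes
    -----
    The neuron equation is evaluated first; because neuron death is
    first order in N, the relative death rate ``-(1/N) dN/dt`` is formed
    directly from the death terms, so the necrosis-leak source of
    extraneural amyloid is well defined even as N -> 0 and no numerical
    differentiation is involved.
    """
    if validate:
        state.validate(ref)
        if np.any(np.asarray(R_val) < 0) or np.any(np.asarray(Rbar_val) < 0):
            raise ValueError("inflammation drivers must be non-negative")
    g_leak, g_astro, g_tau = (1.0, 1.0, 1.0) if drug is None else drug

    fi = nft_from_tau(state.tau, ref.tau_ss)
    excess_abo = positive_part(state.abo - ref.abo_ss)
    hill_fi = fi / (p.K_Fi + fi)
    hill_abo = excess_abo / (p.K_abo + excess_abo)
    nfrac = state.N / ref.N0

    # neurons: tangle-driven and amyloid-driven death only
    death_rate = p.d_N_Fi * hill_fi + p.d_N_abo * hill_abo
    dN = -death_rate * state.N

    # intraneural amyloid: ROS-driven production, first-order clearance
    dabi = (R_val + p.lam_abi - p.d_abi * state.abi) * nfrac

    # extraneural amyloid: constitutive + necrosis leak + astrocytic
    # production, microglial and first-order clearance
    dabo = (
        p.lam_abo
        + p.lam_abo_N * death_rate * state.abi * g_leak
        - p.d_abo_M * state.M * state.abo
        - p.d_abo * state.abo
        + p.lam_abo_A * state.A * state.abo * g_astro
    )

    # tau: ROS- and amyloid-driven hyperphosphorylation
    dtau = (
        Rbar_val
        + p.lam_tau
        + p.lam_tau_abi * positive_part(state.abi - ref.abi_ss) * g_tau
        - p.d_tau * state.tau
    ) * nfrac

    # microglia: activation by amyloid excess and tangles
    dM = (
        p.lam_M
        + state.M * (p.lam_M_abo * hill_abo + p.lam_M_Fi * hill_fi)
        - p.d_M * state.M
    )

    # astrocytes: activation by microglial cytokines (quasi-steady in M)
    dA = p.lam_A + p.lam_A_M * state.M / (p.K_M + state.M) * state.A - p.d_A * state.A

    return ReactionRates(abi=dabi, abo=dabo, tau=dtau, M=dM, A=dA, N=dN)
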