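"""Inflammation drivers: temporal ramp and spatial amplitude maps.

The two reactive-oxygen-species drivers R (amyloid) and R-bar (tau)
share a saturating temporal ramp ``(t/gamma)/(K + t)`` and carry
spatially varying amplitudes.  Amplitude maps are built from seeded
pixel-class maps: each pixel is amyloid-biased, tau-biased, non-biased
or inflammation-free, with exact class fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ABETA_BIASED",
    "TAU_BIASED",
    "NON_BIASED",
    "ZERO",
    "CLASS_NAMES",
    "ramp",
    "PixelMap",
    "make_pixel_map",
    "InflammationField",
    "map_to_field",
    "bias_classification",
]

# pixel class codes
ABETA_BIASED, TAU_BIASED, NON_BIASED, ZERO = 0, 1, 2, 3
CLASS_NAMES = ("abeta-biased", "tau-biased", "non-biased", "zero")

#: published reference amplitudes, g/(cm^3 day)
R_STAR = 1.85e-6
RBAR_STAR = 4.13e-10


def ramp(t, K: float, gamma: float = 1.0):
    """Temporal ramp multiplier ``(t/gamma)/(K + t)``.

    Monotone increasing from 0 at t = 0 toward ``1/gamma`` as t grows;
    with ``gamma = 1`` it is the Michaelis form ``t/(K + t)`` with
    half-time ``K``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if K <= 0 or gamma <= 0:
        raise ValueError("ramp constants K and gamma must be positive")
    out = (t / gamma) / (K + t)
    return float(out) if out.ndim == 0 else out


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer class counts summing to ``total``, by largest remainder."""
    quotas = fractions * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    # assign leftover pixels to the largest fractional remainders;
    # ties break by class order for determinism
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


@dataclass(frozen=True)
class PixelMap:
    """Categorical grid of inflammation pixel classes.

    ``classes`` is an (n_y, n_x) integer array of class codes.  The
    realized class counts are exact largest-remainder roundings of the
    requested fractions; placement is a seeded uniform permutation.
    """

    classes: np.ndarray
    fractions: tuple[float, float, float, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.classes)
        if c.ndim != 2:
            raise ValueError("pixel class map must be two-dimensional")
        if not np.isin(c, [ABETA_BIASED, TAU_BIASED, NON_BIASED, ZERO]).all():
            raise ValueError("pixel map contains unknown class codes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def counts(self) -> np.ndarray:
        return np.bincount(self.classes.ravel(), minlength=4)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.classes, fmt="%d", delimiter=",")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PixelMap":
        classes = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
        frac = tuple(np.bincount(classes.ravel(), minlength=4) / classes.size)
        return cls(classes=classes, fractions=frac)


def make_pixel_map(n_x: int, n_y: int, fractions, seed: int | None = None) -> PixelMap:
    """Randomly place pixel classes with exact fractions.

    Class counts are the largest-remainder rounding of
    ``fraction * n_x * n_y``; the fixed multiset of class labels is then
    shuffled by a seeded generator, so the same seed always yields the
    identical map and the realized percentages never drift from the
    requested ones.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (4,) or np.any(fractions < 0):
        raise ValueError("fractions must be four non-negative numbers")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions.sum()!r}")
    if n_x < 1 or n_y < 1:
        raise ValueError("map dimensions must be positive")
    counts = _largest_remainder_counts(fractions, n_x * n_y)
    labels = np.repeat(np.arange(4), counts)
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return PixelMap(
        classes=labels.reshape(n_y, n_x), fractions=tuple(fractions), seed=seed
    )


@dataclass(frozen=True)
class InflammationField:
    """Spatial amplitudes and temporal ramp of the two drivers.

    ``R_amp`` / ``Rbar_amp`` are scalar or (n_y, n_x) amplitude maps in
    g/(cm^3 day); the local driver at time t is ``amp * ramp(t, K,
    gamma)``.
    """

    R_amp: np.ndarray | float
    Rbar_amp: np.ndarray | float
    K: float = 100.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.R_amp) < 0) or np.any(np.asarray(self.Rbar_amp) < 0):
            raise ValueError("inflammation amplitudes must be non-negative")
        if self.K <= 0 or self.gamma <= 0:
            raise ValueError("ramp constants K and gamma must be positive")

    @property
    def is_uniform(self) -> bool:
        return np.ndim(self.R_amp) == 0 and np.ndim(self.Rbar_amp) == 0

    def at(self, t):
        """Driver values (R, R-bar) at time t."""
        m = ramp(t, self.K, self.gamma)
        return self.R_amp * m, self.Rbar_amp * m

    @classmethod
    def uniform(
        cls, R_amp: float = R_STAR, Rbar_amp: float = RBAR_STAR,
        K: float = 100.0, gamma: float = 1.0,
    ) -> "InflammationField":
        return cls(R_amp=float(R_amp), Rbar_amp=float(Rbar_amp), K=K, gamma=gamma)

    @classmethod
    def zero(cls, K: float = 100.0, gamma: float = 1.0) -> "InflammationField":
        return cls(R_amp=0.0, Rbar_amp=0.0, K=K, gamma=gamma)


def map_to_field(
    pixel_map: PixelMap,
    R_star: float = R_STAR,
    Rbar_star: float = RBAR_STAR,
    K: float = 100.0,
    gamma: float = 1.0,
    N1: float = 1.5,
    N2: float = 0.5,
    block: int = 1,
) -> InflammationField:
    """Expand a pixel-class map into driver amplitude maps.

    Per class the amplitudes are ``(N1*R_star, N2*Rbar_star)`` for
    amyloid-biased, ``(N2*R_star, N1*Rbar_star)`` for tau-biased,
    ``(R_star, Rbar_star)`` for non-biased and ``(0, 0)`` for zero
    pixels, with ``N1 > 1 > N2``.  ``block`` replicates each map pixel
    over a block x block tile of solver grid cells, decoupling map and
    grid resolution.
    """
    if R_star < 0 or Rbar_star < 0:
        raise ValueError("reference amplitudes must be non-negative")
    if not (N1 > 1.0 > N2 >= 0.0):
        raise ValueError(f"bias multipliers must satisfy N1 > 1 > N2 >= 0, got {(N1, N2)}")
    if block < 1:
        raise ValueError("block size must be >= 1")
    r_mult = np.array([N1, N2, 1.0, 0.0])
    rbar_mult = np.array([N2, N1, 1.0, 0.0])
    R_amp = r_mult[pixel_map.classes] * R_star
    Rbar_amp = rbar_mult[pixel_map.classes] * Rbar_star
    if block > 1:
        tile = np.ones((block, block))
        R_amp = np.kron(R_amp, tile)
        Rbar_amp = np.kron(Rbar_amp, tile)
    return InflammationField(R_amp=R_amp, Rbar_amp=Rbar_amp, K=K, gamma=gamma)


def bias_classification(pixel_map: PixelMap) -> str:
    """Classify a map by comparing its amyloid- and tau-biased pixel shares."""
    counts = pixel_map.counts()
    if counts[ABETA_BIASED] > counts[TAU_BIASED]:
        return CLASS_NAMES[ABETA_BIASED]
    if counts[TAU_BIASED] > counts[ABETA_BIASED]:
        return CLASS_NAMES[TAU_BIASED]
    return CLASS_NAMES[NON_BIASED]
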