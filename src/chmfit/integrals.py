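"""Analytic one-electron integrals over normalized s-type Cartesian Gaussians.

All functions work in atomic units (bohr, hartree).  The public entry
point :func:`core_matrices` accepts a :class:`~chmfit.molsys.Configuration`
in Angstrom and converts internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .constants import ANGSTROM_TO_BOHR
from .molsys import (
    AtomTyping,
    Configuration,
    DegenerateGeometryError,
    InputError,
)

__all__ = [
    "SGaussian",
    "CoreMatrices",
    "boys_f0",
    "overlap_ss",
    "kinetic_ss",
    "nuclear_attraction_ss",
    "core_matrices",
    "nuclear_repulsion",
]


@dataclass(frozen=True)
class SGaussian:
    """Normalized s-type Gaussian: N * exp(-alpha |r - center|^2)."""

    center: np.ndarray   # (3,), bohr
    exponent: float      # bohr^-2

    def __post_init__(self):
        if self.exponent <= 0:
            raise InputError(f"Gaussian exponent must be > 0, got {self.exponent}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @property
    def norm(self) -> float:
        return (2.0 * self.exponent / np.pi) ** 0.75


@dataclass(frozen=True)
class CoreMatrices:
    """Overlap, core Hamiltonian (kinetic + nuclear attraction), E_nuc."""

    S: np.ndarray        # (K, K)
    Hcore: np.ndarray    # (K, K), hartree
    Enuc: float          # hartree


def boys_f0(t) -> np.ndarray | float:
    """F0(t) = integral_0^1 exp(-t u^2) du = (1/2) sqrt(pi/t) erf(sqrt(t)).

    Uses a Taylor branch for small t to avoid 0/0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InputError("Boys function argument must be >= 0")
    small = t_arr < 1e-6
    safe = np.where(small, 1.0, t_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = 0.5 * np.sqrt(np.pi / safe) * erf(np.sqrt(safe))
    series = 1.0 - t_arr / 3.0 + t_arr**2 / 10.0 - t_arr**3 / 42.0
    out = np.where(small, series, exact)
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def _gaussian_product(a: SGaussian, b: SGaussian):
    p = a.exponent + b.exponent
    mu = a.exponent * b.exponent / p
    diff = a.center - b.center
    r2 = float(diff @ diff)
    center = (a.exponent * a.center + b.exponent * b.center) / p
    return p, mu, r2, center


def overlap_ss(a: SGaussian, b: SGaussian) -> float:
    """<a|b> for normalized s-Gaussians; 1 at zero separation."""
    p, mu, r2, _ = _gaussian_product(a, b)
    return float(a.norm * b.norm * (np.pi / p) ** 1.5 * np.exp(-mu * r2))


def kinetic_ss(a: SGaussian, b: SGaussian) -> float:
    """<a| -1/2 nabla^2 |b> in hartree."""
    _, mu, r2, _ = _gaussian_product(a, b)
    return float(mu * (3.0 - 2.0 * mu * r2) * overlap_ss(a, b))


def nuclear_attraction_ss(a: SGaussian, b: SGaussian, nuclei) -> float:
    """Sum_c <a| -Z_c / |r - R_c| |b> in hartree.

    ``nuclei`` is an iterable of (Z, position-in-bohr) pairs.
    """
    p, mu, r2, center = _gaussian_product(a, b)
    pref = -2.0 * np.pi / p * a.norm * b.norm * np.exp(-mu * r2)
    total = 0.0
    for z, pos in nuclei:
        if z < 0:
            raise InputError(f"nuclear charge must be >= 0, got {z}")
        d = center - np.asarray(pos, dtype=float)
        total += z * boys_f0(p * float(d @ d))
    return float(pref * total)


def nuclear_repulsion(coords_bohr: np.ndarray, charges: np.ndarray) -> float:
    """Sum_{a<b} Z_a Z_b / d_ab in hartree (coordinates in bohr)."""
    n = coords_bohr.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords_bohr[i] - coords_bohr[j]))
            if d <= 0.0:
                raise DegenerateGeometryError("coincident nuclei")
            e += charges[i] * charges[j] / d
    return e


def core_matrices(config: Configuration, typing: AtomTyping) -> CoreMatrices:
    """S, Hcore and Enuc with one s-Gaussian per atom (class exponents)."""
    n = config.n_atoms
    coords = config.coords * ANGSTROM_TO_BOHR
    charges = config.atomic_numbers()
    gaussians = [
        SGaussian(center=coords[i], exponent=typing.exponent_of(i))
        for i in range(n)
    ]
    nuclei = [(charges[i], coords[i]) for i in range(n)]
    S = np.empty((n, n))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            s = overlap_ss(gaussians[i], gaussians[j])
            h = kinetic_ss(gaussians[i], gaussians[j]) + nuclear_attraction_ss(
                gaussians[i], gaussians[j], nuclei
            )
            S[i, j] = S[j, i] = s
            H[i, j] = H[j, i] = h
    enuc = nuclear_repulsion(coords, charges)
    return CoreMatrices(S=S, Hcore=H, Enuc=enuc)
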