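"""Desk-scale training-data generation.

Analytic surrogate potentials (pairwise Morse + optional three-body and
Coulomb tails) stand in for ab-initio reference surfaces; NVE and
harmonically restrained velocity-Verlet dynamics sample configurations;
grid/midpoint splits and energy-stratified pruning build train/test sets.
An adapter contract is provided for an external electronic-structure
engine, but nothing in the package requires one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMU_TO_ME,
    ANGSTROM_TO_BOHR,
    ATOMIC_MASS,
    BOHR_TO_ANGSTROM,
    CM_TO_HARTREE,
    FS_TO_AUT,
)
from .molsys import (
    AtomTyping,
    ChmError,
    Configuration,
    DegenerateGeometryError,
    InputError,
    distances_batch,
    pair_slots,
)

__all__ = [
    "SurrogatePES",
    "Restraint",
    "TrajectorySpec",
    "IntegrationError",
    "CapabilityError",
    "surrogate_energy_gradient",
    "relax",
    "nve_drift",
    "run_nve",
    "run_restrained",
    "grid_and_midpoint_split",
    "prune_select",
    "qc_adapter",
    "h3_plus_surrogate",
    "ch5_plus_surrogate",
    "initial_geometry",
    "PRESETS",
]


class IntegrationError(ChmError, RuntimeError):
    """NVE integration lost energy conservation; reduce the timestep."""


class CapabilityError(ChmError, RuntimeError):
    """A requested external engine is not available in this environment."""


@dataclass(frozen=True)
class Restraint:
    """Harmonic spring on one atom pair."""

    pair: tuple[int, int]
    r0: float            # Angstrom
    k: float             # hartree / bohr^2

    def __post_init__(self):
        if self.k < 0:
            raise InputError("restraint force constant must be >= 0")

    def energy_gradient(self, coords: np.ndarray):
        """Energy (hartree) and Cartesian gradient (hartree/Angstrom)."""
        a, b = self.pair
        d = coords[a] - coords[b]
        r = float(np.linalg.norm(d))
        dr_bohr = (r - self.r0) * ANGSTROM_TO_BOHR
        e = 0.5 * self.k * dr_bohr**2
        grad = np.zeros_like(coords)
        if r > 0:
            g = self.k * dr_bohr * ANGSTROM_TO_BOHR * d / r
            grad[a] = g
            grad[b] = -g
        return e, grad


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of one sampling trajectory."""

    initial: Configuration
    kinetic_energy: float          # cm^-1
    timestep: float = 1.0          # fs
    steps: int = 1000
    restraints: tuple[Restraint, ...] = ()
    stride: int = 1
    seed: int = 0
    drift_tolerance: float = 0.1   # fraction of the kinetic scale

    def __post_init__(self):
        if self.timestep <= 0:
            raise InputError("timestep must be > 0")
        if self.steps < 1 or self.stride < 1:
            raise InputError("steps and stride must be >= 1")


@dataclass(frozen=True)
class SurrogatePES:
    """Analytic permutation-invariant surrogate surface.

    Pair terms are Morse wells ``De * ((1 - exp(-a (r - re)))^2 - 1)`` with
    parameters per unordered atom-class pair, so the surface is invariant
    under the declared typing by construction.  Optional extras: a
    three-body product term and a Coulomb tail with per-class charges.
    """

    typing: AtomTyping
    pair_params: dict[str, tuple[float, float, float]]   # class -> (De, a, re)
    three_body: float = 0.0        # hartree, coefficient of e_ab e_ac e_bc
    charges: dict[str, float] = field(default_factory=dict)  # per class, e

    def _slot_params(self, n_atoms: int):
        slots = pair_slots(n_atoms)
        de = np.empty(len(slots))
        aa = np.empty(len(slots))
        re = np.empty(len(slots))
        qq = np.zeros(len(slots))
        for k, (i, j) in enumerate(slots):
            pc = self.typing.pair_class_of(i, j)
            if pc not in self.pair_params:
                raise InputError(f"no pair parameters for class {pc!r}")
            de[k], aa[k], re[k] = self.pair_params[pc]
            if self.charges:
                qi = self.charges.get(self.typing.class_of(i), 0.0)
                qj = self.charges.get(self.typing.class_of(j), 0.0)
                qq[k] = qi * qj
        return slots, de, aa, re, qq

    def energy_rgrad(self, dists: np.ndarray, n_atoms: int):
        """Energy and d(energy)/d(distance) per slot (hartree, hartree/A)."""
        slots, de, aa, re, qq = self._slot_params(n_atoms)
        if np.any(dists <= 0) and np.any(qq != 0):
            raise DegenerateGeometryError("coincident atoms with Coulomb terms")
        ex = np.exp(-aa * (dists - re))
        e = float(np.sum(de * ((1.0 - ex) ** 2 - 1.0)))
        dedr = 2.0 * de * (1.0 - ex) * aa * ex
        if np.any(qq != 0):
            r_bohr = dists * ANGSTROM_TO_BOHR
            e += float(np.sum(qq / r_bohr))
            dedr += -qq / r_bohr**2 * ANGSTROM_TO_BOHR
        if self.three_body != 0.0:
            slot_index = {s: k for k, s in enumerate(slots)}
            for a in range(n_atoms):
                for b in range(a + 1, n_atoms):
                    for c in range(b + 1, n_atoms):
                        kab = slot_index[(a, b)]
                        kac = slot_index[(a, c)]
                        kbc = slot_index[(b, c)]
                        prod = ex[kab] * ex[kac] * ex[kbc]
                        e += self.three_body * prod
                        for kk in (kab, kac, kbc):
                            dedr[kk] += self.three_body * prod * (-aa[kk])
        return e, dedr


def surrogate_energy_gradient(pes: SurrogatePES, config: Configuration):
    """Energy (hartree) and Cartesian gradient (hartree/Angstrom)."""
    n = config.n_atoms
    coords = config.coords
    dists = distances_batch(coords[None])[0]
    e, dedr = pes.energy_rgrad(dists, n)
    grad = np.zeros((n, 3))
    for k, (i, j) in enumerate(pair_slots(n)):
        d = coords[i] - coords[j]
        u = d / dists[k]
        grad[i] += dedr[k] * u
        grad[j] -= dedr[k] * u
    return e, grad


# ---------------------------------------------------------------------------
# dynamics


def _masses_me(elements) -> np.ndarray:
    return np.array([ATOMIC_MASS[e] for e in elements]) * AMU_TO_ME


def _initial_velocities(coords_bohr, masses, ke_hartree, rng):
    """Random directions, COM momentum and angular momentum removed,
    rescaled to the target kinetic energy.  Returns bohr / a.u. time."""
    n = len(masses)
    if ke_hartree <= 0:
        return np.zeros((n, 3))
    v = rng.standard_normal((n, 3))
    # remove center-of-mass motion
    p = (masses[:, None] * v).sum(axis=0)
    v -= p / masses.sum()
    # remove rigid rotation: solve I w = L, subtract w x r
    com = (masses[:, None] * coords_bohr).sum(axis=0) / masses.sum()
    r = coords_bohr - com
    ell = np.sum(masses[:, None] * np.cross(r, v), axis=0)
    inertia = np.zeros((3, 3))
    for i in range(n):
        ri = r[i]
        inertia += masses[i] * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    try:
        w = np.linalg.solve(inertia + 1e-12 * np.eye(3), ell)
        v -= np.cross(w, r)
    except np.linalg.LinAlgError:
        pass
    ke = 0.5 * float(np.sum(masses[:, None] * v**2))
    if ke <= 0:
        return np.zeros((n, 3))
    return v * np.sqrt(ke_hartree / ke)


def _propagate(pes: SurrogatePES, spec: TrajectorySpec, restrained: bool):
    cfg = spec.initial
    n = cfg.n_atoms
    masses = _masses_me(cfg.elements)
    rng = np.random.default_rng(spec.seed)
    x = cfg.coords * ANGSTROM_TO_BOHR
    ke_h = spec.kinetic_energy * CM_TO_HARTREE
    v = _initial_velocities(x, masses, ke_h, rng)
    dt = spec.timestep * FS_TO_AUT
    restraints = spec.restraints if restrained else ()

    def eval_pot(x_bohr):
        c = Configuration(elements=cfg.elements,
                          coords=x_bohr * BOHR_TO_ANGSTROM)
        e, g = surrogate_energy_gradient(pes, c)   # hartree, hartree/A
        for restr in restraints:
            er, gr = restr.energy_gradient(c.coords)
            e += er
            g = g + gr
        return c, e, g * BOHR_TO_ANGSTROM  # gradient in hartree/bohr

    _, e_pot, g = eval_pot(x)
    e_total0 = e_pot + 0.5 * float(np.sum(masses[:, None] * v**2))
    pot_lo = pot_hi = e_pot
    frames = []
    for step in range(spec.steps):
        v_half = v - 0.5 * dt * g / masses[:, None]
        x = x + dt * v_half
        c, e_pot, g = eval_pot(x)
        v = v_half - 0.5 * dt * g / masses[:, None]
        e_total = e_pot + 0.5 * float(np.sum(masses[:, None] * v**2))
        pot_lo = min(pot_lo, e_pot)
        pot_hi = max(pot_hi, e_pot)
        # drift is judged against the energy scale actually explored
        scale = max(abs(ke_h), pot_hi - pot_lo, 1e-8)
        if abs(e_total - e_total0) > spec.drift_tolerance * scale:
            raise IntegrationError(
                f"energy drift {abs(e_total - e_total0):.3e} hartree at step "
                f"{step}; reduce the timestep"
            )
        if (step + 1) % spec.stride == 0:
            e_surface, _ = surrogate_energy_gradient(pes, c)
            frames.append((c, e_surface))
    return frames, abs(e_total - e_total0)


def relax(pes: SurrogatePES, config: Configuration,
          tol: float = 1e-10) -> Configuration:
    """Local minimization of the surrogate energy (gradient descent via BFGS)."""
    import scipy.optimize  # noqa: PLC0415

    shape = config.coords.shape

    def fun(x):
        c = Configuration(elements=config.elements, coords=x.reshape(shape))
        e, g = surrogate_energy_gradient(pes, c)
        return e, g.ravel()

    res = scipy.optimize.minimize(
        fun, config.coords.ravel(), jac=True, method="BFGS",
        options={"gtol": tol, "maxiter": 500},
    )
    return Configuration(elements=config.elements,
                         coords=res.x.reshape(shape))


def run_nve(pes: SurrogatePES, spec: TrajectorySpec):
    """Velocity-Verlet NVE sampling; returns [(Configuration, energy)]."""
    frames, _ = _propagate(pes, spec, restrained=False)
    return frames


def run_restrained(pes: SurrogatePES, spec: TrajectorySpec):
    """As run_nve but with the spec's harmonic restraints active during
    propagation; stored energies are the unrestrained surface energies."""
    frames, _ = _propagate(pes, spec, restrained=True)
    return frames


def nve_drift(pes: SurrogatePES, spec: TrajectorySpec) -> float:
    """Absolute total-energy drift (hartree) over the full run."""
    _, drift = _propagate(pes, spec, restrained=False)
    return drift


# ---------------------------------------------------------------------------
# selection


def grid_and_midpoint_split(rmin: float, rmax: float, n: int):
    """Uniform train grid plus the n-1 interior midpoints for testing."""
    if not (0 < rmin < rmax):
        raise InputError("need 0 < rmin < rmax")
    if n < 2:
        raise InputError("need n >= 2 grid points")
    train = np.linspace(rmin, rmax, n)
    test = 0.5 * (train[:-1] + train[1:])
    return train, test


def prune_select(configs, energies, n_target: int, n_bins: int = 10,
                 seed: int = 0):
    """Energy-stratified greedy farthest-point selection.

    Configurations are binned by energy; each nonempty bin receives a
    quota proportional to its occupancy (at least one), and within a bin
    points are picked greedily to maximize the minimum pairwise distance
    of sorted-distance-vector descriptors.  Deterministic given the seed.
    Returns the selected indices (sorted).
    """
    energies = np.asarray(energies, dtype=float)
    n = len(configs)
    if n == 0:
        raise InputError("empty input")
    if n_target > n:
        raise InputError(f"n_target {n_target} exceeds {n} available points")
    if n_target == n:
        return list(range(n))
    rng = np.random.default_rng(seed)
    # permutation-invariant descriptors
    coords = np.stack([c.coords for c in configs])
    desc = np.sort(distances_batch(coords), axis=1)

    edges = np.linspace(energies.min(), energies.max(), n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, energies, side="right") - 1,
                     0, n_bins - 1)
    occupied = [b for b in range(n_bins) if np.any(bin_of == b)]
    counts = np.array([(bin_of == b).sum() for b in occupied], dtype=float)
    quota = np.maximum(1, np.floor(n_target * counts / counts.sum())).astype(int)
    quota = np.minimum(quota, counts.astype(int))
    # distribute the remainder to the fullest bins with headroom
    while quota.sum() < n_target:
        head = counts - quota
        k = int(np.argmax(head))
        if head[k] <= 0:
            break
        quota[k] += 1
    while quota.sum() > n_target:
        k = int(np.argmax(quota))
        quota[k] -= 1

    selected: list[int] = []
    for b, q in zip(occupied, quota):
        members = np.where(bin_of == b)[0]
        if q >= len(members):
            selected.extend(members.tolist())
            continue
        first = members[rng.integers(len(members))]
        chosen = [first]
        dmin = np.linalg.norm(desc[members] - desc[first], axis=1)
        for _ in range(q - 1):
            nxt = members[int(np.argmax(dmin))]
            chosen.append(nxt)
            dmin = np.minimum(
                dmin, np.linalg.norm(desc[members] - desc[nxt], axis=1)
            )
        selected.extend(chosen)
    return sorted(selected)


# ---------------------------------------------------------------------------
# external-engine adapter (contract only; no engine ships with the package)

_QC_CACHE: dict[str, float] = {}


def _geometry_hash(config: Configuration, method: str, basis: str) -> str:
    h = hashlib.sha256()
    h.update(json.dumps({
        "elements": list(config.elements),
        "coords": np.round(config.coords, 10).tolist(),
        "method": method,
        "basis": basis,
    }, sort_keys=True).encode())
    return h.hexdigest()


def qc_adapter(engine: str, config: Configuration, method: str,
               basis: str, charge: int = 0, spin: int = 0) -> float:
    """Single-point energy (hartree) via an external engine, cached.

    Raises :class:`CapabilityError` when the engine is not importable in
    the current environment.
    """
    key = _geometry_hash(config, f"{engine}/{method}", basis)
    if key in _QC_CACHE:
        return _QC_CACHE[key]
    if engine != "pyscf":
        raise CapabilityError(
            f"unknown engine {engine!r}; supported adapters: 'pyscf'"
        )
    try:
        from pyscf import cc, dft, gto, scf  # noqa: PLC0415
    except ImportError as exc:
        raise CapabilityError(
            "the 'pyscf' engine is not installed; install pyscf to run "
            "ab-initio spot checks"
        ) from exc
    atom = [
        (e, tuple(xyz)) for e, xyz in zip(config.elements, config.coords)
    ]
    mol = gto.M(atom=atom, basis=basis, charge=charge, spin=spin, unit="Angstrom")
    method = method.lower()
    if method == "hf":
        energy = scf.RHF(mol).kernel()
    elif method == "ccsd":
        mf = scf.RHF(mol).run()
        energy = cc.CCSD(mf).run().e_tot
    elif method.startswith("b3lyp"):
        mf = dft.RKS(mol)
        mf.xc = "b3lyp"
        energy = mf.kernel()
    else:
        raise CapabilityError(f"unsupported method {method!r}")
    if not np.isfinite(energy):
        raise ChmError(f"engine returned non-finite energy for {method}")
    _QC_CACHE[key] = float(energy)
    return float(energy)


# ---------------------------------------------------------------------------
# stock systems and sampling presets


def h3_plus_typing() -> AtomTyping:
    return AtomTyping(
        classes={"H": (0, 1, 2)},
        populations={"H": 2.0 / 3.0},
        formal_charge=1,
        exponents={"H": 1.0},
    )


def h3_plus_surrogate() -> SurrogatePES:
    """Morse + three-body + Coulomb surrogate for the triangular cation."""
    return SurrogatePES(
        typing=h3_plus_typing(),
        pair_params={"H-H": (0.16, 1.8, 0.9)},
        three_body=0.02,
        charges={"H": 1.0 / 3.0},
    )


def ch5_plus_typing() -> AtomTyping:
    return AtomTyping(
        classes={"C": (0,), "H": (1, 2, 3, 4, 5)},
        populations={"C": 6.0, "H": 0.8},
        formal_charge=1,
        exponents={"C": 1.0, "H": 1.0},
    )


def ch5_plus_surrogate() -> SurrogatePES:
    return SurrogatePES(
        typing=ch5_plus_typing(),
        pair_params={
            "C-H": (0.18, 1.9, 1.12),
            "H-H": (0.02, 1.5, 1.7),
        },
        three_body=0.01,
    )


def initial_geometry(system: str) -> Configuration:
    """Reasonable starting geometries for the stock systems (Angstrom)."""
    if system == "h3+":
        r = 0.9
        h = r * np.sqrt(3.0) / 2.0
        return Configuration(
            elements=("H", "H", "H"),
            coords=np.array(
                [[-r / 2, 0.0, 0.0], [r / 2, 0.0, 0.0], [0.0, h, 0.0]]
            ),
        )
    if system == "ch5+":
        # approximate C_s-like arrangement: C + 5 H
        return Configuration(
            elements=("C", "H", "H", "H", "H", "H"),
            coords=np.array([
                [0.000, 0.000, 0.000],
                [1.120, 0.000, 0.000],
                [-0.400, 1.040, 0.000],
                [-0.400, -0.520, 0.920],
                [-0.400, -0.520, -0.920],
                [0.560, 0.950, 0.300],
            ]),
        )
    raise InputError(f"unknown stock system {system!r}")


# Named restrained-sampling presets (distance anchors in Angstrom, force
# constants in hartree/bohr^2, kinetic energies in cm^-1).
PRESETS: dict[str, dict] = {
    "basin1": {
        "system": "ch5+", "kinetic_energy": 16000.0, "steps": 50000,
        "timestep": 1.0, "stride": 5, "restraints": [],
    },
    "basin2A": {
        "system": "ch5+", "kinetic_energy": 5000.0, "steps": 4000,
        "timestep": 1.0, "stride": 4,
        "restraints": [{"pair": [0, 1], "r0": 2.0, "k": 0.5}],
    },
    "basin2B": {
        "system": "ch5+", "kinetic_energy": 5000.0, "steps": 4000,
        "timestep": 1.0, "stride": 4,
        "restraints": [{"pair": [0, 1], "r0": 3.0, "k": 0.5}],
    },
    "basin2C": {
        "system": "ch5+", "kinetic_energy": 5000.0, "steps": 4000,
        "timestep": 1.0, "stride": 5,
        "restraints": [
            {"pair": [0, 1], "r0": 3.0, "k": 0.5},
            {"pair": [0, 2], "r0": 3.0, "k": 0.5},
        ],
    },
    "basin3": {
        "system": "ch5+", "kinetic_energy": 5000.0, "steps": 4000,
        "timestep": 1.0, "stride": 5,
        "restraints": [{"pair": [0, 1], "r0": 4.0, "k": 0.5}],
    },
    "ts12_tight": {
        "system": "formamide", "kinetic_energy": 1000.0, "steps": 1000,
        "timestep": 1.0, "stride": 3,
        "restraints": [
            {"pair": [5, 2], "r0": 1.337, "k": 0.2},
            {"pair": [4, 2], "r0": 1.343, "k": 0.2},
        ],
    },
    "ts12_loose": {
        "system": "formamide", "kinetic_energy": 5000.0, "steps": 10000,
        "timestep": 1.0, "stride": 7,
        "restraints": [
            {"pair": [5, 2], "r0": 1.337, "k": 0.1},
            {"pair": [4, 2], "r0": 1.343, "k": 0.1},
        ],
    },
}
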