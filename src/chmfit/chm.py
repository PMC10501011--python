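"""Core-Hamiltonian energy model and the conventional PIP baseline.

The model energy for a configuration R is

    E(R) = Enuc(R) + sum_a P_aa(R) Hcore_aa(R)
         + 2 sum_{a<b} P_ab(R) Hcore_ab(R) + dE(R) + offset

with the diagonal density P_aa = n_a + sigma * sum_i c_i^class u_{a,i},
the off-diagonal density P_ab = tau(d_ab) * sum_i c_i^pair v_{ab,i}
(covariant PIPs in independently scaled t-variables), and the correction
dE = sum_i c_i^corr u_i over the invariant basis (constant included).
All linear coefficients are obtained from one weighted least-squares
problem; optional charge-conservation rows push the configuration-
dependent electron count sum_ab P_ab S_ab back toward sum_a n_a.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .constants import CM_TO_HARTREE, HARTREE_TO_CM
from .integrals import core_matrices
from .molsys import (
    AtomTyping,
    Configuration,
    InputError,
    compute_distances,
    distances_batch,
    pair_slots,
)
from .pipbasis import (
    PIPBasis,
    atom_covariant_from,
    augment_basis,
    enumerate_invariant_basis,
    evaluate_basis_batch,
    pair_covariant_from,
)

__all__ = [
    "NonlinearParams",
    "Dataset",
    "CHMModel",
    "PIPModel",
    "FitReport",
    "CHMFeaturizer",
    "fit_linear",
    "fit_chm",
    "fit_pip_baseline",
    "optimize_nonlinear",
    "density_diagonal",
    "density_offdiagonal",
    "density_matrix",
    "chm_energy",
    "total_electron_count",
    "energy_decomposition",
    "evaluate_report",
]


@dataclass(frozen=True)
class NonlinearParams:
    """Nonlinear parameters: Morse ranges, exponents, damping scales."""

    d0: float                       # Angstrom, atom/correction PIPs
    t0: float                       # Angstrom, pair PIPs
    alpha: dict[str, float]         # bohr^-2 per atom class
    tau_rs: float = 0.05            # Angstrom, short-range damping scale

    def __post_init__(self):
        if self.d0 <= 0 or self.t0 <= 0 or self.tau_rs <= 0:
            raise InputError("range and damping parameters must be > 0")
        for name, a in self.alpha.items():
            if a <= 0:
                raise InputError(f"alpha for class {name!r} must be > 0")

    def tau(self, d: np.ndarray) -> np.ndarray:
        """Short-range damping: vanishes smoothly at the united-atom limit."""
        return 1.0 - np.exp(-((np.asarray(d) / self.tau_rs) ** 2))

    def sigma(self, d: np.ndarray) -> float:
        """Long-range damping for diagonal densities (identity by default)."""
        return 1.0


@dataclass
class Dataset:
    """Configurations with reference energies (hartree) and fit weights."""

    configs: list[Configuration]
    energies: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.configs) != self.energies.shape[0]:
            raise InputError("configs and energies length mismatch")
        if not np.all(np.isfinite(self.energies)):
            raise InputError("non-finite reference energies")
        if self.weights is None:
            self.weights = np.ones_like(self.energies)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.energies.shape:
                raise InputError("weights shape mismatch")

    def __len__(self) -> int:
        return len(self.configs)

    @classmethod
    def from_energies(cls, configs, energies, unit="hartree", weights=None):
        energies = np.asarray(energies, dtype=float)
        if unit in ("cm-1", "cm^-1", "wavenumber"):
            energies = energies * CM_TO_HARTREE
        elif unit != "hartree":
            raise InputError(f"unknown energy unit {unit!r}")
        return cls(configs=list(configs), energies=energies, weights=weights)

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.configs])


@dataclass
class FitReport:
    """Fit summary: RMSEs in cm^-1, residuals, conditioning diagnostics."""

    model: object
    rmse_train: float
    rmse_test: float | None
    n_params: int
    residuals_train: np.ndarray          # cm^-1, predicted - reference
    residuals_test: np.ndarray | None
    rank: int
    condition_note: str

    def max_error(self, which="train"):
        res = self.residuals_train if which == "train" else self.residuals_test
        idx = int(np.argmax(np.abs(res)))
        return float(abs(res[idx])), idx


def _rmse(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residuals))))


class CHMFeaturizer:
    """Precomputed bases + design-matrix assembly for one system.

    Column layout: ``[atom classes x (L-1) | pair classes x (L-1) |
    correction x L]``, classes in sorted-name order.
    """

    def __init__(self, typing: AtomTyping, n_atoms: int, M: int,
                 patterns=None, term_cap=None):
        typing.validate(n_atoms)
        self.typing = typing
        self.n_atoms = n_atoms
        self.M = M
        self.patterns = [list(p) for p in patterns] if patterns else None
        kwargs = {} if term_cap is None else {"term_cap": term_cap}
        basis = enumerate_invariant_basis(typing, n_atoms, M, **kwargs)
        if self.patterns:
            basis = augment_basis(basis, self.patterns)
        self.basis = basis
        self.atom_class_names = typing.class_names
        self.pair_class_names = typing.pair_class_names
        self.atom_anchors = {
            name: tuple(sorted(typing.classes[name]))
            for name in self.atom_class_names
        }
        slots = pair_slots(n_atoms)
        self.pair_anchors = {
            name: tuple(s for s in slots if typing.pair_class_of(*s) == name)
            for name in self.pair_class_names
        }
        self.atom_cov = {
            name: [atom_covariant_from(basis, typing, a) for a in anchors]
            for name, anchors in self.atom_anchors.items()
        }
        self.pair_cov = {
            name: [pair_covariant_from(basis, typing, s) for s in anchors]
            for name, anchors in self.pair_anchors.items()
        }
        self.slot_index = {s: k for k, s in enumerate(slots)}
        self._core_cache: dict[tuple, dict] = {}

    @property
    def L(self) -> int:
        return self.basis.L

    @property
    def n_columns(self) -> int:
        n_classes = len(self.atom_class_names) + len(self.pair_class_names)
        return n_classes * (self.L - 1) + self.L

    def column_blocks(self):
        """(name, kind, start, stop) for each coefficient block."""
        blocks = []
        pos = 0
        for name in self.atom_class_names:
            blocks.append((name, "atom", pos, pos + self.L - 1))
            pos += self.L - 1
        for name in self.pair_class_names:
            blocks.append((name, "pair", pos, pos + self.L - 1))
            pos += self.L - 1
        blocks.append(("corr", "corr", pos, pos + self.L))
        return blocks

    # -- core-matrix arrays, cached per exponent set --------------------

    def core_arrays(self, configs, alpha: dict[str, float]) -> dict:
        key = (len(configs),
               tuple(sorted((k, round(v, 12)) for k, v in alpha.items())))
        hit = self._core_cache.get(key)
        if hit is not None and hit[0] is configs:
            return hit[1]
        typing = dataclasses.replace(self.typing, exponents=dict(alpha))
        n = len(configs)
        nat = self.n_atoms
        slots = pair_slots(nat)
        hdiag = np.empty((n, nat))
        hoff = np.empty((n, len(slots)))
        soff = np.empty((n, len(slots)))
        enuc = np.empty(n)
        for i, cfg in enumerate(configs):
            cm = core_matrices(cfg, typing)
            hdiag[i] = np.diag(cm.Hcore)
            hoff[i] = [cm.Hcore[a, b] for a, b in slots]
            soff[i] = [cm.S[a, b] for a, b in slots]
            enuc[i] = cm.Enuc
        out = {"hdiag": hdiag, "hoff": hoff, "soff": soff, "enuc": enuc}
        if len(self._core_cache) > 32:
            self._core_cache.clear()
        self._core_cache[key] = (configs, out)
        return out

    # -- design assembly ------------------------------------------------

    def design(self, configs, nlparams: NonlinearParams,
               with_charge_rows: bool = False):
        """Energy design matrix (and optional charge rows).

        Returns ``(X, base_energy)`` or ``(X, base_energy, Xq)`` where
        ``base_energy = Enuc + sum_a n_a Hcore_aa`` per configuration and
        the energy targets should be ``E_ref - base_energy - offset``.
        """
        if len(configs) == 0:
            raise InputError("empty configuration list")
        coords = np.stack([c.coords for c in configs])
        D = distances_batch(coords)
        core = self.core_arrays(configs, nlparams.alpha)
        n = len(configs)
        X = np.zeros((n, self.n_columns))
        Xq = np.zeros((n, self.n_columns)) if with_charge_rows else None
        pops = np.array(
            [self.typing.population_of(a) for a in range(self.n_atoms)]
        )
        base_energy = core["enuc"] + core["hdiag"] @ pops

        for name, kind, lo, hi in self.column_blocks():
            if kind == "atom":
                for anchor, cov in zip(self.atom_anchors[name],
                                       self.atom_cov[name]):
                    U = evaluate_basis_batch(cov, D, nlparams.d0)
                    sig = nlparams.sigma(D)
                    X[:, lo:hi] += sig * U * core["hdiag"][:, anchor:anchor + 1]
                    if Xq is not None:
                        Xq[:, lo:hi] += sig * U  # S_aa = 1
            elif kind == "pair":
                for slot, cov in zip(self.pair_anchors[name],
                                     self.pair_cov[name]):
                    k = self.slot_index[slot]
                    V = evaluate_basis_batch(cov, D, nlparams.t0)
                    damp = nlparams.tau(D[:, k])[:, None]
                    X[:, lo:hi] += 2.0 * damp * V * core["hoff"][:, k:k + 1]
                    if Xq is not None:
                        Xq[:, lo:hi] += 2.0 * damp * V * core["soff"][:, k:k + 1]
            else:
                X[:, lo:hi] = evaluate_basis_batch(
                    self.basis, D, nlparams.d0
                )
        if not np.all(np.isfinite(X)):
            bad = np.where(~np.isfinite(X).all(axis=1))[0]
            raise InputError(f"non-finite design entries at rows {bad[:5]}")
        if Xq is not None:
            return X, base_energy, Xq
        return X, base_energy


@dataclass
class CHMModel:
    """Fitted core-Hamiltonian model."""

    featurizer: CHMFeaturizer
    coeffs: np.ndarray               # full column vector, featurizer layout
    nlparams: NonlinearParams
    energy_offset: float = 0.0       # hartree

    def __post_init__(self):
        if self.coeffs.shape != (self.featurizer.n_columns,):
            raise InputError(
                f"coefficient vector must have length "
                f"{self.featurizer.n_columns}, got {self.coeffs.shape}"
            )

    @property
    def typing(self) -> AtomTyping:
        return self.featurizer.typing

    @property
    def n_params(self) -> int:
        return self.coeffs.shape[0]

    def block_coeffs(self, name: str) -> np.ndarray:
        for bname, _, lo, hi in self.featurizer.column_blocks():
            if bname == name:
                return self.coeffs[lo:hi]
        raise InputError(f"unknown coefficient block {name!r}")

    def predict(self, configs) -> np.ndarray:
        """Model energies in hartree."""
        X, base = self.featurizer.design(configs, self.nlparams)
        return base + X @ self.coeffs + self.energy_offset


@dataclass
class PIPModel:
    """Conventional invariant-PIP fit of the energy."""

    basis: PIPBasis
    coeffs: np.ndarray
    d0: float
    energy_offset: float = 0.0

    @property
    def n_params(self) -> int:
        return self.coeffs.shape[0]

    def predict(self, configs) -> np.ndarray:
        coords = np.stack([c.coords for c in configs])
        D = distances_batch(coords)
        U = evaluate_basis_batch(self.basis, D, self.d0)
        return U @ self.coeffs + self.energy_offset


# ---------------------------------------------------------------------------
# density / energy evaluation on a fitted model


def _anchor_covariant(model: CHMModel, anchor, kind):
    f = model.featurizer
    if kind == "atom":
        name = f.typing.class_of(anchor)
        idx = f.atom_anchors[name].index(anchor)
        return name, f.atom_cov[name][idx]
    name = f.typing.pair_class_of(*anchor)
    idx = f.pair_anchors[name].index(tuple(sorted(anchor)))
    return name, f.pair_cov[name][idx]


def density_diagonal(config: Configuration, model: CHMModel, a: int) -> float:
    """P_aa = n_a + sigma * sum_i c_i u_{a,i}; equals n_a at zero coeffs."""
    name, cov = _anchor_covariant(model, a, "atom")
    dist = compute_distances(config)
    u = evaluate_basis_batch(cov, dist.values[None, :], model.nlparams.d0)[0]
    c = model.block_coeffs(name)
    return float(model.typing.population_of(a)
                 + model.nlparams.sigma(dist.values) * (c @ u))


def density_offdiagonal(config: Configuration, model: CHMModel,
                        pair: tuple[int, int]) -> float:
    """P_ab = tau(d_ab) * sum_i c_i v_{ab,i}; symmetric, vanishes at large d."""
    a, b = pair
    if a == b:
        raise InputError("use density_diagonal for a == b")
    name, cov = _anchor_covariant(model, tuple(sorted(pair)), "pair")
    dist = compute_distances(config)
    v = evaluate_basis_batch(cov, dist.values[None, :], model.nlparams.t0)[0]
    c = model.block_coeffs(name)
    k = model.featurizer.slot_index[tuple(sorted(pair))]
    damp = float(model.nlparams.tau(dist.values[k]))
    return float(damp * (c @ v))


def density_matrix(config: Configuration, model: CHMModel) -> np.ndarray:
    n = config.n_atoms
    P = np.empty((n, n))
    for a in range(n):
        P[a, a] = density_diagonal(config, model, a)
        for b in range(a + 1, n):
            P[a, b] = P[b, a] = density_offdiagonal(config, model, (a, b))
    return P


def correction_energy(config: Configuration, model: CHMModel) -> float:
    dist = compute_distances(config)
    u = evaluate_basis_batch(
        model.featurizer.basis, dist.values[None, :], model.nlparams.d0
    )[0]
    return float(model.block_coeffs("corr") @ u)


def chm_energy(config: Configuration, model: CHMModel) -> float:
    """Explicit trace-form energy; matches ``model.predict`` exactly."""
    typing_a = dataclasses.replace(model.typing,
                                   exponents=dict(model.nlparams.alpha))
    cm = core_matrices(config, typing_a)
    P = density_matrix(config, model)
    n = config.n_atoms
    e = cm.Enuc
    e += float(np.sum(np.diag(P) * np.diag(cm.Hcore)))
    for a in range(n):
        for b in range(a + 1, n):
            e += 2.0 * P[a, b] * cm.Hcore[a, b]
    return e + correction_energy(config, model) + model.energy_offset


def total_electron_count(config: Configuration, model: CHMModel) -> float:
    """n(R) = sum_ab P_ab S_ab."""
    typing_a = dataclasses.replace(model.typing,
                                   exponents=dict(model.nlparams.alpha))
    cm = core_matrices(config, typing_a)
    P = density_matrix(config, model)
    return float(np.sum(P * cm.S))


def energy_decomposition(config: Configuration, model: CHMModel):
    """(core-Hamiltonian part, correction part) in cm^-1; sums to total."""
    corr = correction_energy(config, model) * HARTREE_TO_CM
    total = chm_energy(config, model) * HARTREE_TO_CM
    return total - corr, corr


# ---------------------------------------------------------------------------
# fitting


def fit_linear(design: np.ndarray, targets: np.ndarray,
               weights: np.ndarray | None = None):
    """Weighted least squares via an orthogonal-decomposition solver.

    Returns ``(coeffs, diagnostics)`` where diagnostics carries the rank
    and a conditioning note.  Rank-deficient systems yield the
    minimum-norm solution.
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if design.shape[0] < 1:
        raise InputError("need at least one row")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.all(weights == 0):
            raise InputError("all-zero weights")
        sw = np.sqrt(weights)
        design = design * sw[:, None]
        targets = targets * sw
    coeffs, _, rank, sv = scipy.linalg.lstsq(
        design, targets, lapack_driver="gelsd"
    )
    cond = float(sv[0] / sv[-1]) if sv is not None and sv[-1] > 0 else np.inf
    note = f"rank {rank}/{design.shape[1]}, cond {cond:.3e}"
    if rank < design.shape[1]:
        note += " (rank deficient: minimum-norm solution)"
    return coeffs, {"rank": int(rank), "cond": cond, "note": note}


def _report(model, train: Dataset, test: Dataset | None, diag) -> FitReport:
    res_tr = (model.predict(train.configs) - train.energies) * HARTREE_TO_CM
    res_te = None
    rmse_te = None
    if test is not None:
        res_te = (model.predict(test.configs) - test.energies) * HARTREE_TO_CM
        rmse_te = _rmse(res_te)
    return FitReport(
        model=model,
        rmse_train=_rmse(res_tr),
        rmse_test=rmse_te,
        n_params=model.n_params,
        residuals_train=res_tr,
        residuals_test=res_te,
        rank=diag["rank"],
        condition_note=diag["note"],
    )


def fit_chm(
    train: Dataset,
    typing: AtomTyping,
    M: int,
    nlparams: NonlinearParams,
    charge_weight: float = 0.01,
    patterns=None,
    test: Dataset | None = None,
    featurizer: CHMFeaturizer | None = None,
) -> FitReport:
    """Fit the core-Hamiltonian model by weighted linear least squares."""
    if len(train) == 0:
        raise InputError("empty training set")
    n_atoms = train.configs[0].n_atoms
    if featurizer is None:
        featurizer = CHMFeaturizer(typing, n_atoms, M, patterns=patterns)
    offset = float(np.min(train.energies))
    if charge_weight > 0:
        X, base, Xq = featurizer.design(
            train.configs, nlparams, with_charge_rows=True
        )
        rows = np.vstack([X, Xq])
        targets = np.concatenate(
            [train.energies - offset - base, np.zeros(len(train))]
        )
        weights = np.concatenate(
            [train.weights, np.full(len(train), charge_weight)]
        )
    else:
        X, base = featurizer.design(train.configs, nlparams)
        rows = X
        targets = train.energies - offset - base
        weights = train.weights
    coeffs, diag = fit_linear(rows, targets, weights)
    model = CHMModel(
        featurizer=featurizer, coeffs=coeffs,
        nlparams=nlparams, energy_offset=offset,
    )
    return _report(model, train, test, diag)


def fit_pip_baseline(
    train: Dataset,
    typing: AtomTyping,
    M: int,
    d0: float,
    patterns=None,
    test: Dataset | None = None,
    basis: PIPBasis | None = None,
) -> FitReport:
    """Conventional invariant-PIP fit: E(R) ~ sum_i c_i u_i(R)."""
    if len(train) == 0:
        raise InputError("empty training set")
    n_atoms = train.configs[0].n_atoms
    if basis is None:
        basis = enumerate_invariant_basis(typing, n_atoms, M)
        if patterns:
            basis = augment_basis(basis, patterns)
    offset = float(np.min(train.energies))
    D = distances_batch(train.coords_array())
    U = evaluate_basis_batch(basis, D, d0)
    coeffs, diag = fit_linear(U, train.energies - offset, train.weights)
    model = PIPModel(basis=basis, coeffs=coeffs, d0=d0, energy_offset=offset)
    return _report(model, train, test, diag)


def evaluate_report(model, dataset: Dataset) -> FitReport:
    """Residual report of a fitted model on an arbitrary dataset."""
    res = (model.predict(dataset.configs) - dataset.energies) * HARTREE_TO_CM
    return FitReport(
        model=model,
        rmse_train=_rmse(res),
        rmse_test=_rmse(res),
        n_params=model.n_params,
        residuals_train=res,
        residuals_test=res,
        rank=-1,
        condition_note="evaluation only",
    )


def residual_table(model, dataset: Dataset) -> np.ndarray:
    """(n, 2): energy above dataset minimum and residual, both cm^-1."""
    pred = model.predict(dataset.configs)
    e_above = (dataset.energies - dataset.energies.min()) * HARTREE_TO_CM
    res = (pred - dataset.energies) * HARTREE_TO_CM
    return np.column_stack([e_above, res])


# ---------------------------------------------------------------------------
# nonlinear parameter search


@dataclass
class SearchSpace:
    """Bounded grids for the nonlinear parameters."""

    d0: tuple[float, float, int] = (1.0, 5.0, 9)
    t0: tuple[float, float, int] = (1.0, 5.0, 9)
    alpha: tuple[float, float, int] = (0.2, 2.0, 7)

    def grid(self, which: str) -> np.ndarray:
        lo, hi, n = getattr(self, which)
        if not (0 < lo < hi and np.isfinite(hi)):
            raise InputError(f"unbounded or invalid search range for {which}")
        return np.geomspace(lo, hi, n)


def optimize_nonlinear(
    train: Dataset,
    val: Dataset | None,
    typing: AtomTyping,
    M: int,
    search_space: SearchSpace | None = None,
    seed: int = 0,
    charge_weight: float = 0.01,
    patterns=None,
    tau_rs: float = 0.05,
    n_sweeps: int = 2,
    refine_maxfev: int = 200,
):
    """Coordinate-wise grid search + simplex refinement of validation RMSE.

    Deterministic given the seed and search space.  Returns
    ``(best NonlinearParams, FitReport)`` with the report computed at the
    optimum (validation set used as the test set when provided).
    """
    del seed  # the search is fully deterministic; kept for the contract
    if search_space is None:
        search_space = SearchSpace()
    if val is None:
        val = train
    n_atoms = train.configs[0].n_atoms
    featurizer = CHMFeaturizer(typing, n_atoms, M, patterns=patterns)
    class_names = typing.class_names
    names = ["d0", "t0"] + [f"alpha:{c}" for c in class_names]

    def make_params(vec):
        alpha = {c: float(v) for c, v in zip(class_names, vec[2:])}
        return NonlinearParams(d0=float(vec[0]), t0=float(vec[1]),
                               alpha=alpha, tau_rs=tau_rs)

    best_seen = {"value": np.inf, "vec": None}

    def objective(vec):
        if np.any(np.asarray(vec) <= 0):
            return np.inf
        try:
            rep = fit_chm(train, typing, M, make_params(vec),
                          charge_weight=charge_weight,
                          featurizer=featurizer, test=val)
        except (InputError, np.linalg.LinAlgError):
            return np.inf
        if rep.rmse_test < best_seen["value"]:
            best_seen["value"] = rep.rmse_test
            best_seen["vec"] = np.array(vec, dtype=float)
        return rep.rmse_test

    grids = [search_space.grid("d0"), search_space.grid("t0")] + [
        search_space.grid("alpha") for _ in class_names
    ]
    current = np.array([g[len(g) // 2] for g in grids])
    best_val = objective(current)
    for _ in range(n_sweeps):
        for k in range(len(names)):
            for cand in grids[k]:
                trial = current.copy()
                trial[k] = cand
                v = objective(trial)
                if v < best_val - 1e-12:
                    best_val = v
                    current = trial
    if refine_maxfev > 0:
        # local refinement on log-parameters keeps everything positive
        scipy.optimize.minimize(
            lambda logv: objective(np.exp(logv)),
            np.log(current),
            method="Nelder-Mead",
            options={"maxfev": refine_maxfev, "xatol": 1e-3, "fatol": 1e-6},
        )
    # return the best point ever evaluated (a truncated simplex may have
    # probed a better point than its final vertex)
    if best_seen["vec"] is not None and best_seen["value"] <= best_val:
        current = best_seen["vec"]
    best = make_params(current)
    report = fit_chm(train, typing, M, best, charge_weight=charge_weight,
                     featurizer=featurizer, test=val)
    return best, report
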