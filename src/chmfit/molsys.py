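"""Molecular configurations, atom typing, distances, and permutation groups.

A configuration is an ordered list of element symbols plus Cartesian
coordinates in Angstrom.  Atom typing partitions the atom indices into
named permutation-equivalence classes and attaches per-class electronic
metadata (permanent populations, Gaussian exponents).  The permutation
group is the direct product of the symmetric groups over each class,
together with its induced action on the N(N-1)/2 distance slots.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .constants import ATOMIC_NUMBER

__all__ = [
    "Configuration",
    "AtomTyping",
    "DistanceVector",
    "PermGroup",
    "ChmError",
    "InputError",
    "TypingError",
    "DegenerateGeometryError",
    "pair_slots",
    "compute_distances",
    "build_perm_group",
    "apply_permutation",
]


class ChmError(Exception):
    """Base class for package errors."""


class InputError(ChmError, ValueError):
    """Malformed or out-of-contract input."""


class TypingError(ChmError, ValueError):
    """Atom typing does not partition the atoms, or a class is unknown."""


class DegenerateGeometryError(ChmError, ValueError):
    """Two atoms coincide; distance-based quantities are singular."""


@dataclass(frozen=True)
class Configuration:
    """One molecular geometry: element symbols + coordinates in Angstrom."""

    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3), Angstrom

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError(f"coords must be (N, 3), got {coords.shape}")
        if coords.shape[0] != len(self.elements):
            raise InputError(
                f"{len(self.elements)} elements but {coords.shape[0]} coordinate rows"
            )
        if not np.all(np.isfinite(coords)):
            raise InputError("non-finite coordinates")
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[e] for e in self.elements], dtype=float)


@dataclass(frozen=True)
class AtomTyping:
    """Partition of atom indices into permutation classes with metadata.

    Parameters
    ----------
    classes
        Mapping class name -> tuple of 0-based atom indices.  Must
        partition ``0..n_atoms-1`` exactly.
    populations
        Permanent electron population ``n_a`` per class (per atom).
    formal_charge
        Total formal charge of the system.
    exponents
        Gaussian s-function exponent alpha per class, bohr^-2.
    """

    classes: dict[str, tuple[int, ...]]
    populations: dict[str, float] = field(default_factory=dict)
    formal_charge: int = 0
    exponents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "classes", {k: tuple(v) for k, v in self.classes.items()}
        )
        seen = sorted(i for ids in self.classes.values() for i in ids)
        if len(seen) != len(set(seen)):
            raise TypingError("atom classes overlap")

    @property
    def n_atoms(self) -> int:
        return sum(len(v) for v in self.classes.values())

    @property
    def class_names(self) -> tuple[str, ...]:
        """Class names in a canonical (sorted) order."""
        return tuple(sorted(self.classes))

    def validate(self, n_atoms: int) -> None:
        seen = sorted(i for ids in self.classes.values() for i in ids)
        if seen != list(range(n_atoms)):
            raise TypingError(
                f"classes must partition 0..{n_atoms - 1}, got indices {seen}"
            )
        for name, alpha in self.exponents.items():
            if alpha <= 0:
                raise TypingError(f"exponent for class {name!r} must be > 0")
        for name, pop in self.populations.items():
            if pop < 0:
                raise TypingError(f"population for class {name!r} must be >= 0")

    def class_of(self, atom: int) -> str:
        for name, ids in self.classes.items():
            if atom in ids:
                return name
        raise TypingError(f"atom index {atom} not covered by any class")

    def population_of(self, atom: int) -> float:
        return float(self.populations[self.class_of(atom)])

    def exponent_of(self, atom: int) -> float:
        return float(self.exponents[self.class_of(atom)])

    def check_electron_count(self, elements: tuple[str, ...]) -> None:
        """Verify sum(n_a) + formal_charge == sum(Z_a)."""
        total_pop = sum(self.population_of(i) for i in range(len(elements)))
        total_z = sum(ATOMIC_NUMBER[e] for e in elements)
        if abs(total_pop + self.formal_charge - total_z) > 1e-9:
            raise TypingError(
                f"populations ({total_pop}) + charge ({self.formal_charge}) "
                f"!= nuclear charge ({total_z})"
            )

    def pair_class_of(self, a: int, b: int) -> str:
        ca, cb = sorted((self.class_of(a), self.class_of(b)))
        return f"{ca}-{cb}"

    @property
    def pair_class_names(self) -> tuple[str, ...]:
        """Names of the symmetry-unique unordered pair classes, sorted."""
        names = set()
        n = self.n_atoms
        for i, j in pair_slots(n):
            names.add(self.pair_class_of(i, j))
        return tuple(sorted(names))


@dataclass(frozen=True)
class DistanceVector:
    """Canonically ordered internuclear distances (Angstrom)."""

    pairs: tuple[tuple[int, int], ...]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.pairs)


def pair_slots(n_atoms: int) -> list[tuple[int, int]]:
    """Canonical lexicographic ordering of the unordered atom pairs."""
    return [(i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms)]


def compute_distances(config: Configuration) -> DistanceVector:
    """All N(N-1)/2 internuclear distances in canonical slot order."""
    n = config.n_atoms
    if n < 2:
        raise InputError("need at least 2 atoms for distances")
    slots = pair_slots(n)
    diff = config.coords[:, None, :] - config.coords[None, :, :]
    dmat = np.linalg.norm(diff, axis=-1)
    values = np.array([dmat[i, j] for i, j in slots])
    if np.any(values <= 0.0):
        raise DegenerateGeometryError("coincident atoms (zero internuclear distance)")
    return DistanceVector(pairs=tuple(slots), values=values)


def distances_batch(coords: np.ndarray) -> np.ndarray:
    """Distance vectors for a batch of geometries.

    Parameters
    ----------
    coords : (n_conf, N, 3) array, Angstrom.

    Returns
    -------
    (n_conf, N(N-1)/2) array in canonical slot order.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    diff = coords[:, iu, :] - coords[:, ju, :]
    return np.linalg.norm(diff, axis=-1)


@dataclass(frozen=True)
class PermGroup:
    """Product of symmetric groups over atom classes + slot action.

    ``elements[k]`` is a tuple p with the meaning "atom a moves to
    position p[a]".  ``slot_actions[k]`` gives the induced action on
    distance slots: slot s moves to slot ``slot_actions[k][s]``, so a
    distance vector v transforms as ``v_new = v[inverse_action]``.
    """

    n_atoms: int
    elements: tuple[tuple[int, ...], ...]
    slot_actions: np.ndarray       # (|G|, n_slots) int
    slot_actions_inv: np.ndarray   # (|G|, n_slots) int

    @property
    def order(self) -> int:
        return len(self.elements)

    @property
    def n_slots(self) -> int:
        return self.slot_actions.shape[1]

    def permute_distance_vector(self, k: int, values: np.ndarray) -> np.ndarray:
        """Distance values after applying group element k to the atoms."""
        return np.asarray(values)[..., self.slot_actions_inv[k]]


def _slot_action_of(perm: tuple[int, ...], slots: list[tuple[int, int]],
                    slot_index: dict) -> list[int]:
    return [slot_index[tuple(sorted((perm[i], perm[j])))] for i, j in slots]


def build_perm_group(typing: AtomTyping, n_atoms: int) -> PermGroup:
    """Enumerate the full product group and its distance-slot action."""
    typing.validate(n_atoms)
    class_lists = [list(ids) for ids in typing.classes.values()]
    slots = pair_slots(n_atoms)
    slot_index = {s: k for k, s in enumerate(slots)}
    elements = []
    for images in itertools.product(
        *[itertools.permutations(ids) for ids in class_lists]
    ):
        p = list(range(n_atoms))
        for ids, img in zip(class_lists, images):
            for a, b in zip(ids, img):
                p[a] = b
        elements.append(tuple(p))
    acts = np.array(
        [_slot_action_of(p, slots, slot_index) for p in elements], dtype=np.int64
    )
    inv = np.empty_like(acts)
    rng = np.arange(len(slots))
    for k in range(acts.shape[0]):
        inv[k, acts[k]] = rng
    return PermGroup(
        n_atoms=n_atoms,
        elements=tuple(elements),
        slot_actions=acts,
        slot_actions_inv=inv,
    )


def stabilizer_indices(group: PermGroup, anchor) -> list[int]:
    """Indices of group elements fixing an atom index or an unordered pair."""
    if isinstance(anchor, int):
        return [k for k, p in enumerate(group.elements) if p[anchor] == anchor]
    a, b = anchor
    return [
        k for k, p in enumerate(group.elements)
        if {p[a], p[b]} == {a, b}
    ]


def apply_permutation(
    config: Configuration, perm: tuple[int, ...], typing: AtomTyping | None = None
) -> Configuration:
    """Move atom a to position perm[a]; optionally enforce class safety."""
    n = config.n_atoms
    if sorted(perm) != list(range(n)):
        raise InputError(f"not a permutation of 0..{n - 1}: {perm}")
    if typing is not None:
        for a in range(n):
            if typing.class_of(a) != typing.class_of(perm[a]):
                raise TypingError(
                    f"permutation moves atom {a} across classes "
                    f"({typing.class_of(a)} -> {typing.class_of(perm[a])})"
                )
    new_coords = np.empty_like(config.coords)
    new_elements = [""] * n
    for a in range(n):
        new_coords[perm[a]] = config.coords[a]
        new_elements[perm[a]] = config.elements[a]
    return Configuration(elements=tuple(new_elements), coords=new_coords)
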