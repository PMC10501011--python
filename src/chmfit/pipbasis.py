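"""Permutationally invariant and covariant polynomial bases.

Invariant terms are orbits of distance-slot monomials under the induced
action of the molecular permutation group; each orbit is evaluated as a
plain sum over its distinct members in Morse-transformed distances
y = exp(-d/scale).  Covariant terms attach a polynomial to an atom (or an
unordered atom pair) by symmetrizing a generator monomial over the
anchor's stabilizer subgroup; anchors within one class are related by
transporting the generator with a group element, which makes the values
exchange consistently when like atoms are permuted.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .molsys import (
    AtomTyping,
    DistanceVector,
    InputError,
    PermGroup,
    build_perm_group,
    pair_slots,
    stabilizer_indices,
)

__all__ = [
    "Monomial",
    "PIPTerm",
    "PIPBasis",
    "CovariantBasis",
    "ResourceError",
    "enumerate_invariant_basis",
    "enumerate_atom_covariant_basis",
    "enumerate_pair_covariant_basis",
    "atom_covariant_from",
    "pair_covariant_from",
    "morse_variables",
    "evaluate_basis",
    "evaluate_basis_batch",
    "augment_basis",
]

DEFAULT_TERM_CAP = 5_000_000


class ResourceError(InputError):
    """Enumeration would exceed the configured raw-monomial cap."""


@dataclass(frozen=True)
class Monomial:
    """One distance-slot monomial: integer exponent per slot."""

    exponents: tuple[int, ...]

    @property
    def degree(self) -> int:
        return sum(self.exponents)


@dataclass(frozen=True)
class PIPTerm:
    """One symmetrized term: the orbit of a monomial under the group."""

    canonical: tuple[int, ...]   # lexicographically minimal exponent vector
    degree: int
    orbit: np.ndarray            # (orbit_size, n_slots) distinct exponent rows

    def __post_init__(self):
        degs = self.orbit.sum(axis=1)
        if not np.all(degs == self.degree):
            raise InputError("orbit members have inconsistent degree")


@dataclass(frozen=True)
class PIPBasis:
    """Ordered invariant basis (degree-then-canonical-key order)."""

    group: PermGroup
    M: int
    terms: tuple[PIPTerm, ...]
    includes_constant: bool = True

    @property
    def L(self) -> int:
        return len(self.terms)

    @property
    def n_slots(self) -> int:
        return self.group.n_slots

    def canonical_keys(self) -> set[tuple[int, ...]]:
        return {t.canonical for t in self.terms}


@dataclass(frozen=True)
class CovariantBasis:
    """Generator terms symmetrized over the stabilizer of one anchor."""

    group: PermGroup
    anchor: object               # atom index or unordered (a, b) tuple
    kind: str                    # "atom" | "pair"
    orbits: tuple[np.ndarray, ...]
    degrees: tuple[int, ...]

    @property
    def n_terms(self) -> int:
        return len(self.orbits)

    @property
    def n_slots(self) -> int:
        return self.group.n_slots


# ---------------------------------------------------------------------------
# enumeration


def _compositions_upto(n_slots: int, max_degree: int) -> np.ndarray:
    """All exponent vectors over n_slots with total degree <= max_degree."""
    rows: list[np.ndarray] = [np.zeros((1, n_slots), dtype=np.int64)]
    # build degree-by-degree: each degree-d vector extends a degree-(d-1)
    # vector by incrementing one slot at or after its last nonzero slot
    prev = [(np.zeros(n_slots, dtype=np.int64), 0)]
    for _ in range(max_degree):
        cur = []
        for vec, start in prev:
            for s in range(start, n_slots):
                nv = vec.copy()
                nv[s] += 1
                cur.append((nv, s))
        rows.append(np.array([v for v, _ in cur], dtype=np.int64))
        prev = cur
    return np.vstack(rows)


def _canonical_keys(mono: np.ndarray, group: PermGroup) -> np.ndarray:
    """Integer key of the lexicographically minimal orbit member per row."""
    n_slots = mono.shape[1]
    base = int(mono.max(initial=0)) + 1
    if base**n_slots >= 2**62:  # exact integer keys via Python ints
        powers = (base ** np.arange(n_slots - 1, -1, -1)).astype(object)
        work = mono.astype(object)
    else:
        powers = base ** np.arange(n_slots - 1, -1, -1, dtype=np.int64)
        work = mono
    best = None
    for k in range(group.order):
        permuted = work[:, group.slot_actions_inv[k]]
        key = permuted @ powers
        best = key if best is None else np.minimum(best, key)
    return best


def _orbit_of(vec: np.ndarray, group: PermGroup,
              action_indices=None) -> np.ndarray:
    """Distinct images of one exponent vector under (a subset of) the group."""
    idx = range(group.order) if action_indices is None else action_indices
    images = np.array([vec[group.slot_actions_inv[k]] for k in idx])
    return np.unique(images, axis=0)


def _decode_key(key: int, base: int, n_slots: int) -> tuple[int, ...]:
    out = []
    for _ in range(n_slots):
        out.append(int(key % base))
        key //= base
    return tuple(reversed(out))


def enumerate_invariant_basis(
    typing: AtomTyping,
    n_atoms: int,
    M: int,
    term_cap: int = DEFAULT_TERM_CAP,
    group: PermGroup | None = None,
) -> PIPBasis:
    """All distinct monomial orbits of total degree <= M (constant included).

    The basis size is the L of the model; terms are ordered by degree then
    by canonical exponent vector.
    """
    if M < 0:
        raise InputError(f"M must be >= 0, got {M}")
    if group is None:
        group = build_perm_group(typing, n_atoms)
    n_slots = group.n_slots
    raw = comb(n_slots + M, M)
    if raw > term_cap:
        raise ResourceError(
            f"{raw} raw monomials exceed the cap of {term_cap}; "
            "raise term_cap explicitly to proceed"
        )
    mono = _compositions_upto(n_slots, M)
    keys = _canonical_keys(mono, group)
    base = int(mono.max(initial=0)) + 1
    canon: dict[tuple[int, ...], int] = {}
    for key in np.unique(keys):
        vec = _decode_key(int(key), base, n_slots)
        canon[vec] = sum(vec)
    terms = []
    for vec in sorted(canon, key=lambda v: (sum(v), v)):
        orbit = _orbit_of(np.array(vec, dtype=np.int64), group)
        terms.append(PIPTerm(canonical=vec, degree=sum(vec), orbit=orbit))
    return PIPBasis(group=group, M=M, terms=tuple(terms))


def augment_basis(basis: PIPBasis, patterns: list[list[int]]) -> PIPBasis:
    """Extend a basis with orbits of extra monomial shapes.

    Each pattern is a degree partition placed on distinct distance slots
    (e.g. ``[2, 1]`` means x^2 on one slot times x on another, over all
    ordered assignments of distinct slots).  New orbits are deduplicated
    against the base terms and appended in degree-then-key order.
    """
    group = basis.group
    n_slots = basis.n_slots
    seen = basis.canonical_keys()
    extra_vecs = set()
    for pat in patterns:
        if any(p <= 0 for p in pat):
            raise InputError(f"pattern entries must be positive: {pat}")
        _assign_pattern(tuple(pat), n_slots, extra_vecs)
    if not extra_vecs:
        return basis
    mono = np.array(sorted(extra_vecs), dtype=np.int64)
    keys = _canonical_keys(mono, group)
    base = int(mono.max(initial=0)) + 1
    new_terms = []
    for key in np.unique(keys):
        vec = _decode_key(int(key), base, n_slots)
        if vec in seen:
            continue
        seen.add(vec)
        orbit = _orbit_of(np.array(vec, dtype=np.int64), group)
        new_terms.append(PIPTerm(canonical=vec, degree=sum(vec), orbit=orbit))
    new_terms.sort(key=lambda t: (t.degree, t.canonical))
    return PIPBasis(
        group=group,
        M=basis.M,
        terms=basis.terms + tuple(new_terms),
        includes_constant=basis.includes_constant,
    )


def _assign_pattern(pat: tuple[int, ...], n_slots: int, out: set) -> None:
    """All placements of pattern exponents on distinct slots."""
    import itertools

    k = len(pat)
    for slots_sel in itertools.permutations(range(n_slots), k):
        vec = [0] * n_slots
        for p, s in zip(pat, slots_sel):
            vec[s] = p
        out.add(tuple(vec))


# ---------------------------------------------------------------------------
# covariant bases


def _transporter(group: PermGroup, ref, target, kind: str) -> int:
    """Index of a group element mapping the reference anchor to the target."""
    if kind == "atom":
        for k, p in enumerate(group.elements):
            if p[ref] == target:
                return k
    else:
        rset, tset = set(ref), set(target)
        for k, p in enumerate(group.elements):
            if {p[ref[0]], p[ref[1]]} == tset:
                return k
    raise InputError(f"no group element maps anchor {ref} to {target}")


def _generator_seed(term: PIPTerm) -> np.ndarray:
    # lexicographically maximal orbit member: places weight on low slots,
    # i.e. on distances involving low-index atoms
    idx = np.lexsort(term.orbit.T[::-1])
    return term.orbit[idx[-1]].copy()


def _covariant_for_anchor(
    basis: PIPBasis, anchor, kind: str
) -> CovariantBasis:
    group = basis.group
    if kind == "atom":
        ref = anchor
    else:
        ref = tuple(sorted(anchor))
        if ref[0] == ref[1]:
            raise InputError("pair anchor atoms must be distinct")
        anchor = ref
    stab = stabilizer_indices(group, anchor)
    orbits = []
    degrees = []
    for term in basis.terms:
        if term.degree == 0:
            continue
        seed = _generator_seed(term)
        orbit = _orbit_of(seed, group, action_indices=stab)
        orbits.append(orbit)
        degrees.append(term.degree)
    return CovariantBasis(
        group=group, anchor=anchor, kind=kind,
        orbits=tuple(orbits), degrees=tuple(degrees),
    )


def _transport_covariant(
    cov: CovariantBasis, target, kind: str
) -> CovariantBasis:
    group = cov.group
    k = _transporter(group, cov.anchor, target, kind)
    inv = group.slot_actions_inv[k]
    orbits = tuple(
        np.unique(orb[:, inv], axis=0) for orb in cov.orbits
    )
    return CovariantBasis(
        group=group, anchor=target, kind=kind,
        orbits=orbits, degrees=cov.degrees,
    )


def enumerate_atom_covariant_basis(
    typing: AtomTyping, n_atoms: int, M: int, anchor: int,
    basis: PIPBasis | None = None,
) -> CovariantBasis:
    """Covariant functions attached to one atom (count = L - 1).

    Functions for anchors within the same class are transported copies of
    the reference anchor's stabilizer-symmetrized generators, so permuting
    like atoms 1, 2 exchanges the anchor-1 and anchor-2 value sets.
    """
    if not (0 <= anchor < n_atoms):
        raise InputError(f"anchor {anchor} out of range for {n_atoms} atoms")
    if M < 1:
        raise InputError("covariant bases require M >= 1")
    if basis is None:
        basis = enumerate_invariant_basis(typing, n_atoms, M)
    return atom_covariant_from(basis, typing, anchor)


def atom_covariant_from(
    basis: PIPBasis, typing: AtomTyping, anchor: int
) -> CovariantBasis:
    ref = min(typing.classes[typing.class_of(anchor)])
    cov = _covariant_for_anchor(basis, ref, "atom")
    if anchor == ref:
        return cov
    return _transport_covariant(cov, anchor, "atom")


def enumerate_pair_covariant_basis(
    typing: AtomTyping, n_atoms: int, M: int, anchor: tuple[int, int],
    basis: PIPBasis | None = None,
) -> CovariantBasis:
    """Covariant functions attached to one unordered atom pair (L - 1)."""
    a, b = anchor
    if a == b:
        raise InputError("pair anchor atoms must be distinct")
    if M < 1:
        raise InputError("covariant bases require M >= 1")
    if basis is None:
        basis = enumerate_invariant_basis(typing, n_atoms, M)
    return pair_covariant_from(basis, typing, tuple(sorted((a, b))))


def pair_covariant_from(
    basis: PIPBasis, typing: AtomTyping, anchor: tuple[int, int]
) -> CovariantBasis:
    anchor = tuple(sorted(anchor))
    pc = typing.pair_class_of(*anchor)
    n = typing.n_atoms
    ref = min(
        s for s in pair_slots(n) if typing.pair_class_of(*s) == pc
    )
    cov = _covariant_for_anchor(basis, ref, "pair")
    if anchor == ref:
        return cov
    return _transport_covariant(cov, anchor, "pair")


# ---------------------------------------------------------------------------
# evaluation


def morse_variables(dist: DistanceVector | np.ndarray, scale: float) -> np.ndarray:
    """y = exp(-d / scale) per distance slot."""
    if scale <= 0:
        raise InputError(f"range parameter must be > 0, got {scale}")
    values = dist.values if isinstance(dist, DistanceVector) else np.asarray(dist)
    return np.exp(-values / scale)


def _orbit_stack(orbits) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate orbit exponent rows; offsets delimit each term."""
    sizes = [o.shape[0] for o in orbits]
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return np.vstack(orbits).astype(np.float64), offsets.astype(np.int64)


def evaluate_basis_batch(
    basis: PIPBasis | CovariantBasis,
    dist_batch: np.ndarray,
    scale: float,
    chunk: int = 512,
) -> np.ndarray:
    """Evaluate every term for a batch of distance vectors.

    Parameters
    ----------
    dist_batch : (n_conf, n_slots) distances in Angstrom.
    scale : Morse range parameter (d0 for invariant/atom terms, t0 for
        pair terms).

    Returns
    -------
    (n_conf, n_terms) array of orbit sums.
    """
    dist_batch = np.atleast_2d(np.asarray(dist_batch, dtype=float))
    if dist_batch.shape[1] != basis.n_slots:
        raise InputError(
            f"distance vector has {dist_batch.shape[1]} slots, "
            f"basis needs {basis.n_slots}"
        )
    orbits = (
        [t.orbit for t in basis.terms]
        if isinstance(basis, PIPBasis)
        else list(basis.orbits)
    )
    if not orbits:
        return np.zeros((dist_batch.shape[0], 0))
    exps, offsets = _orbit_stack(orbits)
    n = dist_batch.shape[0]
    out = np.empty((n, len(orbits)))
    logy = -dist_batch / scale      # log of Morse variables
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        monomial_vals = np.exp(logy[lo:hi] @ exps.T)
        out[lo:hi] = np.add.reduceat(monomial_vals, offsets, axis=1)
    return out


def evaluate_basis(
    basis: PIPBasis | CovariantBasis,
    dist: DistanceVector | np.ndarray,
    scale: float,
) -> np.ndarray:
    """Evaluate every term for a single distance vector."""
    values = dist.values if isinstance(dist, DistanceVector) else np.asarray(dist)
    return evaluate_basis_batch(basis, values[None, :], scale)[0]


# ---------------------------------------------------------------------------
# serialization


def basis_to_dict(basis: PIPBasis) -> dict:
    return {
        "M": basis.M,
        "n_atoms": basis.group.n_atoms,
        "includes_constant": basis.includes_constant,
        "terms": [list(t.canonical) for t in basis.terms],
    }


def basis_from_dict(data: dict, typing: AtomTyping) -> PIPBasis:
    group = build_perm_group(typing, data["n_atoms"])
    terms = []
    for vec in data["terms"]:
        vec = tuple(int(x) for x in vec)
        orbit = _orbit_of(np.array(vec, dtype=np.int64), group)
        terms.append(PIPTerm(canonical=vec, degree=sum(vec), orbit=orbit))
    return PIPBasis(
        group=group,
        M=int(data["M"]),
        terms=tuple(terms),
        includes_constant=bool(data["includes_constant"]),
    )
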