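"""Shared helpers for the test suite (independent of package internals
where they serve as oracles)."""

import itertools

import numpy as np

from chmfit.molsys import Configuration


def random_config(elements, rng, spread=1.5, min_dist=0.5):
    """Random geometry with a minimum-separation guard."""
    n = len(elements)
    while True:
        coords = rng.uniform(-spread, spread, size=(n, 3))
        dmin = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                dmin = min(dmin, np.linalg.norm(coords[i] - coords[j]))
        if dmin > min_dist:
            return Configuration(elements=tuple(elements), coords=coords)


# -- brute-force orbit oracle (kept deliberately naive) ---------------------


def _pairs(n):
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def brute_force_orbit_reps(class_lists, n_atoms, max_degree):
    """Distinct orbit representatives of all monomials of degree <= M,
    by explicit full-group symmetrization of exponent tuples."""
    slots = _pairs(n_atoms)
    perms = []
    for prods in itertools.product(
        *[itertools.permutations(c) for c in class_lists]
    ):
        p = list(range(n_atoms))
        for cls, img in zip(class_lists, prods):
            for a, b in zip(cls, img):
                p[a] = b
        perms.append(p)

    def images(vec):
        out = set()
        for p in perms:
            new = [0] * len(slots)
            for k, (i, j) in enumerate(slots):
                tgt = slots.index(tuple(sorted((p[i], p[j]))))
                new[tgt] = vec[k]
            out.add(tuple(new))
        return out

    monos = []

    def rec(pos, rem, cur):
        if pos == len(slots):
            monos.append(tuple(cur))
            return
        for e in range(rem + 1):
            cur.append(e)
            rec(pos + 1, rem - e, cur)
            cur.pop()

    rec(0, max_degree, [])
    reps = set()
    for m in monos:
        reps.add(min(images(m)))
    return reps
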