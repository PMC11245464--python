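"""Forward model for the CFN process on the unrooted 3-leaf star tree.

The Cavender-Farris-Neyman (CFN) model is the two-state symmetric Markov
substitution model: each site carries a state in {-1, +1} (purine / pyrimidine),
the root state is uniform, and along an edge ``e`` of length ``d_e`` (expected
substitutions per site) the endpoint states agree with probability
``(1 + theta_e) / 2`` where ``theta_e = exp(-2 d_e)`` is the *Hadamard
parameter* of the edge -- the correlation of the states at its endpoints.
``theta = 1`` is a zero-length branch, ``theta = 0`` an infinitely long one.

This module provides the parameter conversions, the 8-entry site-pattern
distribution and its 4-entry split collapse, Sylvester-Hadamard matrices and
Hadamard conjugation, the Fourier (monomial) coordinates, and the
semi-algebraic constraints that characterise distributions arising from trees
with strictly positive, finite branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PATTERNS",
    "PATTERN_LABELS",
    "SPLIT_LABELS",
    "SPLIT_OF_PATTERN",
    "SPLIT_SIGNS",
    "theta_from_lengths",
    "lengths_from_theta",
    "pattern_probabilities",
    "split_probabilities",
    "hadamard_matrix",
    "hadamard_conjugation",
    "fourier_from_theta",
    "fourier_from_split",
    "ConstraintReport",
    "satisfies_semialgebraic_constraints",
]

#: All 8 leaf-state patterns sigma in {-1,+1}^3, in binary counting order with
#: -1 before +1: (-1,-1,-1), (-1,-1,+1), ..., (+1,+1,+1).  This is the order in
#: which site-frequency vectors are written throughout the package.
PATTERNS = np.array(
    [[(1 if (i >> b) & 1 else -1) for b in (2, 1, 0)] for i in range(8)],
    dtype=np.int64,
)

PATTERN_LABELS = tuple(
    "".join("+" if x > 0 else "-" for x in row) for row in PATTERNS
)

#: Split classes alpha, ordered lexicographically: {}, {1}, {2}, {1,2}.
#: A pattern sigma has alpha-split pattern when the leaves taking one of the
#: two states are exactly those in alpha (alpha is a subset of {1,2}; leaf 3
#: anchors the complement).
SPLIT_LABELS = ("{}", "{1}", "{2}", "{1,2}")

#: split class index of each of the 8 patterns:
#: {}  <-> (---), (+++);   {1}  <-> (+--), (-++)
#: {2} <-> (-+-), (+-+);   {1,2}<-> (--+), (++-)
SPLIT_OF_PATTERN = np.array([0, 3, 2, 1, 1, 2, 3, 0], dtype=np.intp)

#: Signs (-1)^{|{i,j} ∩ alpha|} of the pair products (theta1*theta2,
#: theta1*theta3, theta2*theta3) in the split-class probabilities:
#: pbar_alpha = (1/4)(1 + e12*t1t2 + e13*t1t3 + e23*t2t3).
SPLIT_SIGNS = np.array(
    [[1, 1, 1], [-1, -1, 1], [-1, 1, -1], [1, -1, -1]], dtype=np.int64
)

_HADAMARD_MAX_ORDER = 12


def _as_theta(theta) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (3,):
        raise ValueError(f"expected 3 edge parameters, got shape {theta.shape}")
    if np.any(theta < 0.0) or np.any(theta > 1.0):
        raise ValueError(f"theta must lie in [0,1]^3, got {theta}")
    return theta


def theta_from_lengths(d) -> np.ndarray:
    """Convert branch lengths (expected substitutions/site) to Hadamard parameters.

    ``theta_e = exp(-2 d_e)``; ``d = inf`` maps to exactly 0, ``d = 0`` to 1.
    Raises ``ValueError`` for negative or NaN lengths.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (3,):
        raise ValueError(f"expected 3 branch lengths, got shape {d.shape}")
    if np.any(np.isnan(d)) or np.any(d < 0.0):
        raise ValueError(f"branch lengths must be in [0, inf], got {d}")
    return np.exp(-2.0 * d)


def lengths_from_theta(theta) -> np.ndarray:
    """Inverse of :func:`theta_from_lengths`: ``d_e = -0.5 log(theta_e)``.

    ``theta = 0`` maps to ``inf`` (an infinitely long branch), ``theta = 1``
    to 0.
    """
    theta = _as_theta(theta)
    with np.errstate(divide="ignore"):
        return -0.5 * np.log(theta) + 0.0  # "+ 0.0" normalizes -0.0 at theta=1


def split_probabilities(theta) -> np.ndarray:
    """The 4-entry split-class distribution pbar(theta).

    ``pbar_alpha = (1/4)(1 + sum_{i<j} (-1)^{|{i,j} ∩ alpha|} theta_i theta_j)``
    in the lexicographic order {}, {1}, {2}, {1,2}.
    """
    theta = _as_theta(theta)
    pair_products = np.array(
        [theta[0] * theta[1], theta[0] * theta[2], theta[1] * theta[2]]
    )
    pbar = 0.25 * (1.0 + SPLIT_SIGNS @ pair_products)
    # exact zeros can round to tiny negatives; the model is polynomial and
    # nonnegative on the closed cube
    return np.clip(pbar, 0.0, 1.0)


def pattern_probabilities(theta) -> tuple[np.ndarray, np.ndarray]:
    """Full 8-entry site-pattern distribution p(theta) and its split collapse.

    ``p_sigma = (1/8)(1 + s1 s2 t1 t2 + s1 s3 t1 t3 + s2 s3 t2 t3)``, which is
    invariant under global sign flip (``p_sigma = p_{-sigma}``, the uniform-root
    symmetry).  Returns ``(p, pbar)`` with ``p`` in the fixed binary pattern
    order and ``pbar`` over the split classes.
    """
    theta = _as_theta(theta)
    s = PATTERNS
    quad = (
        s[:, 0] * s[:, 1] * theta[0] * theta[1]
        + s[:, 0] * s[:, 2] * theta[0] * theta[2]
        + s[:, 1] * s[:, 2] * theta[1] * theta[2]
    )
    p = np.clip((1.0 + quad) / 8.0, 0.0, 1.0)
    pbar = np.zeros(4)
    np.add.at(pbar, SPLIT_OF_PATTERN, p)
    return p, pbar


def hadamard_matrix(k: int) -> np.ndarray:
    """Sylvester-Hadamard matrix ``H_k`` of size ``2^k``.

    ``H_0 = [1]`` and ``H_{k+1} = [[H_k, H_k], [H_k, -H_k]]``; under the
    lexicographic subset ordering its entries are ``(-1)^{|alpha ∩ beta|}``.
    ``H_k H_k = 2^k I``.  ``k`` is capped at 12 to bound memory.
    """
    if not isinstance(k, (int, np.integer)) or k < 0:
        raise ValueError(f"order must be a nonnegative integer, got {k!r}")
    if k > _HADAMARD_MAX_ORDER:
        raise ValueError(f"order {k} exceeds the cap of {_HADAMARD_MAX_ORDER}")
    h = np.array([[1]], dtype=np.int64)
    block = np.array([[1, 1], [1, -1]], dtype=np.int64)
    for _ in range(k):
        h = np.kron(block, h)
    return h


def hadamard_conjugation(gamma) -> np.ndarray:
    """Split distribution from an edge spectrum: ``pbar = H^{-1} exp(H gamma)``.

    ``gamma`` must have length ``2^k``.  For the 3-leaf tree the edge spectrum
    is ``gamma = (-(d1+d2+d3), d1, d2, d3)`` and the result equals the split
    collapse of :func:`pattern_probabilities` evaluated at
    ``theta = exp(-2 d)``.
    """
    gamma = np.asarray(gamma, dtype=float)
    n = gamma.shape[0]
    k = int(n).bit_length() - 1
    if n != 2**k:
        raise ValueError(f"edge spectrum length {n} is not a power of two")
    h = hadamard_matrix(k)
    return (h @ np.exp(h @ gamma)) / float(n)


def fourier_from_theta(theta) -> np.ndarray:
    """Fourier coordinates ``q = (q111, q101, q011, q110)`` of the model point.

    These are the monomials ``(1, theta1*theta3, theta2*theta3,
    theta1*theta2)`` and equal ``H_2 @ pbar(theta)``; q111 = 1 is the single
    phylogenetic invariant of the 3-leaf model.
    """
    theta = _as_theta(theta)
    return np.array(
        [1.0, theta[0] * theta[2], theta[1] * theta[2], theta[0] * theta[1]]
    )


def fourier_from_split(pbar) -> np.ndarray:
    """Fourier transform of a split distribution: ``q = H_2 @ pbar``."""
    pbar = np.asarray(pbar, dtype=float)
    if pbar.shape != (4,):
        raise ValueError(f"expected a 4-entry split vector, got {pbar.shape}")
    return hadamard_matrix(2).astype(float) @ pbar


@dataclass(frozen=True)
class ConstraintReport:
    """Verdict on the semi-algebraic constraints at a Fourier point.

    ``positivity`` maps each nontrivial coordinate name to whether it is
    positive (strictly or not, per ``strict``); ``products`` maps each
    triangle-type inequality (``q110*q101 < q011`` and cyclic) to its verdict.
    All constraints hold simultaneously iff the point comes from a tree with
    strictly positive, finite branch lengths.
    """

    positivity: dict[str, bool]
    products: dict[str, bool]
    strict: bool

    @property
    def all_hold(self) -> bool:
        return all(self.positivity.values()) and all(self.products.values())

    @property
    def failed(self) -> list[str]:
        out = [f"positivity({k})" for k, v in self.positivity.items() if not v]
        out += [f"product({k})" for k, v in self.products.items() if not v]
        return out


def satisfies_semialgebraic_constraints(q, strict: bool = True) -> ConstraintReport:
    """Check positivity and the three triangle-type product inequalities.

    ``q`` is a 4-vector ``(q111, q101, q011, q110)`` with ``q111 = 1``.  With
    ``strict=True`` (the biologically-plausible case) inequalities are strict;
    otherwise non-strict, which is the closure corresponding to branch lengths
    in ``[0, inf]``.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"expected 4 Fourier coordinates, got {q.shape}")
    if not np.isclose(q[0], 1.0, atol=1e-9):
        raise ValueError(f"q111 must equal 1 (the phylogenetic invariant), got {q[0]}")
    _, q101, q011, q110 = q

    def gt(a, b):
        return a > b if strict else a >= b

    positivity = {
        "q101": bool(gt(q101, 0.0)),
        "q011": bool(gt(q011, 0.0)),
        "q110": bool(gt(q110, 0.0)),
    }
    lt = (lambda a, b: a < b) if strict else (lambda a, b: a <= b)
    products = {
        "q110*q101<q011": bool(lt(q110 * q101, q011)),
        "q110*q011<q101": bool(lt(q110 * q011, q101)),
        "q101*q011<q110": bool(lt(q101 * q011, q110)),
    }
    return ConstraintReport(positivity=positivity, products=products, strict=strict)
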