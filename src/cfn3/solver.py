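"""Closed-form global maximum-likelihood solver for the 3-leaf CFN model.

Given generic pattern counts (every split class observed; pair correlations
B12, B13, B23 nonzero and distinct), the set of global maximizers of the
log-likelihood over the closed cube [0,1]^3 has exactly one of four shapes,
decided entirely by where the correlation triple B lies relative to the
model's semi-algebraic constraints:

* INTERIOR -- B lies in the open region D (all B in (0,1), and B_i*B_j < B_k
  for every assignment): the unique maximizer is the biologically plausible
  tree ``theta* = (sqrt(B12*B13/B23), sqrt(B12*B23/B13), sqrt(B13*B23/B12))``,
  whose pair products reproduce B exactly.
* FACE_THETA_ONE -- all B positive but one product constraint fails: the
  maximizer is the single point with the "short" branch pinned to theta = 1
  (branch length 0) and the other two coordinates equal to their correlation
  with that leaf.
* CURVE_THETA_ZERO -- exactly one B positive: the maximizers form a curve with
  the odd leaf's branch pinned to theta = 0 (infinite length) and the product
  of the two free coordinates fixed to the positive correlation.
* INDEPENDENCE_UNION -- all B negative: the maximizers are every parameter
  point at which the three leaves are mutually independent (at least two
  coordinates zero); the likelihood there is flat at -N log 8.

All branching is performed on exact integers (N*B and the integer products
N*B_i * N*B_j vs N^2 * B_k), so regime decisions never depend on floating
point.  Each regime's maximal log-likelihood is computed by two algebraically
equivalent closed forms and cross-checked against direct likelihood
evaluation at a representative point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import likelihood
from .stats import (
    PAIR_LABELS,
    PAIRS,
    BStatistics,
    GenericityReport,
    SiteFrequencyVector,
    check_genericity,
    compute_B,
    read_counts,
    split_collapse,
)

__all__ = [
    "Regime",
    "RegionVerdict",
    "MLESolution",
    "GenericityError",
    "in_region_D",
    "interior_mle",
    "solve_mle",
    "interior_loglik",
    "face_loglik",
    "curve_loglik",
    "independence_loglik",
]

_XCHECK_TOL = 1e-9

#: cycle-notation label and excluded leaf (1-based) for each pair, matching
#: the permutation indexing (1) <-> pair (1,2), (123) <-> (2,3), (132) <-> (3,1).
_CYCLE_OF_PAIR = ("(1)", "(132)", "(123)")
_EXCLUDED_LEAF = (3, 2, 1)  # leaf not in the pair, per PAIRS order


class Regime(str, Enum):
    INTERIOR = "INTERIOR"
    FACE_THETA_ONE = "FACE_THETA_ONE"
    CURVE_THETA_ZERO = "CURVE_THETA_ZERO"
    INDEPENDENCE_UNION = "INDEPENDENCE_UNION"
    NUMERIC_FALLBACK = "NUMERIC_FALLBACK"


class GenericityError(ValueError):
    """Raised when the closed form's genericity assumptions fail."""

    def __init__(self, report: GenericityReport):
        self.report = report
        super().__init__(
            "data violate the genericity assumptions required by the closed-form "
            "solver: " + "; ".join(report.violations)
        )


@dataclass(frozen=True)
class RegionVerdict:
    """Membership of the correlation triple B in the interior region D."""

    in_D: bool
    failed_inequalities: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"in_D": self.in_D, "failed_inequalities": list(self.failed_inequalities)}


@dataclass(frozen=True)
class MLESolution:
    """The solved maximizer set: regime, a representative point, constraints.

    ``constraints`` describes the full maximizer set: a list of dicts with
    either ``{"fix": leaf, "value": v}`` (coordinate pinned) or
    ``{"product": [i, j], "value": v}`` (product of two free coordinates
    fixed).  ``theta`` is one canonical representative; it attains
    ``max_loglik`` exactly.  ``sorted_pairs`` lists (cycle label, pair label,
    B value) in increasing B order.
    """

    regime: Regime
    theta: np.ndarray
    max_loglik: float
    constraints: tuple[dict, ...]
    sorted_pairs: tuple[tuple[str, str, float], ...]
    b: BStatistics
    genericity: GenericityReport
    region: RegionVerdict
    is_singleton: bool
    oracle_trace: list = field(default_factory=list, repr=False)

    @property
    def branch_lengths(self) -> np.ndarray:
        from .model import lengths_from_theta

        return lengths_from_theta(self.theta)

    def to_dict(self) -> dict:
        d = [None if not math.isfinite(x) else float(x) for x in self.branch_lengths]
        return {
            "regime": self.regime.value,
            "theta": [float(t) for t in self.theta],
            "branch_lengths": ["inf" if x is None else x for x in d],
            "constraints": list(self.constraints),
            "loglik": float(self.max_loglik),
            "is_singleton": self.is_singleton,
            "sorted_pairs": [list(t) for t in self.sorted_pairs],
            "B": self.b.to_dict(),
            "genericity": self.genericity.to_dict(),
            "region": self.region.to_dict(),
        }


def in_region_D(b: BStatistics) -> RegionVerdict:
    """Exact test of whether B lies in the interior region D.

    D = {x in (0,1)^3 : x_i * x_j < x_k for all distinct i,j,k}.  Evaluated on
    the integers nb = N*B: positivity is nb > 0 (nb < N for the upper bound,
    guaranteed strict unless a pair never disagrees), and each product
    constraint nb_i * nb_j < N * nb_k.
    """
    nb = b.nb
    n = b.n
    failed = []
    for label, v in zip(PAIR_LABELS, nb):
        if v <= 0:
            failed.append(f"positivity(B{label})")
        elif v >= n:
            failed.append(f"B{label}<1")
    # product constraints: index k is the pair NOT equal to i or j
    product_triples = ((0, 1, 2), (0, 2, 1), (1, 2, 0))
    for i, j, k in product_triples:
        if nb[i] * nb[j] >= n * nb[k]:
            failed.append(f"B{PAIR_LABELS[i]}*B{PAIR_LABELS[j]}<B{PAIR_LABELS[k]}")
    return RegionVerdict(in_D=not failed, failed_inequalities=tuple(failed))


def interior_mle(b: BStatistics) -> np.ndarray:
    """The interior maximizer ``theta* = phi(B)`` (requires B in D).

    ``theta* = (sqrt(B12 B13 / B23), sqrt(B12 B23 / B13), sqrt(B13 B23 / B12))``;
    its pair products invert back to B exactly (up to rounding).
    """
    verdict = in_region_D(b)
    if not verdict.in_D:
        raise ValueError(
            "B lies outside the interior region D "
            f"(failed: {', '.join(verdict.failed_inequalities)}); use solve_mle "
            "for the boundary cases"
        )
    b12, b13, b23 = (float(x) for x in b.b)
    return np.array(
        [
            math.sqrt(b12 * b13 / b23),
            math.sqrt(b12 * b23 / b13),
            math.sqrt(b13 * b23 / b12),
        ]
    )


def interior_loglik(s: SiteFrequencyVector) -> float:
    """Maximal log-likelihood in the interior regime.

    ``sum_alpha sbar_alpha log(sbar_alpha / N) - N log 2`` -- the saturated
    multinomial value on the split classes, achievable because theta* fits the
    empirical split frequencies exactly.
    """
    sbar = split_collapse(s)
    n = sbar.N
    value = -n * math.log(2.0)
    for c in sbar.sbar:
        if c > 0:
            value += c * math.log(c / n)
    return value


def face_loglik(b: BStatistics, pinned_pair_idx: int) -> float:
    """Maximal log-likelihood on the face with one theta pinned to 1.

    ``pinned_pair_idx`` identifies the pair whose B is smallest; the pinned
    leaf is the one excluded from that pair.  Two algebraically equivalent
    forms are computed -- the ``-N log 8 + sum M± log(1±B)`` form over the two
    other pairs and the ``sum M± log(M± / (sqrt(2) N))`` form -- and asserted
    to agree to 1e-9 as an internal consistency check.
    """
    n = b.n
    others = [i for i in range(3) if i != pinned_pair_idx]
    bvals = b.b
    value_a = -n * math.log(8.0)
    value_b = 0.0
    for i in others:
        mp, mm = b.m_plus[i], b.m_minus[i]
        if mp == 0 or mm == 0:
            raise ValueError(
                f"pair {PAIR_LABELS[i]} has a zero agreement count; the face "
                "formula requires every split class observed"
            )
        value_a += mp * math.log1p(bvals[i]) + mm * math.log1p(-bvals[i])
        value_b += mp * math.log(mp / (math.sqrt(2.0) * n)) + mm * math.log(
            mm / (math.sqrt(2.0) * n)
        )
    if abs(value_a - value_b) > _XCHECK_TOL * max(1.0, abs(value_a)):
        raise AssertionError(
            f"face log-likelihood forms disagree: {value_a} vs {value_b}"
        )
    return value_a


def curve_loglik(b: BStatistics, pair_idx: int) -> float:
    """Maximal log-likelihood on the curve with one theta pinned to 0.

    ``pair_idx`` identifies the single pair with positive B (the free pair).
    Forms: ``M+ log(1+B) + M- log(1-B) - N log 8`` and
    ``M+ log(M+/(4N)) + M- log(M-/(4N))``, asserted equal.
    """
    n = b.n
    mp, mm = b.m_plus[pair_idx], b.m_minus[pair_idx]
    if mp == 0 or mm == 0:
        raise ValueError(
            f"pair {PAIR_LABELS[pair_idx]} has a zero agreement count; the "
            "curve formula requires every split class observed"
        )
    bv = float(b.b[pair_idx])
    value_a = mp * math.log1p(bv) + mm * math.log1p(-bv) - n * math.log(8.0)
    value_b = mp * math.log(mp / (4.0 * n)) + mm * math.log(mm / (4.0 * n))
    if abs(value_a - value_b) > _XCHECK_TOL * max(1.0, abs(value_a)):
        raise AssertionError(
            f"curve log-likelihood forms disagree: {value_a} vs {value_b}"
        )
    return value_a


def independence_loglik(n: int) -> float:
    """Log-likelihood on the independence set: flat at ``-N log 8``."""
    return -n * math.log(8.0)


def _sorted_pairs(b: BStatistics) -> list[int]:
    """Pair indices sorted by increasing integer N*B (exact; A.2 forbids ties)."""
    nb = b.nb
    return sorted(range(3), key=lambda i: nb[i])


def solve_mle(
    s,
    force_numeric: bool = False,
    oracle_seed: int = 0,
) -> MLESolution:
    """Solve the 3-leaf maximum-likelihood problem in closed form.

    Dispatches on the exact position of the correlation triple B relative to
    the semi-algebraic constraints and returns the full maximizer set with a
    canonical representative and the maximal log-likelihood (natural log).

    Non-generic data (a split class unobserved, or tied/zero B values) fall
    outside the closed form's hypotheses: the solver refuses with
    :class:`GenericityError` unless ``force_numeric=True``, in which case the
    numerical oracle's maximizer is returned instead, tagged
    ``NUMERIC_FALLBACK``.
    """
    s = read_counts(s)
    genericity = check_genericity(s)
    b = compute_B(s)
    region = in_region_D(b)
    if not genericity.generic:
        if not force_numeric:
            raise GenericityError(genericity)
        result = likelihood.numeric_oracle(split_collapse(s), seed=oracle_seed)
        return MLESolution(
            regime=Regime.NUMERIC_FALLBACK,
            theta=result.best_theta,
            max_loglik=result.best_loglik,
            constraints=(),
            sorted_pairs=(),
            b=b,
            genericity=genericity,
            region=region,
            is_singleton=True,
            oracle_trace=result.trace,
        )

    order = _sorted_pairs(b)
    bvals = b.b
    sorted_pairs = tuple(
        (_CYCLE_OF_PAIR[i], PAIR_LABELS[i], float(bvals[i])) for i in order
    )
    nb = b.nb

    if region.in_D:
        theta = interior_mle(b)
        value = interior_loglik(s)
        constraints = tuple(
            {"fix": leaf, "value": float(t)} for leaf, t in enumerate(theta, start=1)
        )
        regime = Regime.INTERIOR
        singleton = True
    elif nb[order[1]] > 0:
        # case (i): middle B positive but B outside D -> face theta = 1.
        # pi_1 = pair with smallest B; its excluded leaf is pinned to 1 and the
        # other two coordinates equal their correlation with that leaf.
        pair1 = order[0]
        pinned_leaf = _EXCLUDED_LEAF[pair1]  # 1-based
        theta = np.empty(3)
        theta[pinned_leaf - 1] = 1.0
        constraints = [{"fix": pinned_leaf, "value": 1.0}]
        for leaf in range(1, 4):
            if leaf == pinned_leaf:
                continue
            val = b.pair_value(leaf, pinned_leaf)
            theta[leaf - 1] = val
            constraints.append({"fix": leaf, "value": float(val)})
        constraints = tuple(
            sorted(constraints, key=lambda c: c["fix"])
        )
        value = face_loglik(b, pair1)
        regime = Regime.FACE_THETA_ONE
        singleton = True
    elif nb[order[2]] > 0:
        # case (ii): exactly one positive B -> curve with theta = 0 at the odd
        # leaf and the free pair's product fixed to the positive correlation.
        pair3 = order[2]
        pinned_leaf = _EXCLUDED_LEAF[pair3]
        i, j = PAIRS[pair3]
        bv = float(bvals[pair3])
        theta = np.zeros(3)
        theta[i] = math.sqrt(bv)
        theta[j] = math.sqrt(bv)
        constraints = (
            {"fix": pinned_leaf, "value": 0.0},
            {"product": [i + 1, j + 1], "value": bv},
        )
        value = curve_loglik(b, pair3)
        regime = Regime.CURVE_THETA_ZERO
        singleton = False
    else:
        # case (iii): all B negative -> independence union, flat likelihood.
        theta = np.zeros(3)
        constraints = ({"independence": "at least two coordinates equal 0"},)
        value = independence_loglik(b.n)
        regime = Regime.INDEPENDENCE_UNION
        singleton = False

    direct = likelihood.loglik(theta, split_collapse(s))
    if abs(direct - value) > _XCHECK_TOL * max(1.0, abs(value)):
        raise AssertionError(
            f"closed-form log-likelihood {value} disagrees with direct "
            f"evaluation {direct} at the representative point"
        )
    return MLESolution(
        regime=regime,
        theta=theta,
        max_loglik=value,
        constraints=constraints,
        sorted_pairs=sorted_pairs,
        b=b,
        genericity=genericity,
        region=region,
        is_singleton=singleton,
    )


def to_newick(solution: MLESolution, inf_repr: str = "Inf", digits: int = 6) -> str:
    """Render the representative tree as a trivial 3-leaf newick string.

    Infinite branch lengths (theta = 0) are rendered as ``inf_repr``.
    """
    parts = []
    for leaf, d in zip(("1", "2", "3"), solution.branch_lengths):
        parts.append(f"{leaf}:{inf_repr if math.isinf(d) else round(float(d), digits)}")
    return "(" + ",".join(parts) + ");"
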