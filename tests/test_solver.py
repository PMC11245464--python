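"""The closed-form MLE: region dispatch, the four regimes, likelihood formulas."""

import itertools
import math

import numpy as np
import pytest

from cfn3 import (
    GenericityError,
    Regime,
    check_genericity,
    compute_B,
    in_region_D,
    interior_mle,
    loglik,
    numeric_oracle,
    read_counts,
    simulate_sites,
    solve_mle,
    split_collapse,
    to_newick,
)
from cfn3.simulate import counts_from_split
from cfn3.solver import (
    curve_loglik,
    face_loglik,
    independence_loglik,
    interior_loglik,
)
from cfn3.stats import BStatistics


def b_from_counts(counts):
    return compute_B(read_counts(counts))


def make_b(n, nb12, nb13, nb23):
    """BStatistics from integer N*B values (M+ = (N + N*B)/2)."""
    m_plus, m_minus = [], []
    for nb in (nb12, nb13, nb23):
        assert (n + nb) % 2 == 0
        m_plus.append((n + nb) // 2)
        m_minus.append((n - nb) // 2)
    return BStatistics(n=n, m_plus=tuple(m_plus), m_minus=tuple(m_minus))


class TestRegionD:
    def test_published_face_case_fails_product_inequality(self, counts_face_case):
        verdict = in_region_D(compute_B(counts_face_case))
        assert not verdict.in_D
        assert verdict.failed_inequalities == ("B12*B13<B23",)

    def test_published_curve_case_fails_positivity(self, counts_curve_case):
        verdict = in_region_D(compute_B(counts_curve_case))
        assert not verdict.in_D
        assert "positivity(B12)" in verdict.failed_inequalities
        assert "positivity(B23)" in verdict.failed_inequalities

    def test_interior_triple_admitted(self):
        # (0.1, 0.3, 0.2): products 0.03 < 0.2, 0.02 < 0.3, 0.06 < 0.1
        verdict = in_region_D(make_b(100, 10, 30, 20))
        assert verdict.in_D and verdict.failed_inequalities == ()

    def test_membership_decided_on_exact_integers(self):
        # boundary of a product inequality: nb12*nb13 == n*nb23 exactly -> not in D
        assert not in_region_D(make_b(100, 40, 50, 20)).in_D
        assert in_region_D(make_b(100, 40, 50, 22)).in_D


class TestInteriorMLE:
    def test_derived_point(self):
        theta = interior_mle(make_b(100, 10, 30, 20))
        assert theta == pytest.approx([0.387298, 0.258199, 0.774597], abs=1e-6)

    def test_round_trip_products_recover_b(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            nb = sorted(rng.integers(2, 49, size=3) * 2)
            b = make_b(100, int(nb[2]), int(nb[1]), int(nb[0]))
            if not in_region_D(b).in_D:
                continue
            th = interior_mle(b)
            products = (th[0] * th[1], th[0] * th[2], th[1] * th[2])
            assert products == pytest.approx(tuple(b.b), abs=1e-12)
            assert np.all((th > 0) & (th < 1))

    def test_symmetric_b_gives_symmetric_root(self):
        b = make_b(100, 40, 40, 40)
        # A.2 violated (ties) but the interior map itself is still defined
        assert interior_mle(b) == pytest.approx([math.sqrt(0.4)] * 3, abs=1e-12)

    def test_outside_region_refused(self, counts_face_case):
        with pytest.raises(ValueError, match="outside the interior region"):
            interior_mle(compute_B(counts_face_case))


class TestSolveRegimes:
    def test_curve_regime_on_first_published_example(self, counts_curve_case):
        sol = solve_mle(counts_curve_case)
        assert sol.regime is Regime.CURVE_THETA_ZERO
        assert not sol.is_singleton
        fixed = next(c for c in sol.constraints if "fix" in c)
        prod = next(c for c in sol.constraints if "product" in c)
        assert fixed == {"fix": 2, "value": 0.0}
        assert prod["product"] == [1, 3] and prod["value"] == pytest.approx(0.1, abs=0)
        # representative point lies on the constraint set
        assert sol.theta[1] == 0.0
        assert sol.theta[0] * sol.theta[2] == pytest.approx(0.1, abs=1e-12)

    def test_face_regime_on_second_published_example(self, counts_face_case):
        sol = solve_mle(counts_face_case)
        assert sol.regime is Regime.FACE_THETA_ONE
        assert sol.is_singleton
        assert sol.theta == pytest.approx([1.0, 0.3, 0.12], abs=1e-12)
        assert math.isinf(sol.branch_lengths[1]) is False
        assert sol.branch_lengths[0] == 0.0

    def test_interior_regime(self, counts_interior_case):
        sol = solve_mle(counts_interior_case)
        assert sol.regime is Regime.INTERIOR
        assert sol.theta == pytest.approx([0.387298, 0.258199, 0.774597], abs=1e-6)
        expected = (
            40 * math.log(0.4)
            + 20 * math.log(0.2)
            + 25 * math.log(0.25)
            + 15 * math.log(0.15)
            - 100 * math.log(2)
        )
        assert sol.max_loglik == pytest.approx(expected, abs=1e-9)

    def test_independence_regime_all_negative_b(self):
        # sbar = (15, 31, 29, 25): nb = (-20, -12, -8), all negative
        s = counts_from_split((15, 31, 29, 25))
        b = compute_B(s)
        assert all(v < 0 for v in b.nb)
        sol = solve_mle(s)
        assert sol.regime is Regime.INDEPENDENCE_UNION
        assert sol.max_loglik == pytest.approx(-100 * math.log(8), abs=1e-12)
        assert np.all(sol.theta == 0.0)

    def test_sorted_pair_bookkeeping(self, counts_curve_case, counts_face_case):
        # pair labels under the cycle indexing: (1) -> 12, (123) -> 23, (132) -> 13
        sol1 = solve_mle(counts_curve_case)
        assert [p[1] for p in sol1.sorted_pairs] == ["23", "12", "13"]
        assert [p[0] for p in sol1.sorted_pairs] == ["(123)", "(1)", "(132)"]
        sol2 = solve_mle(counts_face_case)
        assert [p[1] for p in sol2.sorted_pairs] == ["23", "13", "12"]

    def test_genericity_refusal_and_numeric_fallback(self):
        s = read_counts([10] * 8)
        with pytest.raises(GenericityError):
            solve_mle(s)
        sol = solve_mle(s, force_numeric=True)
        assert sol.regime is Regime.NUMERIC_FALLBACK
        # uniform data: independence value is the max
        assert sol.max_loglik == pytest.approx(-80 * math.log(8), abs=1e-6)

    def test_closed_form_equals_direct_evaluation_at_representative(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 60:
            th = rng.uniform(0, 1, 3)
            n = int(rng.integers(60, 400))
            s = simulate_sites(theta=th, n_sites=n, seed=int(rng.integers(2**31)))
            if not check_genericity(s).generic:
                continue
            sol = solve_mle(s)
            direct = loglik(sol.theta, split_collapse(s))
            assert direct == pytest.approx(sol.max_loglik, abs=1e-9)
            checked += 1


class TestBoundaryLoglikFormulas:
    def test_independence_value(self):
        assert independence_loglik(100) == pytest.approx(-100 * math.log(8), abs=0)
        assert independence_loglik(100) == pytest.approx(-207.944154, abs=1e-6)

    def test_curve_formula_from_agreement_counts(self, counts_curve_case):
        b = compute_B(counts_curve_case)
        assert (b.m_plus[1], b.m_minus[1]) == (55, 45)
        expected = 55 * math.log(55 / 400) + 45 * math.log(45 / 400)
        assert curve_loglik(b, 1) == pytest.approx(expected, abs=1e-9)
        # and equals direct evaluation at a curve point (sqrt(B), 0, sqrt(B))
        rep = np.array([math.sqrt(0.1), 0.0, math.sqrt(0.1)])
        assert loglik(rep, split_collapse(counts_curve_case)) == pytest.approx(
            curve_loglik(b, 1), abs=1e-9
        )

    def test_face_formula_equals_direct_evaluation(self, counts_face_case):
        b = compute_B(counts_face_case)
        value = face_loglik(b, 2)  # pair 23 has the smallest B
        direct = loglik((1.0, 0.3, 0.12), split_collapse(counts_face_case))
        assert value == pytest.approx(direct, abs=1e-9)

    def test_likelihood_flat_along_curve_set(self, counts_curve_case):
        sbar = split_collapse(counts_curve_case)
        target = solve_mle(counts_curve_case).max_loglik
        for t1 in (0.2, 0.4, 0.8, 1.0):
            t3 = 0.1 / t1
            if t3 > 1:
                continue
            assert loglik((t1, 0.0, t3), sbar) == pytest.approx(target, abs=1e-9)

    def test_regime_value_ordering(self):
        """Interior value dominates every boundary formula whenever D is hit,
        and any curve value beats the independence plateau."""
        rng = np.random.default_rng(23)
        hits = 0
        while hits < 40:
            th = rng.uniform(0.3, 0.95, 3)
            n = int(rng.integers(100, 500))
            s = simulate_sites(theta=th, n_sites=n, seed=int(rng.integers(2**31)))
            if not check_genericity(s).generic:
                continue
            b = compute_B(s)
            if not in_region_D(b).in_D:
                continue
            interior = interior_loglik(s)
            for pair in range(3):
                assert interior > face_loglik(b, pair)
                assert interior > curve_loglik(b, pair)
                assert curve_loglik(b, pair) > independence_loglik(b.n)
            assert interior > independence_loglik(b.n)
            hits += 1


def classify_by_table(nb, n):
    """Independent Table-1 row classifier from exact integer correlations."""
    pos = [v > 0 for v in nb]
    prod_fail = [
        nb[0] * nb[1] >= n * nb[2],  # B12*B13 >= B23
        nb[0] * nb[2] >= n * nb[1],  # B12*B23 >= B13
        nb[1] * nb[2] >= n * nb[0],  # B13*B23 >= B12
    ]
    if all(pos) and not any(prod_fail) and all(v < n for v in nb):
        return "INTERIOR"
    # sorted B: case (i) middle positive, (ii) middle negative < largest
    # positive, (iii) all negative
    n_neg = sum(1 for v in nb if v < 0)
    if n_neg <= 1:
        return "FACE_THETA_ONE"
    if n_neg == 2:
        return "CURVE_THETA_ZERO"
    return "INDEPENDENCE_UNION"


class TestTableExhaustiveness:
    def test_exactly_one_row_fires_on_a_generic_lattice(self):
        """Over a lattice of exact correlation triples satisfying the
        genericity assumptions, the solver regime matches an independent
        row-by-row classification and exactly one case applies."""
        n = 80
        grid = range(-72, 73, 12)  # multiples of 4 keep all class counts integral
        checked = 0
        for nb in itertools.product(grid, repeat=3):
            if 0 in nb or len(set(nb)) < 3:
                continue  # A.2
            sbar = [
                (n + nb[0] + nb[1] + nb[2]),
                (n - nb[0] - nb[1] + nb[2]),
                (n - nb[0] + nb[1] - nb[2]),
                (n + nb[0] - nb[1] - nb[2]),
            ]
            if any(v <= 0 or v % 4 != 0 for v in sbar):
                continue  # A.1 or non-integral counts
            s = counts_from_split([v // 4 for v in sbar])
            b = compute_B(s)
            assert b.nb == nb
            sol = solve_mle(s)
            assert sol.regime.value == classify_by_table(nb, n)
            checked += 1
        assert checked > 100  # the lattice must actually exercise the table


class TestOracleEquivalence:
    def test_oracle_matches_closed_form_on_random_corpus(self):
        rng = np.random.default_rng(31)
        regime_seen = set()
        checked = 0
        while checked < 40:
            th = rng.uniform(0, 1, 3)
            n = int(rng.integers(100, 1001))
            s = simulate_sites(theta=th, n_sites=n, seed=int(rng.integers(2**31)))
            if not check_genericity(s).generic:
                continue
            sol = solve_mle(s)
            result = numeric_oracle(s, seed=int(rng.integers(2**31)))
            assert abs(result.best_loglik - sol.max_loglik) < 1e-6
            # oracle never beats the closed form
            assert result.best_loglik <= sol.max_loglik + 1e-9
            regime_seen.add(sol.regime)
            checked += 1
        assert Regime.INTERIOR in regime_seen


class TestParameterRecovery:
    def test_interior_truth_recovered_at_large_n(self):
        theta = np.array([0.6, 0.7, 0.8])
        interior, close = 0, 0
        n_seeds = 12
        for seed in range(n_seeds):
            s = simulate_sites(theta=theta, n_sites=100_000, seed=seed)
            sol = solve_mle(s)
            if sol.regime is Regime.INTERIOR:
                interior += 1
                if np.max(np.abs(sol.theta - theta)) < 0.02:
                    close += 1
        assert interior == n_seeds
        assert close >= n_seeds - 1


class TestNewick:
    def test_renders_lengths_and_infinity(self, counts_curve_case, counts_face_case):
        assert to_newick(solve_mle(counts_curve_case)) == "(1:0.575646,2:Inf,3:0.575646);"
        nwk = to_newick(solve_mle(counts_face_case))
        assert nwk.startswith("(1:0.0,") or nwk.startswith("(1:0,")
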