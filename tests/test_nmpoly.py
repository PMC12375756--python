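"""NM-polynomial algebra, the five operators, and the index recipes."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import cycle_graph, random_partition
from nmqspr.molgraph import EdgePartition, edge_partition
from nmqspr.nmpoly import (
    INDEX_RECIPES,
    DivergentIntegralError,
    NMPolynomial,
    derive_index,
    from_partition,
)

F = Fraction

# the worked-example polynomial, expanded: 2x^7y^8 + 4x^6y^8 + 4x^6y^6 +
# 2x^5y^7 + 2x^5y^6 + 4x^4y^7 + 2x^4y^5 + x^4y^4 + 2x^2y^5
WORKED_TERMS = {
    (7, 8): 2, (6, 8): 4, (6, 6): 4, (5, 7): 2, (5, 6): 2,
    (4, 7): 4, (4, 5): 2, (4, 4): 1, (2, 5): 2,
}


@pytest.fixture()
def worked_poly(worked_partition):
    return from_partition(worked_partition)


class TestConstruction:
    def test_from_partition_examples(self, worked_poly):
        assert from_partition(EdgePartition({(4, 4): 5})).terms == {(4, 4): F(5)}
        assert from_partition(EdgePartition({(1, 1): 1})).terms == {(1, 1): F(1)}
        assert worked_poly.terms == {k: F(m) for k, m in WORKED_TERMS.items()}

    def test_partition_polynomial_round_trip(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            p = random_partition(rng)
            assert from_partition(p).to_partition() == p

    def test_zero_coefficients_dropped(self):
        assert NMPolynomial({(1, 2): 0, (2, 2): 1}).terms == {(2, 2): F(1)}


class TestOperators:
    def test_dx_multiplies_by_x_exponent(self):
        f = NMPolynomial({(2, 3): 1})
        assert f.d_x().terms == {(2, 3): F(2)}
        g = NMPolynomial({(4, 1): 3, (2, 1): 1})
        assert g.d_x().terms == {(4, 1): F(12), (2, 1): F(2)}
        assert NMPolynomial({}).d_x() == NMPolynomial({})

    def test_sx_divides_by_x_exponent(self):
        assert NMPolynomial({(4, 5): 8}).s_x().terms == {(4, 5): F(2)}
        g = NMPolynomial({(3, 1): 6, (2, 1): 4}).s_x()
        assert g.terms == {(3, 1): F(2), (2, 1): F(2)}

    def test_sx_diverges_on_zero_exponent(self):
        with pytest.raises(DivergentIntegralError):
            NMPolynomial({(0, 2): 1}).s_x()
        with pytest.raises(DivergentIntegralError):
            NMPolynomial({(2, 0): 1}).s_y()

    def test_j_merges_exponents_and_collects(self, worked_poly):
        assert NMPolynomial({(2, 3): 1}).j_diag().terms == {(5, 0): F(1)}
        assert NMPolynomial({(1, 3): 1, (3, 1): 1}).j_diag().terms == {(4, 0): F(2)}
        # worked example: J(NM) = x^7 (2x^8 + 4x^7 + 6x^5 + 6x^4 + 2x^2 + x + 2)
        expected = {(15, 0): 2, (14, 0): 4, (12, 0): 6, (11, 0): 6,
                    (9, 0): 2, (8, 0): 1, (7, 0): 2}
        assert worked_poly.j_diag().terms == {k: F(c) for k, c in expected.items()}

    def test_evaluate_at_one_sums_coefficients(self, worked_poly):
        assert worked_poly.evaluate_at_one() == 23
        assert NMPolynomial({}).evaluate_at_one() == 0
        rng = np.random.default_rng(7)
        p = random_partition(rng)
        assert from_partition(p).evaluate_at_one() == p.total_edges

    def test_operator_linearity(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            f = from_partition(random_partition(rng))
            g = from_partition(random_partition(rng))
            for op in ("d_x", "d_y", "s_x", "s_y", "j_diag"):
                lhs = getattr(f + g, op)()
                rhs = getattr(f, op)() + getattr(g, op)()
                assert lhs == rhs, op

    def test_dx_sx_inverse_on_positive_exponents(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            f = from_partition(random_partition(rng))
            assert f.s_x().d_x() == f
            assert f.d_x().s_x() == f

    def test_nd3_operator_order_is_immaterial(self):
        # all primitives are termwise-diagonal, so Dx Dy (Dx+Dy) commutes
        rng = np.random.default_rng(41)
        for _ in range(50):
            f = from_partition(random_partition(rng))
            a = (f.d_x() + f.d_y()).d_y().d_x()
            b = f.d_x().d_y().d_x() + f.d_y().d_y().d_x()
            c = (f.d_x() + f.d_y()).d_x().d_y()
            assert a == b == c


class TestDeriveIndex:
    def test_worked_example_m1(self, worked_poly):
        assert derive_index(worked_poly, "M1") == 264

    def test_cycle_nh(self):
        f = from_partition(edge_partition(cycle_graph(5)))
        assert derive_index(f, "NH") == F(5, 4)

    def test_single_edge_ni(self):
        f = from_partition(EdgePartition({(1, 1): 1}))
        assert derive_index(f, "NI") == F(1, 2)

    def test_unknown_recipe_rejected(self, worked_poly):
        with pytest.raises(KeyError):
            derive_index(worked_poly, "W")

    @pytest.mark.parametrize("n", range(3, 13))
    def test_cycle_closed_forms(self, n):
        """For C_n all weights are 4: closed forms in n for all eight indices."""
        f = from_partition(edge_partition(cycle_graph(n)))
        expected = {
            "M1": F(8 * n), "M2": F(16 * n), "FN": F(32 * n),
            "M2mm": F(n, 16), "ND3": F(128 * n), "ND5": F(2 * n),
            "NH": F(n, 4), "NI": F(2 * n),
        }
        for name, value in expected.items():
            assert derive_index(f, name) == value, name

    def test_operator_route_matches_sympy(self, worked_poly):
        """Independent symbolic cross-check of every recipe on the worked example."""
        sympy = pytest.importorskip("sympy")
        x, y = sympy.symbols("x y")
        f = sum(int(c) * x**i * y**j for (i, j), c in worked_poly.terms.items())
        Dx = lambda e: sympy.expand(x * sympy.diff(e, x))
        Dy = lambda e: sympy.expand(y * sympy.diff(e, y))
        t = sympy.symbols("t", positive=True)
        Sx = lambda e: sympy.expand(sympy.integrate(e.subs(x, t) / t, (t, 0, x)))
        Sy = lambda e: sympy.expand(sympy.integrate(e.subs(y, t) / t, (t, 0, y)))
        Jd = lambda e: sympy.expand(e.subs(y, x))
        recipes = {
            "M1": Dx(f) + Dy(f),
            "M2": Dx(Dy(f)),
            "FN": Dx(Dx(f)) + Dy(Dy(f)),
            "M2mm": Sx(Sy(f)),
            "ND3": Dx(Dy(Dx(f) + Dy(f))),
            "ND5": Dx(Sy(f)) + Sx(Dy(f)),
            "NH": 2 * Sx(Jd(f)),
            "NI": Sx(Jd(Dx(Dy(f)))),
        }
        for name, expr in recipes.items():
            ref = sympy.Rational(expr.subs({x: 1, y: 1}))
            ours = derive_index(worked_poly, name)
            assert F(int(ref.p), int(ref.q)) == ours, name

    def test_recipe_table_has_exactly_eight_rows(self):
        assert set(INDEX_RECIPES) == {"M1", "M2", "FN", "M2mm", "ND3", "ND5", "NH", "NI"}
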