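"""Exact NM-polynomial algebra and the operator calculus that derives indices.

The NM-polynomial of a graph G collects its neighborhood degree-sum edge
partition into a bivariate generating polynomial

    NM(G; x, y) = sum_{i<=j} m(i, j) x^i y^j,

and every neighborhood index in this family is recovered from NM(G) by
composing five primitive operators and evaluating at x = y = 1:

    Dx f = x df/dx          (termwise multiply by the x-exponent)
    Dy f = y df/dy
    Sx f = int_0^x f(t,y)/t dt   (termwise divide by the x-exponent)
    Sy f = int_0^y f(x,t)/t dt
    J  f = f(x, x)          (merge exponents, collect like terms)

Coefficients are exact ``Fraction``s end-to-end, so the operator route can be
compared with the direct summation formulas by *equality*, not tolerance;
floating decimals appear only when results are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Mapping

from .molgraph import EdgePartition

__all__ = [
    "DivergentIntegralError",
    "NMPolynomial",
    "from_partition",
    "INDEX_RECIPES",
    "derive_index",
]


class DivergentIntegralError(ArithmeticError):
    """Sx/Sy applied to a term with zero exponent: the integral diverges."""


@dataclass(frozen=True)
class NMPolynomial:
    """Sparse bivariate polynomial with exact rational coefficients.

    ``terms`` maps exponent pairs (i, j) to nonzero Fractions.  Zero
    coefficients are dropped on construction so equality is structural.
    """

    terms: Mapping[tuple[int, int], Fraction] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[tuple[int, int], Fraction] = {}
        for (i, j), c in dict(self.terms).items():
            i, j = int(i), int(j)
            if i < 0 or j < 0:
                raise ValueError(f"negative exponent in term ({i},{j})")
            c = Fraction(c)
            if c != 0:
                clean[(i, j)] = clean.get((i, j), Fraction(0)) + c
        clean = {k: c for k, c in clean.items() if c != 0}
        object.__setattr__(self, "terms", clean)

    # -- algebra ----------------------------------------------------------

    def __add__(self, other: "NMPolynomial") -> "NMPolynomial":
        merged = dict(self.terms)
        for k, c in other.terms.items():
            merged[k] = merged.get(k, Fraction(0)) + c
        return NMPolynomial(merged)

    def __eq__(self, other) -> bool:
        return isinstance(other, NMPolynomial) and self.terms == dict(other.terms)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.terms.items())))

    def scale(self, factor) -> "NMPolynomial":
        f = Fraction(factor)
        return NMPolynomial({k: c * f for k, c in self.terms.items()})

    # -- primitive operators ---------------------------------------------

    def d_x(self) -> "NMPolynomial":
        """x * d/dx : term c x^i y^j -> (c*i) x^i y^j."""
        return NMPolynomial({(i, j): c * i for (i, j), c in self.terms.items()})

    def d_y(self) -> "NMPolynomial":
        return NMPolynomial({(i, j): c * j for (i, j), c in self.terms.items()})

    def s_x(self) -> "NMPolynomial":
        """int_0^x f(t,y)/t dt : term c x^i y^j -> (c/i) x^i y^j, i >= 1."""
        out = {}
        for (i, j), c in self.terms.items():
            if i == 0:
                raise DivergentIntegralError(
                    f"Sx diverges on term with x-exponent 0 (coefficient {c}, y^{j})"
                )
            out[(i, j)] = c / i
        return NMPolynomial(out)

    def s_y(self) -> "NMPolynomial":
        out = {}
        for (i, j), c in self.terms.items():
            if j == 0:
                raise DivergentIntegralError(
                    f"Sy diverges on term with y-exponent 0 (coefficient {c}, x^{i})"
                )
            out[(i, j)] = c / j
        return NMPolynomial(out)

    def j_diag(self) -> "NMPolynomial":
        """f(x, x): term c x^i y^j -> c x^(i+j) y^0, collecting like terms."""
        out: dict[tuple[int, int], Fraction] = {}
        for (i, j), c in self.terms.items():
            key = (i + j, 0)
            out[key] = out.get(key, Fraction(0)) + c
        return NMPolynomial(out)

    # -- evaluation / conversion -----------------------------------------

    def evaluate_at_one(self) -> Fraction:
        """f(1, 1) = sum of coefficients (= |E| for a partition polynomial)."""
        return sum(self.terms.values(), Fraction(0))

    def to_partition(self) -> EdgePartition:
        """Inverse of :func:`from_partition`; requires positive-integer terms."""
        counts = {}
        for (i, j), c in self.terms.items():
            if c.denominator != 1 or c < 1:
                raise ValueError(f"term ({i},{j}) has non-count coefficient {c}")
            counts[(i, j)] = int(c)
        return EdgePartition(counts)

    def __str__(self) -> str:
        if not self.terms:
            return "0"

        def fmt(k, c):
            i, j = k
            parts = [] if c == 1 and (i or j) else [str(c)]
            if i:
                parts.append(f"x^{i}" if i > 1 else "x")
            if j:
                parts.append(f"y^{j}" if j > 1 else "y")
            return "*".join(parts)

        keys = sorted(self.terms, key=lambda k: (-(k[0] + k[1]), -k[0]))
        return " + ".join(fmt(k, self.terms[k]) for k in keys)


def from_partition(p: EdgePartition) -> NMPolynomial:
    """Build NM(G; x, y): the class (i, j) with count m becomes m x^i y^j."""
    return NMPolynomial({k: Fraction(m) for k, m in p.counts.items()})


# ---------------------------------------------------------------------------
# Index recipes: operator composition per index, evaluated at x = y = 1.
# Compositions read right-to-left; all primitives act termwise on the
# diagonal, so the order within a pure Dx/Dy product is immaterial.
# ---------------------------------------------------------------------------

INDEX_RECIPES: dict[str, Callable[[NMPolynomial], Fraction]] = {
    # (Dx + Dy) f |_{x=y=1}
    "M1": lambda f: (f.d_x() + f.d_y()).evaluate_at_one(),
    # Dx Dy f
    "M2": lambda f: f.d_y().d_x().evaluate_at_one(),
    # (Dx^2 + Dy^2) f
    "FN": lambda f: (f.d_x().d_x() + f.d_y().d_y()).evaluate_at_one(),
    # Sx Sy f
    "M2mm": lambda f: f.s_y().s_x().evaluate_at_one(),
    # Dx Dy (Dx + Dy) f
    "ND3": lambda f: (f.d_x() + f.d_y()).d_y().d_x().evaluate_at_one(),
    # (Dx Sy + Sx Dy) f
    "ND5": lambda f: (f.s_y().d_x() + f.d_y().s_x()).evaluate_at_one(),
    # 2 Sx J f  (the scalar 2 multiplies the evaluated result)
    "NH": lambda f: 2 * f.j_diag().s_x().evaluate_at_one(),
    # Sx J Dx Dy f
    "NI": lambda f: f.d_y().d_x().j_diag().s_x().evaluate_at_one(),
}


def derive_index(f: NMPolynomial, name: str) -> Fraction:
    """Apply the named operator recipe to f and evaluate at x = y = 1."""
    try:
        recipe = INDEX_RECIPES[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; expected one of {sorted(INDEX_RECIPES)}"
        ) from None
    return recipe(f)
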