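"""Direct closed-form computation of the eight neighborhood indices.

Each index is a sum over the edge partition of count * f(i, j), where (i, j)
are the endpoint neighborhood degree sums of an edge class:

    M1   = i + j              (first neighborhood Zagreb)
    M2   = i * j              (second neighborhood Zagreb)
    FN   = i^2 + j^2          (neighborhood forgotten)
    M2mm = 1 / (i * j)        (modified second neighborhood Zagreb)
    ND3  = i * j * (i + j)    (third neighborhood index)
    ND5  = i/j + j/i          (fifth neighborhood index)
    NH   = 2 / (i + j)        (neighborhood harmonic)
    NI   = i*j / (i + j)      (neighborhood inverse-sum)

This module is the independent oracle for the operator-calculus route in
:mod:`nmqspr.nmpoly`: both are exact over the rationals and must agree to
equality on every partition.  Reported tables round to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import IO, Callable

from .molgraph import EdgePartition

__all__ = ["INDEX_NAMES", "IndexVector", "index_direct", "all_indices"]

INDEX_NAMES: tuple[str, ...] = ("M1", "M2", "FN", "M2mm", "ND3", "ND5", "NH", "NI")

_EDGE_FUNCTIONS: dict[str, Callable[[int, int], Fraction]] = {
    "M1": lambda i, j: Fraction(i + j),
    "M2": lambda i, j: Fraction(i * j),
    "FN": lambda i, j: Fraction(i * i + j * j),
    "M2mm": lambda i, j: Fraction(1, i * j),
    "ND3": lambda i, j: Fraction(i * j * (i + j)),
    "ND5": lambda i, j: Fraction(i, j) + Fraction(j, i),
    "NH": lambda i, j: Fraction(2, i + j),
    "NI": lambda i, j: Fraction(i * j, i + j),
}


@dataclass(frozen=True)
class IndexVector:
    """The eight neighborhood indices of one graph, exact rationals."""

    M1: Fraction
    M2: Fraction
    FN: Fraction
    M2mm: Fraction
    ND3: Fraction
    ND5: Fraction
    NH: Fraction
    NI: Fraction

    def as_dict(self, *, rounded: int | None = None) -> dict[str, float | Fraction]:
        out = {name: getattr(self, name) for name in INDEX_NAMES}
        if rounded is not None:
            out = {k: round(float(v), rounded) for k, v in out.items()}
        return out

    def __getitem__(self, name: str) -> Fraction:
        if name not in INDEX_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def index_direct(p: EdgePartition, name: str) -> Fraction:
    """Sum count * f(i, j) over the partition classes for the named index."""
    try:
        f = _EDGE_FUNCTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; expected one of {INDEX_NAMES}"
        ) from None
    return sum((m * f(i, j) for (i, j), m in p.items()), Fraction(0))


def all_indices(p: EdgePartition) -> IndexVector:
    return IndexVector(**{name: index_direct(p, name) for name in INDEX_NAMES})


def write_index_table(rows: list[tuple[str, str, IndexVector]], stream: IO[str],
                      *, decimals: int = 4) -> None:
    """CSV writer mirroring the reference layout: drug plus eight index columns."""
    stream.write("graph_id,drug," + ",".join(INDEX_NAMES) + "\n")
    for graph_id, drug, vec in rows:
        vals = vec.as_dict(rounded=decimals)
        cells = [f"{vals[n]:g}" for n in INDEX_NAMES]
        stream.write(f"{graph_id},{drug}," + ",".join(cells) + "\n")
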