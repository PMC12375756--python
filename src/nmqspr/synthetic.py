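"""Synthetic chemistry-like graphs and QSPR datasets with known ground truth.

The generator emulates the statistical setting the regression stage assumes:
connected, degree-bounded graphs (max degree 4 by default, mimicking organic
heavy-atom skeletons and keeping neighborhood degree sums in the low-teens
range typical of drug molecules), and properties generated as a low-degree
polynomial in one index plus Gaussian noise:

    y_k = a + b x_k + c x_k^2 + eps_k,   eps_k ~ N(0, noise_sd^2).

A single global seed fans out to per-graph substreams, so extending a
dataset with more graphs never reshuffles the ones already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import index_direct
from .molgraph import MolecularGraph, edge_partition

__all__ = ["SynthConfig", "random_graph", "synth_qspr_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    n_graphs: int = 50
    vertices_range: tuple[int, int] = (10, 30)
    max_degree: int = 4
    extra_edge_prob: float = 0.15
    index_name: str = "M1"
    coefficients: tuple[float, float, float] = (2.0, 0.5, 0.001)
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.max_degree < 2:
            raise ValueError("max_degree must be >= 2")
        if self.vertices_range[0] < 2 or self.vertices_range[0] > self.vertices_range[1]:
            raise ValueError(f"bad vertices_range {self.vertices_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def random_graph(
    n_vertices: int,
    max_degree: int = 4,
    extra_edge_prob: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> MolecularGraph:
    """Connected simple graph: random degree-bounded spanning tree plus extras.

    Vertices join one at a time, attaching to a uniformly chosen existing
    vertex with residual degree capacity; afterwards each candidate non-edge
    between capacity-holding vertices is added with ``extra_edge_prob``.
    The max-degree bound is never exceeded.  Deterministic under seed.
    """
    if n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    if max_degree < 2:
        raise ValueError("max_degree must be >= 2 to grow a connected graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    degree = np.zeros(n_vertices, dtype=int)
    edges: list[tuple[str, str]] = []
    for v in range(1, n_vertices):
        candidates = [u for u in range(v) if degree[u] < max_degree]
        if not candidates:
            raise ValueError(
                f"degree bound {max_degree} infeasible at vertex {v} of {n_vertices}"
            )
        u = int(rng.choice(candidates))
        edges.append((str(u), str(v)))
        degree[u] += 1
        degree[v] += 1

    if extra_edge_prob > 0:
        existing = {frozenset(e) for e in edges}
        # fixed candidate order keeps the draw reproducible
        for u in range(n_vertices):
            for v in range(u + 1, n_vertices):
                if degree[u] >= max_degree or degree[v] >= max_degree:
                    continue
                key = frozenset((str(u), str(v)))
                if key in existing:
                    continue
                if rng.random() < extra_edge_prob:
                    edges.append((str(u), str(v)))
                    existing.add(key)
                    degree[u] += 1
                    degree[v] += 1
    return MolecularGraph(edges)


def synth_qspr_dataset(
    cfg: SynthConfig,
) -> tuple[list[MolecularGraph], np.ndarray, np.ndarray]:
    """Draw graphs, compute the chosen index, and generate noisy properties.

    Returns ``(graphs, x, y)`` with x the exact index values (as floats) and
    y = a + b x + c x^2 + eps.  Graph topology and noise come from separate
    substreams of the global seed, so two configs differing only in seed
    share no randomness, while the same seed always reproduces both.
    """
    root = np.random.SeedSequence(cfg.seed)
    graph_streams, noise_stream = root.spawn(2)
    per_graph = graph_streams.spawn(cfg.n_graphs)

    lo, hi = cfg.vertices_range
    graphs = []
    xs = np.empty(cfg.n_graphs)
    for k in range(cfg.n_graphs):
        rng = np.random.default_rng(per_graph[k])
        n = int(rng.integers(lo, hi + 1))
        g = random_graph(n, cfg.max_degree, cfg.extra_edge_prob, rng)
        graphs.append(g)
        xs[k] = float(index_direct(edge_partition(g), cfg.index_name))

    a, b, c = cfg.coefficients
    noise_rng = np.random.default_rng(noise_stream)
    eps = noise_rng.normal(0.0, cfg.noise_sd, size=cfg.n_graphs)
    ys = a + b * xs + c * xs**2 + eps
    return graphs, xs, ys
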