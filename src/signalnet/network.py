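"""Synthetic scale-free disassortative graphs.

Signal networks are assumed to be scale-free (approximately power-law
degree distribution) and disassortative (negative degree correlation
across edges), with the key nodes being the highest-degree hubs.  This
module generates graphs with those structural properties for the
stochastic validation layer: a power-law degree sequence realised by
configuration-model stub matching (self-loops and multi-edges rejected
and repaired), followed by degree-targeted Maslov-Sneppen rewiring that
preserves the degree sequence while driving the assortativity negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "generate_network",
    "assortativity",
    "sample_powerlaw_degrees",
    "read_edgelist",
    "write_edgelist",
    "read_graphml",
    "write_graphml",
]


@dataclass
class Graph:
    """An undirected simple graph with a designated ordered key-node set.

    Key nodes are the k highest-degree nodes, ties broken by node id,
    mirroring the identification of key nodes with the network's hubs.
    """

    n: int
    nx_graph: nx.Graph = field(repr=False)
    key_nodes: list[int]

    @property
    def edges(self):
        return self.nx_graph.edges

    def degree(self, i: int) -> int:
        return self.nx_graph.degree[i]


def select_key_nodes(g: nx.Graph, k: int) -> list[int]:
    """Top-k nodes by degree; ties broken by ascending node id."""
    return sorted(g.nodes, key=lambda i: (-g.degree[i], i))[:k]


def sample_powerlaw_degrees(
    n: int,
    exponent: float,
    rng: np.random.Generator,
    max_degree: int | None = None,
) -> np.ndarray:
    """Sample a graphical power-law degree sequence with minimum degree 1.

    Degrees d are drawn from P(d) proportional to d^(-exponent) on
    [1, max_degree], with max_degree capped at 2*sqrt(n) so that the
    sequence remains graphical and hubs do not dominate the edge set.
    The sum is made even and graphicality is enforced by resampling.
    """
    if max_degree is None:
        max_degree = max(2, int(2 * np.sqrt(n)))
    support = np.arange(1, max_degree + 1)
    weights = support.astype(float) ** (-exponent)
    weights /= weights.sum()
    for _ in range(100):
        seq = rng.choice(support, size=n, p=weights)
        if seq.sum() % 2 == 1:
            j = int(rng.integers(n))
            if seq[j] < max_degree:
                seq[j] += 1
            else:
                seq[j] -= 1
        if seq.min() >= 1 and nx.is_graphical(sorted(seq)):
            return seq
    raise RuntimeError("failed to sample a graphical degree sequence")


def _match_stubs(seq: np.ndarray, rng: np.random.Generator, max_repair: int = 10_000) -> nx.Graph:
    """Configuration-model matching; bad pairs repaired by edge swaps."""
    stubs = np.repeat(np.arange(len(seq)), seq)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    edges: set[tuple[int, int]] = set()
    bad: list[tuple[int, int]] = []
    for u, v in pairs:
        u, v = int(u), int(v)
        e = (min(u, v), max(u, v))
        if u == v or e in edges:
            bad.append((u, v))
        else:
            edges.add(e)
    for _ in range(max_repair):
        if not bad:
            break
        u, v = bad.pop()
        x, y = list(edges)[int(rng.integers(len(edges)))]
        if rng.integers(2):
            x, y = y, x
        e1 = (min(u, x), max(u, x))
        e2 = (min(v, y), max(v, y))
        if u != x and v != y and e1 not in edges and e2 not in edges and e1 != e2:
            edges.discard((min(x, y), max(x, y)))
            edges.add(e1)
            edges.add(e2)
        else:
            bad.append((u, v))
    if bad:
        raise RuntimeError("could not repair configuration-model collisions")
    g = nx.Graph()
    g.add_nodes_from(range(len(seq)))
    g.add_edges_from(edges)
    return g


def _pearson_from_product_sum(deg_sums: tuple[float, float, float], sxy: float) -> float:
    """Assortativity from the (fixed) degree marginals and sum of d_u*d_v.

    Over the 2m directed edge endpoints the marginal moments depend only
    on the degree sequence, so under degree-preserving rewiring only the
    edge product sum sxy = sum over undirected edges of d_u*d_v changes.
    """
    two_m, s1, s2 = deg_sums  # 2m, sum over endpoints of d, of d^2
    mean = s1 / two_m
    var = s2 / two_m - mean**2
    if var <= 0:
        return float("nan")
    cov = 2.0 * sxy / two_m - mean**2
    return cov / var


def generate_network(
    n: int,
    degree_exponent: float = 2.5,
    k: int = 2,
    seed: int = 0,
    target_assortativity: float = -0.1,
    rewiring_steps: int = 20_000,
) -> Graph:
    """Generate a scale-free, disassortative graph with k key nodes.

    After stub matching, pairs of edges are repeatedly rewired (degrees
    preserved) accepting only rewirings that lower the degree-degree
    product sum, until the measured assortativity drops below
    ``target_assortativity`` or the step budget is exhausted (best-effort
    with a warning).  Deterministic for a given seed.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if not (2.0 <= degree_exponent <= 4.0):
        raise ValueError("degree_exponent must be in [2, 4]")
    if not (0 <= k < n):
        raise ValueError("k must satisfy 0 <= k < n")
    if target_assortativity > 0:
        raise ValueError("target_assortativity must be <= 0")

    rng = np.random.default_rng(seed)
    seq = sample_powerlaw_degrees(n, degree_exponent, rng)
    g = _match_stubs(seq, rng)

    deg = dict(g.degree())
    edge_list = [tuple(e) for e in g.edges]
    two_m = 2 * len(edge_list)
    s1 = float(sum(deg[u] + deg[v] for u, v in edge_list))
    s2 = float(sum(deg[u] ** 2 + deg[v] ** 2 for u, v in edge_list))
    sxy = float(sum(deg[u] * deg[v] for u, v in edge_list))
    edge_set = {(min(u, v), max(u, v)) for u, v in edge_list}

    r = _pearson_from_product_sum((two_m, s1, s2), sxy)
    steps = 0
    while np.isfinite(r) and r > target_assortativity and steps < rewiring_steps:
        steps += 1
        i, j = rng.integers(len(edge_list)), rng.integers(len(edge_list))
        if i == j:
            continue
        u, v = edge_list[i]
        x, y = edge_list[j]
        if len({u, v, x, y}) < 4:
            continue
        # choose the degree-ordered pairing: hook the highest-degree node
        # to the lowest-degree one, which minimises the product sum
        nodes = sorted({u, v, x, y}, key=lambda z: deg[z])
        a, b, c, d = nodes  # ascending degree
        new1, new2 = (a, d), (b, c)
        e1 = (min(new1), max(new1))
        e2 = (min(new2), max(new2))
        if e1 in edge_set or e2 in edge_set or e1 == e2:
            continue
        new_sxy = sxy - deg[u] * deg[v] - deg[x] * deg[y] \
            + deg[e1[0]] * deg[e1[1]] + deg[e2[0]] * deg[e2[1]]
        if new_sxy >= sxy:
            continue
        edge_set.discard((min(u, v), max(u, v)))
        edge_set.discard((min(x, y), max(x, y)))
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i] = e1
        edge_list[j] = e2
        sxy = new_sxy
        r = _pearson_from_product_sum((two_m, s1, s2), sxy)

    if np.isfinite(r) and r > target_assortativity:
        warnings.warn(
            f"rewiring budget exhausted at assortativity {r:.4f} > "
            f"target {target_assortativity}; returning best effort",
            stacklevel=2,
        )

    out = nx.Graph()
    out.add_nodes_from(range(n))
    out.add_edges_from(edge_set)
    return Graph(n=n, nx_graph=out, key_nodes=select_key_nodes(out, k))


def assortativity(g: Graph | nx.Graph) -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Each undirected edge contributes both orientations.  For graphs with
    zero degree variance (regular graphs) the correlation is undefined
    and NaN is returned rather than claiming any value.
    """
    nxg = g.nx_graph if isinstance(g, Graph) else g
    if nxg.number_of_edges() == 0:
        raise ValueError("assortativity requires at least one edge")
    deg = dict(nxg.degree())
    du = np.array([deg[u] for u, v in nxg.edges], dtype=float)
    dv = np.array([deg[v] for u, v in nxg.edges], dtype=float)
    x = np.concatenate([du, dv])
    y = np.concatenate([dv, du])
    if np.var(x) == 0 or np.var(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def write_edgelist(g: Graph, path) -> None:
    """Write tab-separated 0-based edge list, one undirected edge per line."""
    with open(path, "w") as fh:
        for u, v in sorted((min(e), max(e)) for e in g.nx_graph.edges):
            fh.write(f"{u}\t{v}\n")


def write_graphml(g: Graph, path) -> None:
    nx.write_graphml(g.nx_graph, path)


def read_graphml(path, k: int = 2) -> Graph:
    nxg = nx.read_graphml(path, node_type=int)
    g = nx.Graph()
    g.add_nodes_from(nxg.nodes)
    g.add_edges_from(nxg.edges)
    return Graph(n=g.number_of_nodes(), nx_graph=g, key_nodes=select_key_nodes(g, k))


def read_edgelist(path, k: int = 2) -> Graph:
    """Read a tab-separated edge list written by :func:`write_edgelist`."""
    nxg = nx.read_edgelist(path, delimiter="\t", nodetype=int)
    g = nx.Graph()
    g.add_nodes_from(range(max(nxg.nodes) + 1 if nxg.nodes else 0))
    g.add_edges_from(nxg.edges)
    return Graph(n=g.number_of_nodes(), nx_graph=g, key_nodes=select_key_nodes(g, k))
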