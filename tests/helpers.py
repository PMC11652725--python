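"""Independent oracles used by the tests: random linear-Gaussian DAGs, their
exact implied covariance, brute-force d-separation by path enumeration, and
the maximally oriented pattern of a DAG by exhaustive extension enumeration.

These deliberately avoid the package's own graph machinery so they can serve
as cross-checks for it.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd


def random_dag(rng: np.random.Generator, n_nodes: int = 8, p_edge: float = 0.3):
    """Random DAG over nodes v0..v{n-1} with edges respecting index order and
    coefficients of magnitude 0.4-0.9 (strong enough for finite-sample tests)."""
    names = [f"v{i}" for i in range(n_nodes)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    coefs = {}
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            c = rng.uniform(0.4, 0.9) * rng.choice([-1.0, 1.0])
            g.add_edge(names[i], names[j])
            coefs[(names[i], names[j])] = c
    return g, coefs


def sem_covariance(g: nx.DiGraph, coefs: dict, noise_sd: float = 1.0) -> pd.DataFrame:
    """Exact covariance of the linear-Gaussian SEM x = B^T x + e."""
    names = list(g.nodes)
    k = len(names)
    idx = {v: i for i, v in enumerate(names)}
    B = np.zeros((k, k))
    for (a, b), c in coefs.items():
        B[idx[a], idx[b]] = c
    inv = np.linalg.inv(np.eye(k) - B.T)
    cov = inv @ (noise_sd**2 * np.eye(k)) @ inv.T
    return pd.DataFrame(cov, index=names, columns=names)


def sample_sem(g: nx.DiGraph, coefs: dict, n: int, rng: np.random.Generator) -> pd.DataFrame:
    data = {}
    for v in nx.topological_sort(g):
        x = rng.standard_normal(n)
        for p in g.predecessors(v):
            x = x + coefs[(p, v)] * data[p]
        data[v] = x
    return pd.DataFrame({v: data[v] for v in g.nodes})


def true_markov_blanket(g: nx.DiGraph, v: str) -> frozenset:
    mb = set(g.predecessors(v)) | set(g.successors(v))
    for child in g.successors(v):
        mb |= set(g.predecessors(child))
    mb.discard(v)
    return frozenset(mb)


def brute_force_d_separated(g: nx.DiGraph, x: str, y: str, zs) -> bool:
    """d-separation by exhaustive enumeration of undirected simple paths."""
    zs = set(zs)
    skel = g.to_undirected()
    anc_of_z = set(zs)
    for z in zs:
        anc_of_z |= nx.ancestors(g, z)
    for path in nx.all_simple_paths(skel, x, y):
        blocked = False
        for a, w, b in zip(path, path[1:], path[2:]):
            collider = g.has_edge(a, w) and g.has_edge(b, w)
            if collider:
                if w not in anc_of_z:
                    blocked = True
                    break
            elif w in zs:
                blocked = True
                break
        if not blocked:
            return False
    return True


def _v_structures(g: nx.DiGraph) -> frozenset:
    out = set()
    for w in g.nodes:
        for a, b in itertools.combinations(sorted(g.predecessors(w)), 2):
            if not (g.has_edge(a, b) or g.has_edge(b, a)):
                out.add((a, w, b))
    return frozenset(out)


def cpdag_by_enumeration(g: nx.DiGraph):
    """Maximally oriented pattern of a DAG: enumerate every DAG on the same
    skeleton with the same unshielded colliders; an edge is compelled iff its
    orientation is constant across all of them.

    Returns (directed edge set, undirected frozenset-pair set).
    """
    edges = [tuple(sorted(e)) for e in g.to_undirected().edges]
    target_vs = _v_structures(g)
    orientations = []
    for mask in itertools.product((0, 1), repeat=len(edges)):
        h = nx.DiGraph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from((a, b) if m == 0 else (b, a) for (a, b), m in zip(edges, mask))
        if nx.is_directed_acyclic_graph(h) and _v_structures(h) == target_vs:
            orientations.append(mask)
    assert orientations, "true DAG must be among its own extensions"
    directed, undirected = set(), set()
    arr = np.asarray(orientations)
    for k, (a, b) in enumerate(edges):
        vals = set(arr[:, k])
        if vals == {0}:
            directed.add((a, b))
        elif vals == {1}:
            directed.add((b, a))
        else:
            undirected.add(frozenset((a, b)))
    return directed, undirected
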