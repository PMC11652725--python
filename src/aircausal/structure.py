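"""Constrained constraint-based structure learning.

Pipeline: Fisher-z partial-correlation conditional-independence tests ->
Grow-Shrink Markov blanket discovery per node -> skeleton from symmetrised
blankets (AND rule) with separating-set search -> edge orientation (forced
whitelist directions, collider rule, Meek rules 1-4, blacklist forcing),
yielding a partially directed acyclic graph (PDAG).

Constraints follow the study design: directed edges that must appear with a
fixed orientation (severity -> count outcome, wall thickness -> count
outcome) and nodes that may not receive incoming edges (age, sex).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstraintConflictError, DegenerateDataError
from .moments import Moments


# ---------------------------------------------------------------------------
# conditional-independence testing


@dataclass(frozen=True)
class CITestResult:
    x: str
    y: str
    z: tuple
    r: float
    stat: float
    p: float
    independent: bool


def _partial_correlation(R: np.ndarray, i: int, j: int, ks: tuple[int, ...]) -> float:
    """Partial correlation of variables i, j given ks, from a correlation (or
    covariance) matrix, by inverting the relevant submatrix."""
    idx = [i, j, *ks]
    sub = R[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise DegenerateDataError(f"singular conditioning submatrix for indices {idx}") from None
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise DegenerateDataError(f"degenerate conditioning set for indices {idx}")
    return float(-prec[0, 1] / math.sqrt(denom))


class FisherZTester:
    """Gaussian CI tester on a data frame: statistic
    sqrt(n - |Z| - 3) * atanh(r_xy.Z), two-sided normal p-value."""

    def __init__(self, data: pd.DataFrame, alpha: float = 0.05):
        self.columns = tuple(data.columns)
        self.alpha = float(alpha)
        self.n = len(data)
        arr = data.to_numpy(dtype=float)
        sds = arr.std(axis=0, ddof=1)
        if np.any(sds == 0):
            bad = [c for c, s in zip(self.columns, sds) if s == 0]
            raise DegenerateDataError(f"zero-variance columns: {bad}")
        self._R = np.corrcoef(arr, rowvar=False)
        self._idx = {c: k for k, c in enumerate(self.columns)}

    def test(self, x: str, y: str, z=()) -> CITestResult:
        z = tuple(z)
        if self.n <= len(z) + 3:
            raise DegenerateDataError(f"n={self.n} too small for |Z|={len(z)}")
        r = _partial_correlation(self._R, self._idx[x], self._idx[y], tuple(self._idx[v] for v in z))
        r_c = min(max(r, -1 + 1e-15), 1 - 1e-15)
        stat = math.sqrt(self.n - len(z) - 3) * math.atanh(r_c)
        p = 2 * stats.norm.sf(abs(stat))
        return CITestResult(x, y, z, r, float(stat), float(p), bool(p > self.alpha))


class OracleTester:
    """Population CI oracle answering from an exact covariance matrix.

    The independence decision is |partial correlation| < ``eps``. A small
    positive ``eps`` (default 1e-2) is needed because severity enters
    learning as its ordinal code while the structural shifts are per-group,
    leaving partial correlations of order 1e-3 on d-separated pairs routed
    through severity; true-edge partial correlations are two orders larger.
    """

    def __init__(self, cov: pd.DataFrame, eps: float = 1e-2):
        self.columns = tuple(cov.columns)
        self.eps = float(eps)
        self.n = None
        self._R = cov.to_numpy(dtype=float)
        self._idx = {c: k for k, c in enumerate(self.columns)}

    @classmethod
    def from_moments(cls, moments: Moments, nodes=None, eps: float = 1e-2) -> "OracleTester":
        cov = moments.cov
        if nodes is not None:
            cov = cov.loc[list(nodes), list(nodes)]
        return cls(cov, eps=eps)

    def test(self, x: str, y: str, z=()) -> CITestResult:
        z = tuple(z)
        r = _partial_correlation(self._R, self._idx[x], self._idx[y], tuple(self._idx[v] for v in z))
        independent = abs(r) < self.eps
        return CITestResult(x, y, z, r, math.inf if not independent else 0.0,
                            0.0 if not independent else 1.0, independent)


def fisher_z_test(data: pd.DataFrame, x: str, y: str, z=(), alpha: float = 0.05) -> CITestResult:
    """One-shot Fisher-z conditional-independence test on cohort columns."""
    cols = [x, y, *z]
    return FisherZTester(data[cols], alpha=alpha).test(x, y, z)


# ---------------------------------------------------------------------------
# constraints


@dataclass(frozen=True)
class ConstraintSet:
    """Directed-edge whitelist/blacklist plus 'no incoming edges' nodes."""

    whitelist: frozenset = frozenset()
    blacklist: frozenset = frozenset()
    no_incoming: frozenset = frozenset()

    def __post_init__(self):
        wl = frozenset(tuple(e) for e in self.whitelist)
        bl = frozenset(tuple(e) for e in self.blacklist)
        object.__setattr__(self, "whitelist", wl)
        object.__setattr__(self, "blacklist", bl)
        object.__setattr__(self, "no_incoming", frozenset(self.no_incoming))
        for a, b in wl:
            if b in self.no_incoming:
                raise ConstraintConflictError(f"whitelist edge {a}->{b} enters no-incoming node {b}")
        g = nx.DiGraph(wl)
        if not nx.is_directed_acyclic_graph(g):
            raise ConstraintConflictError("whitelist contains a directed cycle")

    def forbidden(self, a: str, b: str) -> bool:
        """Is the directed edge a->b disallowed?"""
        return (a, b) in self.blacklist or b in self.no_incoming

    def expanded_blacklist(self, nodes) -> frozenset:
        nodes = tuple(nodes)
        extra = {(a, b) for b in self.no_incoming for a in nodes if a != b}
        full = self.blacklist | extra
        if full & self.whitelist:
            clash = sorted(full & self.whitelist)
            raise ConstraintConflictError(f"whitelist/blacklist overlap: {clash}")
        return frozenset(full)


def default_constraints(outcome: str = "log_tac") -> ConstraintSet:
    """The study's constraints for one count outcome: fixed orientations
    severity->outcome and wall thickness->outcome; no edges into age or sex."""
    return ConstraintSet(
        whitelist=frozenset({("severity", outcome), ("log_wt", outcome)}),
        no_incoming=frozenset({"age", "sex"}),
    )


def load_constraints(path) -> ConstraintSet:
    """Read a JSON constraint file with keys whitelist / blacklist / no_incoming."""
    with open(path) as fh:
        raw = json.load(fh)
    return ConstraintSet(
        whitelist=frozenset(tuple(e) for e in raw.get("whitelist", [])),
        blacklist=frozenset(tuple(e) for e in raw.get("blacklist", [])),
        no_incoming=frozenset(raw.get("no_incoming", [])),
    )


# ---------------------------------------------------------------------------
# PDAG container


@dataclass
class Pdag:
    """Mixed graph: directed edges plus undirected leftovers."""

    nodes: tuple
    directed: frozenset = frozenset()
    undirected: frozenset = frozenset()  # frozensets of size 2
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.directed = frozenset(tuple(e) for e in self.directed)
        self.undirected = frozenset(frozenset(e) for e in self.undirected)
        dg = self.directed_graph()
        if not nx.is_directed_acyclic_graph(dg):
            raise ConstraintConflictError("directed part of PDAG contains a cycle")
        for a, b in self.directed:
            if frozenset((a, b)) in self.undirected:
                raise ConstraintConflictError(f"edge {a}-{b} both directed and undirected")

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": list(self.nodes),
                "directed": sorted(list(e) for e in self.directed),
                "undirected": sorted(sorted(e) for e in self.undirected),
                "meta": {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str, bool))},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Pdag":
        raw = json.loads(text)
        return cls(
            nodes=tuple(raw["nodes"]),
            directed=frozenset(tuple(e) for e in raw["directed"]),
            undirected=frozenset(frozenset(e) for e in raw["undirected"]),
            meta=raw.get("meta", {}),
        )

    def to_dot(self, name: str = "pdag") -> str:
        lines = [f"digraph {name} {{"]
        for node in self.nodes:
            lines.append(f'  "{node}";')
        for a, b in sorted(self.directed):
            lines.append(f'  "{a}" -> "{b}";')
        for e in sorted(sorted(pair) for pair in self.undirected):
            lines.append(f'  "{e[0]}" -> "{e[1]}" [dir=none];')
        lines.append("}")
        return "\n".join(lines)

    @classmethod
    def from_dot(cls, text: str) -> "Pdag":
        """Parse the DOT dialect written by :meth:`to_dot` (round-trip use)."""
        nodes, directed, undirected = [], set(), set()
        for line in text.splitlines():
            line = line.strip().rstrip(";")
            if not line or line.startswith(("digraph", "}")):
                continue
            if "->" in line:
                left, right = line.split("->")
                a = left.strip().strip('"')
                undir = "dir=none" in right
                b = right.split("[")[0].strip().strip('"')
                if undir:
                    undirected.add(frozenset((a, b)))
                else:
                    directed.add((a, b))
            else:
                nodes.append(line.strip('"'))
        return cls(tuple(nodes), frozenset(directed), frozenset(undirected))


# ---------------------------------------------------------------------------
# Grow-Shrink Markov blanket


def grow_shrink_mb(tester, target: str, order=None) -> tuple:
    """Grow-Shrink Markov blanket of ``target``.

    Grow: repeatedly sweep the variables in fixed order, adding any variable
    dependent on the target given the current blanket, until a full sweep
    adds nothing. Shrink: drop any member independent of the target given
    the rest. Deterministic given data and ordering.
    """
    order = tuple(order) if order is not None else tuple(tester.columns)
    blanket: list[str] = []
    changed = True
    while changed:
        changed = False
        for v in order:
            if v == target or v in blanket:
                continue
            if not tester.test(target, v, tuple(blanket)).independent:
                blanket.append(v)
                changed = True
    for v in list(blanket):
        rest = tuple(u for u in blanket if u != v)
        if tester.test(target, v, rest).independent:
            blanket.remove(v)
    return tuple(blanket)


def _subsets_smallest_first(pool):
    pool = tuple(sorted(pool))
    for size in range(len(pool) + 1):
        yield from itertools.combinations(pool, size)


def _find_sepset(tester, x: str, y: str, pool) -> tuple | None:
    for sub in _subsets_smallest_first(pool):
        if tester.test(x, y, sub).independent:
            return sub
    return None


def learn_skeleton(tester, nodes=None, constraints: ConstraintSet | None = None):
    """Skeleton + separating sets from symmetrised Grow-Shrink blankets.

    Returns ``(adjacencies, sepsets, blankets)`` where adjacencies is a set of
    frozenset pairs and sepsets maps frozenset pairs to the separating set
    found (smallest first, lexicographic tie-break, searched within the
    smaller candidate blanket). Whitelisted pairs are forced adjacent;
    pairs blacklisted in both directions are forced non-adjacent.
    """
    constraints = constraints or ConstraintSet()
    nodes = tuple(nodes) if nodes is not None else tuple(tester.columns)
    mbs = {v: frozenset(grow_shrink_mb(tester, v, order=nodes)) for v in nodes}

    adjacencies: set[frozenset] = set()
    sepsets: dict[frozenset, tuple] = {}
    wl_pairs = {frozenset(e) for e in constraints.whitelist}
    for x, y in itertools.combinations(nodes, 2):
        pair = frozenset((x, y))
        if pair in wl_pairs:
            adjacencies.add(pair)
            continue
        fully_blacklisted = constraints.forbidden(x, y) and constraints.forbidden(y, x)
        candidate = (y in mbs[x]) and (x in mbs[y])
        # search pool: the smaller blanket, excluding the pair itself
        pool_x = tuple(v for v in mbs[x] if v != y)
        pool_y = tuple(v for v in mbs[y] if v != x)
        if len(pool_x) < len(pool_y) or (len(pool_x) == len(pool_y) and x < y):
            pool = pool_x
        else:
            pool = pool_y
        sep = _find_sepset(tester, x, y, pool)
        if sep is not None:
            sepsets[pair] = sep
        if fully_blacklisted:
            continue
        if candidate and sep is None:
            adjacencies.add(pair)
    return adjacencies, sepsets, mbs


# ---------------------------------------------------------------------------
# orientation


def _creates_cycle(directed: set, a: str, b: str) -> bool:
    """Would adding a->b close a directed cycle? (depth-first from b to a)"""
    stack, seen = [b], set()
    while stack:
        v = stack.pop()
        if v == a:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(w for (u, w) in directed if u == v)
    return False


def _meek_pass(nodes, directed: set, undirected: set, constraints: ConstraintSet) -> bool:
    """One sweep of Meek rules 1-4. Returns True if anything was oriented."""

    def adjacent(a, b):
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    def orient(a, b):
        if constraints.forbidden(a, b):
            raise ConstraintConflictError(
                f"orientation {a}->{b} forced by propagation but blacklisted"
            )
        if _creates_cycle(directed, a, b):
            # finite-sample patterns can be internally inconsistent; a rule
            # application that would close a cycle is skipped
            return False
        undirected.discard(frozenset((a, b)))
        directed.add((a, b))
        return True

    for pair in sorted(undirected, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        for x, y in ((a, b), (b, a)):
            # R1: w -> x, x - y, w and y non-adjacent  =>  x -> y
            if any((w, x) in directed and not adjacent(w, y) and w != y for w in nodes):
                if orient(x, y):
                    return True
                continue
            # R2: x -> w -> y and x - y  =>  x -> y
            if any((x, w) in directed and (w, y) in directed for w in nodes):
                if orient(x, y):
                    return True
                continue
            # R3: x - w1 -> y, x - w2 -> y, w1/w2 non-adjacent  =>  x -> y
            spouses = [
                w
                for w in nodes
                if frozenset((x, w)) in undirected and (w, y) in directed
            ]
            if any(
                not adjacent(w1, w2)
                for w1, w2 in itertools.combinations(sorted(spouses), 2)
            ):
                if orient(x, y):
                    return True
                continue
            # R4: d -> c -> y with x adjacent to d and y/d non-adjacent  =>  x -> y
            if any(
                (d, c) in directed
                and (c, y) in directed
                and adjacent(x, d)
                and not adjacent(d, y)
                and d != x != c
                for d in nodes
                for c in nodes
            ):
                if orient(x, y):
                    return True
    return False


def orient_edges(nodes, adjacencies, sepsets, constraints: ConstraintSet | None = None,
                 meta: dict | None = None) -> Pdag:
    """Orient a skeleton into a PDAG.

    Order of operations: whitelist orientations; collider (v-structure) rule
    for unshielded triples whose separating set excludes the middle node,
    skipping any arm that is blacklisted or already directed the other way;
    blacklist forcing (an undirected edge with one forbidden direction takes
    the other); Meek rules 1-4 to closure. Raises on whitelist cycles or when
    propagation forces a blacklisted direction.
    """
    constraints = constraints or ConstraintSet()
    nodes = tuple(nodes)
    constraints.expanded_blacklist(nodes)  # validates whitelist/blacklist coherence
    directed: set = set()
    undirected: set = {frozenset(p) for p in adjacencies}

    for a, b in sorted(constraints.whitelist):
        if frozenset((a, b)) in undirected or (a, b) in directed:
            undirected.discard(frozenset((a, b)))
            directed.add((a, b))

    def adjacent(a, b):
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    def try_orient(a, b):
        if constraints.forbidden(a, b) or (b, a) in directed or _creates_cycle(directed, a, b):
            return
        undirected.discard(frozenset((a, b)))
        directed.add((a, b))

    # collider rule on unshielded triples
    for z in sorted(nodes):
        neigh = sorted(v for v in nodes if v != z and adjacent(v, z))
        for x, y in itertools.combinations(neigh, 2):
            if adjacent(x, y):
                continue
            sep = sepsets.get(frozenset((x, y)))
            if sep is None or z in sep:
                continue
            try_orient(x, z)
            try_orient(y, z)

    # blacklist forcing + Meek closure
    dropped: list = []
    changed = True
    while changed:
        changed = False
        for pair in sorted(undirected, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            fa, fb = constraints.forbidden(a, b), constraints.forbidden(b, a)
            if fa and fb:
                raise ConstraintConflictError(f"adjacency {a}-{b} blacklisted in both directions")
            if fa or fb:
                src, dst = (b, a) if fa else (a, b)
                undirected.discard(pair)
                if _creates_cycle(directed, src, dst):
                    dropped.append((src, dst))
                else:
                    directed.add((src, dst))
                changed = True
        while _meek_pass(nodes, directed, undirected, constraints):
            changed = True

    meta = dict(meta or {})
    if dropped:
        meta["dropped_contradictory_edges"] = sorted(dropped)
    pdag = Pdag(nodes, frozenset(directed), frozenset(undirected), meta)
    for a, b in constraints.whitelist:
        if a in nodes and b in nodes and (a, b) not in pdag.directed:
            raise ConstraintConflictError(f"whitelist edge {a}->{b} missing from result")
    bl = constraints.expanded_blacklist(nodes)
    violated = pdag.directed & bl
    if violated:
        raise ConstraintConflictError(f"blacklisted edges present: {sorted(violated)}")
    return pdag


def learn_pdag(
    data: pd.DataFrame | None = None,
    alpha: float = 0.05,
    constraints: ConstraintSet | None = None,
    nodes=None,
    tester=None,
) -> Pdag:
    """Full pipeline: Grow-Shrink blankets -> skeleton -> orientation.

    Either pass cohort ``data`` (Fisher-z tests at level ``alpha``) or a
    prebuilt ``tester`` (e.g. an :class:`OracleTester` on the generator's
    implied covariance). Deterministic for fixed inputs.
    """
    if tester is None:
        if data is None:
            raise ValueError("need data or tester")
        cols = list(nodes) if nodes is not None else list(data.columns)
        tester = FisherZTester(data[cols], alpha=alpha)
    nodes = tuple(nodes) if nodes is not None else tuple(tester.columns)
    adjacencies, sepsets, mbs = learn_skeleton(tester, nodes=nodes, constraints=constraints)
    meta = {
        "alpha": getattr(tester, "alpha", None),
        "n": tester.n,
        "blankets": {k: tuple(sorted(v)) for k, v in mbs.items()},
    }
    return orient_edges(nodes, adjacencies, sepsets, constraints, meta=meta)


# ---------------------------------------------------------------------------
# d-separation


def d_separated(graph, xs, ys, zs=()) -> bool:
    """d-separation of node sets on the directed part of a graph.

    ``graph`` may be a :class:`Pdag` (its directed subgraph is used) or a
    networkx DiGraph. Sets must be disjoint and present in the graph.
    """
    g = graph.directed_graph() if isinstance(graph, Pdag) else graph
    xs = {xs} if isinstance(xs, str) else set(xs)
    ys = {ys} if isinstance(ys, str) else set(ys)
    zs = {zs} if isinstance(zs, str) else set(zs)
    for node in xs | ys | zs:
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
    if (xs & ys) or (xs & zs) or (ys & zs):
        raise ValueError("node sets must be disjoint")
    return nx.is_d_separator(g, xs, ys, zs)
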