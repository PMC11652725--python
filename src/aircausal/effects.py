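"""Linear-Gaussian SEM fitting and direct/indirect/total effect decomposition.

The effect of COPD severity on a log airway count splits into a direct
pathway (attributed to narrowing/obliteration of small airways) and an
indirect pathway mediated by airway wall thickness (wall thinning reducing
CT detectability). Identification is graphical: the single-door criterion
gives the direct effect (regression adjustment set that d-separates severity
from the outcome once the direct edge is removed), the back-door criterion
gives the total effect, and the indirect effect is the product of fitted
path coefficients along severity -> wall thickness -> outcome. Severity
enters all effect regressions as three dummies against the preserved-lung-
function reference, so each pathway yields one coefficient per COPD group.

Log-scale coefficients are converted to percentage change via
(e^alpha - 1) * 100.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IdentifiabilityError, OrientationError
from .moments import LinearFit, Moments, regress
from .schema import SEVERITY_DUMMIES, Cohort
from .structure import Pdag, d_separated

GROUPS = ("mild", "moderate", "severe")
SEVERITY = "severity"


# ---------------------------------------------------------------------------
# graph plumbing


def _as_pdag(graph) -> Pdag:
    if isinstance(graph, Pdag):
        return graph
    if isinstance(graph, nx.DiGraph):
        return Pdag(tuple(graph.nodes), frozenset(graph.edges), frozenset())
    raise TypeError("graph must be a Pdag or networkx DiGraph")


def _effective_digraph(pdag: Pdag, x: str, y: str) -> nx.DiGraph:
    """Directed subgraph for effect estimation between x and y.

    Undirected edges are tolerated only if irrelevant: any undirected edge
    incident to x, y, or a node on a directed x->y path raises
    :class:`OrientationError`. Adjustment sets found on the directed part are
    afterwards re-verified under every orientation of the dropped undirected
    edges (see :func:`_verify_under_undirected`).
    """
    g = pdag.directed_graph()
    on_paths = {x, y}
    for path in nx.all_simple_paths(g, x, y):
        on_paths.update(path)
    for pair in pdag.undirected:
        if pair & on_paths:
            a, b = sorted(pair)
            raise OrientationError(
                f"edge {a}-{b} is undirected but touches the {x}->{y} effect machinery; "
                "orient it (whitelist) or drop it before effect estimation"
            )
    return g


def _verify_under_undirected(pdag: Pdag, check) -> bool:
    """Run ``check(digraph)`` under every acyclic orientation of the
    undirected edges; True only if all pass."""
    und = [tuple(sorted(p)) for p in sorted(pdag.undirected, key=lambda p: tuple(sorted(p)))]
    base = pdag.directed_graph()
    if not und:
        return check(base)
    for mask in itertools.product((0, 1), repeat=len(und)):
        g = base.copy()
        g.add_edges_from((a, b) if m == 0 else (b, a) for (a, b), m in zip(und, mask))
        if not nx.is_directed_acyclic_graph(g):
            continue
        if not check(g):
            return False
    return True


def _subsets(pool):
    pool = tuple(sorted(pool))
    for size in range(len(pool) + 1):
        yield from itertools.combinations(pool, size)


def single_door_set(graph, x: str = SEVERITY, y: str = "log_tac") -> tuple:
    """Minimal single-door adjustment set for the direct effect along x->y.

    Z contains no descendant of y and d-separates x from y in the graph with
    the edge x->y removed; among admissible sets the minimum-cardinality,
    lexicographically first one is returned (exhaustive subset search).
    """
    pdag = _as_pdag(graph)
    g = _effective_digraph(pdag, x, y)
    if not g.has_edge(x, y):
        raise IdentifiabilityError(f"no directed edge {x}->{y} in graph")

    def admissible(digraph: nx.DiGraph, z) -> bool:
        gm = digraph.copy()
        gm.remove_edge(x, y)
        if set(z) & (nx.descendants(digraph, y) | {y}):
            return False
        return d_separated(gm, x, y, z)

    forbidden = nx.descendants(g, y) | {x, y}
    pool = [v for v in g.nodes if v not in forbidden]
    for z in _subsets(pool):
        if admissible(g, z) and _verify_under_undirected(pdag, lambda gg: admissible(gg, z)):
            return z
    raise IdentifiabilityError(f"no admissible single-door set for {x}->{y}")


def back_door_set(graph, x: str = SEVERITY, y: str = "log_tac") -> tuple:
    """Minimal back-door adjustment set for the total effect of x on y.

    Z contains no descendant of x and blocks every back-door path (checked by
    d-separation on the graph with x's outgoing edges removed); same
    deterministic tie-break as :func:`single_door_set`.
    """
    pdag = _as_pdag(graph)
    g = _effective_digraph(pdag, x, y)

    def admissible(digraph: nx.DiGraph, z) -> bool:
        if set(z) & (nx.descendants(digraph, x) | {x}):
            return False
        gb = digraph.copy()
        gb.remove_edges_from(list(gb.out_edges(x)))
        return d_separated(gb, x, y, z)

    forbidden = nx.descendants(g, x) | {x, y}
    pool = [v for v in g.nodes if v not in forbidden]
    for z in _subsets(pool):
        if admissible(g, z) and _verify_under_undirected(pdag, lambda gg: admissible(gg, z)):
            return z
    raise IdentifiabilityError(f"no admissible back-door set for {x} -> {y}")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PathCoefficients:
    """Per-node OLS fits of the linear-Gaussian SEM on a directed graph."""

    fits: dict[str, LinearFit]
    n: int | None

    def coef(self, parent: str, child: str) -> float:
        return self.fits[child].coef[parent]

    def severity_coefs(self, child: str) -> dict[str, float]:
        """Per-group severity dummy coefficients in the child's equation."""
        fit = self.fits[child]
        return {g: fit.coef[dummy] for g, dummy in zip(GROUPS, SEVERITY_DUMMIES)}


def _as_moments(data, needed) -> Moments:
    if isinstance(data, Moments):
        missing = [c for c in needed if c not in data.variables]
        if missing:
            raise KeyError(f"moments lack variables {missing}")
        return data
    df = data.data if isinstance(data, Cohort) else data
    if SEVERITY in df.columns and any(d not in df.columns for d in SEVERITY_DUMMIES):
        df = df.copy()
        sev = df[SEVERITY].to_numpy()
        for level, col in zip((1, 2, 3), SEVERITY_DUMMIES):
            df[col] = (sev == level).astype(int)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"cohort lacks columns {missing}")
    return Moments.from_frame(df, [c for c in needed if c in df.columns])


def _expand_severity(parents) -> list[str]:
    out = []
    for p in parents:
        out.extend(SEVERITY_DUMMIES if p == SEVERITY else [p])
    return out


def fit_sem(graph, data, severity_mode: str = "dummies") -> PathCoefficients:
    """OLS of every endogenous node on its graph parents.

    Wherever severity is a parent it enters as the three group dummies
    (``severity_mode="ordinal"`` keeps the 0-3 code instead). ``data`` may be
    a Cohort, a plain data frame, or exact population :class:`Moments`.
    """
    pdag = _as_pdag(graph)
    g = pdag.directed_graph()
    endogenous = [v for v in g.nodes if g.in_degree(v) > 0]
    needed = set()
    for v in g.nodes:
        needed.add(v)
    if severity_mode == "dummies" and SEVERITY in g.nodes:
        needed.update(SEVERITY_DUMMIES)
    moments = _as_moments(data, sorted(needed))
    fits = {}
    for v in sorted(endogenous):
        parents = sorted(g.predecessors(v))
        xs = _expand_severity(parents) if severity_mode == "dummies" else parents
        fits[v] = regress(moments, v, xs)
    for v in sorted(set(g.nodes) - set(endogenous)):
        fits[v] = regress(moments, v, ())
    return PathCoefficients(fits=fits, n=moments.n)


def _effect_regression(moments: Moments, outcome: str, adjust) -> dict[str, float]:
    xs = list(SEVERITY_DUMMIES) + [z for z in adjust if z != SEVERITY]
    fit = regress(moments, outcome, xs)
    return {g: fit.coef[dummy] for g, dummy in zip(GROUPS, SEVERITY_DUMMIES)}


def direct_effect(graph, data, outcome: str = "log_tac", x: str = SEVERITY,
                  adjustment: str = "minimal") -> dict[str, float]:
    """Per-group direct effects a_g: OLS of the outcome on the severity
    dummies plus a single-door adjustment set.

    ``adjustment="minimal"`` uses the minimum-cardinality single-door set;
    ``"parents"`` adjusts for all other parents of the outcome (a superset
    that is also single-door admissible in the reference graph).
    """
    pdag = _as_pdag(graph)
    if adjustment == "minimal":
        z = single_door_set(pdag, x, outcome)
    elif adjustment == "parents":
        g = _effective_digraph(pdag, x, outcome)
        if not g.has_edge(x, outcome):
            raise IdentifiabilityError(f"no directed edge {x}->{outcome} in graph")
        z = tuple(sorted(set(g.predecessors(outcome)) - {x}))
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    moments = _as_moments(data, sorted({outcome, *SEVERITY_DUMMIES, *z}))
    return _effect_regression(moments, outcome, z)


def total_effect(graph, data, outcome: str = "log_tac", x: str = SEVERITY) -> dict[str, float]:
    """Per-group total effects t_g: OLS of the outcome on the severity
    dummies plus a back-door adjustment set (mediators excluded)."""
    pdag = _as_pdag(graph)
    z = back_door_set(pdag, x, outcome)
    moments = _as_moments(data, sorted({outcome, *SEVERITY_DUMMIES, *z}))
    return _effect_regression(moments, outcome, z)


def indirect_effect(coeffs: PathCoefficients, graph, outcome: str = "log_tac",
                    x: str = SEVERITY) -> dict[str, float]:
    """Product-of-path-coefficients indirect effects bd_g, summed over every
    directed mediated path x -> m1 -> ... -> outcome.

    The first hop contributes the per-group severity dummy coefficient in the
    mediator's equation; subsequent hops contribute ordinary parent
    coefficients. The reference graph has exactly one mediated path,
    severity -> log wall thickness -> outcome."""
    pdag = _as_pdag(graph)
    g = _effective_digraph(pdag, x, outcome)
    totals = {grp: 0.0 for grp in GROUPS}
    n_paths = 0
    for path in nx.all_simple_paths(g, x, outcome):
        if len(path) < 3:
            continue  # the direct edge is not a mediated path
        n_paths += 1
        first = coeffs.severity_coefs(path[1])
        rest = 1.0
        for a, b in zip(path[1:-1], path[2:]):
            rest *= coeffs.coef(a, b)
        for grp in GROUPS:
            totals[grp] += first[grp] * rest
    if n_paths == 0:
        raise IdentifiabilityError(f"no mediated directed path from {x} to {outcome}")
    return totals


def percent_change(alpha: float) -> float:
    """Translate a log-scale coefficient into percentage change: (e^a - 1)*100."""
    if not math.isfinite(alpha):
        raise ValueError("coefficient must be finite")
    return (math.exp(alpha) - 1.0) * 100.0


def percent_decline(alpha: float) -> float:
    """Decline magnitude (1 - e^a)*100; positive for negative coefficients."""
    return -percent_change(alpha)


# ---------------------------------------------------------------------------
# decomposition bundle


@dataclass
class EffectDecomposition:
    outcome: str
    direct: dict[str, float]
    indirect: dict[str, float]
    total: dict[str, float]
    direct_parents_adjusted: dict[str, float]
    single_door: tuple
    back_door: tuple
    n: int | None
    meta: dict = field(default_factory=dict)

    @property
    def consistency_delta(self) -> dict[str, float]:
        """total - direct - indirect per group (0 in a correctly specified
        linear SEM at the population level)."""
        return {g: self.total[g] - self.direct[g] - self.indirect[g] for g in GROUPS}

    @property
    def indirect_difference(self) -> dict[str, float]:
        """Difference-method indirect effect, total - direct (cross-check)."""
        return {g: self.total[g] - self.direct[g] for g in GROUPS}

    def percent_declines(self) -> pd.DataFrame:
        rows = []
        for grp in GROUPS:
            rows.append(
                {
                    "group": grp,
                    "direct_coef": self.direct[grp],
                    "indirect_coef": self.indirect[grp],
                    "total_coef": self.total[grp],
                    "direct_decline_pct": percent_decline(self.direct[grp]),
                    "indirect_decline_pct": percent_decline(self.indirect[grp]),
                    "total_decline_pct": percent_decline(self.total[grp]),
                }
            )
        return pd.DataFrame(rows)

    def dominant_pathway(self) -> dict[str, str]:
        """Which pathway dominates the loss, per COPD group."""
        return {
            g: ("indirect" if abs(self.indirect[g]) > abs(self.direct[g]) else "direct")
            for g in GROUPS
        }

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "direct": self.direct,
            "indirect": self.indirect,
            "total": self.total,
            "direct_parents_adjusted": self.direct_parents_adjusted,
            "indirect_difference": self.indirect_difference,
            "consistency_delta": self.consistency_delta,
            "single_door_set": list(self.single_door),
            "back_door_set": list(self.back_door),
            "percent_declines": self.percent_declines().to_dict(orient="records"),
            "dominant_pathway": self.dominant_pathway(),
            "n": self.n,
        }


def decompose(graph, data, outcome: str = "log_tac", x: str = SEVERITY) -> EffectDecomposition:
    """Full decomposition: direct (single-door), total (back-door), indirect
    (product method) per COPD group, plus percentage declines and the
    consistency delta total - direct - indirect."""
    pdag = _as_pdag(graph)
    sd = single_door_set(pdag, x, outcome)
    bd = back_door_set(pdag, x, outcome)
    needed = sorted({outcome, x, *SEVERITY_DUMMIES, *sd, *bd, *pdag.nodes})
    moments = _as_moments(data, needed)
    coeffs = fit_sem(pdag, moments)
    direct = _effect_regression(moments, outcome, sd)
    total = _effect_regression(moments, outcome, bd)
    indirect = indirect_effect(coeffs, pdag, outcome, x)
    g = _effective_digraph(pdag, x, outcome)
    parents_z = tuple(sorted(set(g.predecessors(outcome)) - {x}))
    direct_parents = _effect_regression(moments, outcome, parents_z)
    return EffectDecomposition(
        outcome=outcome,
        direct=direct,
        indirect=indirect,
        total=total,
        direct_parents_adjusted=direct_parents,
        single_door=sd,
        back_door=bd,
        n=moments.n,
    )
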