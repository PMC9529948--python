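"""Directed cohort friendship graphs and social network position metrics.

A roster-based friendship survey yields, for each cohort, a directed,
unweighted, simple graph: an edge ego -> alter means "ego nominated alter
as a friend".  Five position characteristics are computed per subject:

* out-degree — number of nominations made;
* in-degree — number of nominations received;
* eigenvector centrality — prestige score from the leading eigenvector of
  the incoming-tie relation (x_i proportional to the summed scores of i's
  nominators);
* betweenness centrality — fraction of shortest paths through the node on
  the symmetrized (undirected) graph, unnormalized;
* Burt constraint — sum over direct contacts j of
  (P_ij + sum_q P_iq P_qj)^2, with P_ij the proportion of i's ties going
  to j and q running over mutual contacts, on the symmetrized graph.
  Its negation is the local brokerage score.

Before modeling, each metric is square-root transformed (sign-preserving)
and z-scored within cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

__all__ = [
    "DirectedCohortGraph",
    "build_graph",
    "out_degree",
    "in_degree",
    "eigenvector_centrality",
    "betweenness_centrality",
    "constraint",
    "constraint_all",
    "network_summary",
    "position_profiles",
    "transform_metrics",
    "METRICS",
]

#: The five position characteristics entering the predictive models.
METRICS = ("out_degree", "in_degree", "eigenvector", "betweenness", "constraint")


@dataclass
class DirectedCohortGraph:
    """Simple directed friendship graph for one cohort.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    declared node.  Surveyed subjects with no ties are retained as isolated
    nodes.
    """

    cohort_id: str
    nodes: list = field(default_factory=list)
    edges: set = field(default_factory=set)

    def __post_init__(self):
        self.nodes = list(self.nodes)
        self._index = {v: k for k, v in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        self.edges = set(self.edges)
        for ego, alter in self.edges:
            if ego == alter:
                raise ValueError(f"self-loop at node {ego!r}")
            if ego not in self._index or alter not in self._index:
                raise ValueError(f"edge ({ego!r}, {alter!r}) references undeclared node")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index_of(self, node) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r} in cohort {self.cohort_id!r}") from None

    def adjacency(self) -> np.ndarray:
        """Binary adjacency matrix A with A[i, j] = 1 iff i nominated j."""
        a = np.zeros((self.n, self.n))
        for ego, alter in self.edges:
            a[self._index[ego], self._index[alter]] = 1.0
        return a

    def symmetrized_adjacency(self) -> np.ndarray:
        """Any tie, in either direction, counts as an undirected edge."""
        a = self.adjacency()
        return np.maximum(a, a.T)


def build_graph(edge_records, cohort, roster=None) -> DirectedCohortGraph:
    """Build the directed cohort graph from survey edge records.

    Parameters
    ----------
    edge_records : iterable of (ego, alter) or (ego, alter, cohort)
        Three-element records are filtered to the requested cohort.
    cohort : label
        Cohort to build.  If three-element records are supplied and none
        matches, a ``KeyError`` is raised (unknown cohort).
    roster : iterable, optional
        Full list of surveyed subjects; isolated subjects are retained as
        nodes even if they made and received no nominations.

    Self-nominations are rejected with a warning; duplicate nominations are
    collapsed (simple graph).
    """
    records = list(edge_records)
    tagged = [r for r in records if len(r) >= 3]
    if tagged:
        matching = [r[:2] for r in tagged if r[2] == cohort]
        if not matching and all(len(r) >= 3 for r in records):
            seen = sorted({str(r[2]) for r in tagged})
            raise KeyError(f"unknown cohort {cohort!r}; cohorts present: {seen}")
        pairs = matching + [r[:2] for r in records if len(r) == 2]
    else:
        pairs = [r[:2] for r in records]

    edges = set()
    for ego, alter in pairs:
        if ego == alter:
            warnings.warn(f"dropping self-nomination by {ego!r}", stacklevel=2)
            continue
        edges.add((ego, alter))
    nodes = list(roster) if roster is not None else []
    known = set(nodes)
    for ego, alter in sorted(edges, key=repr):
        for v in (ego, alter):
            if v not in known:
                known.add(v)
                nodes.append(v)
    return DirectedCohortGraph(cohort_id=cohort, nodes=nodes, edges=edges)


def out_degree(g: DirectedCohortGraph, node) -> int:
    """Number of outgoing nominations made by ``node``."""
    g.index_of(node)  # raises for unknown node
    return sum(1 for ego, _ in g.edges if ego == node)


def in_degree(g: DirectedCohortGraph, node) -> int:
    """Number of incoming nominations received by ``node``."""
    g.index_of(node)
    return sum(1 for _, alter in g.edges if alter == node)


def _is_dag(g: DirectedCohortGraph) -> bool:
    h = ig.Graph(n=g.n, edges=[(g.index_of(e), g.index_of(a)) for e, a in g.edges],
                 directed=True)
    return h.is_dag()


def eigenvector_centrality(g: DirectedCohortGraph, tol: float = 1e-10,
                           max_iter: int = 10_000) -> dict:
    """Eigenvector centrality from incoming ties only.

    Scores solve x_i proportional to sum_{j: j->i} x_j, i.e. the leading
    eigenvector of A^T, computed by shifted power iteration (A^T + I, which
    has the same eigenvectors but no periodicity problems), started from a
    uniform positive vector.  Scores are nonnegative and normalized so the
    maximum equals 1.

    An edgeless graph raises ``ValueError`` ("centrality undefined").  A
    nilpotent adjacency (the directed graph is acyclic, leading eigenvalue
    0) is degenerate: all-zero scores are returned with a warning.
    """
    if not g.edges:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    if _is_dag(g):
        warnings.warn(
            f"cohort {g.cohort_id!r}: adjacency is nilpotent (acyclic digraph); "
            "eigenvector centrality degenerate, returning all-zero scores",
            stacklevel=2,
        )
        return {v: 0.0 for v in g.nodes}
    at = g.adjacency().T
    x = np.ones(g.n)
    for _ in range(max_iter):
        y = at @ x + x
        y /= y.max()
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x = np.maximum(x, 0.0)
    x /= x.max()
    return {v: float(x[k]) for k, v in enumerate(g.nodes)}


def _undirected_igraph(g: DirectedCohortGraph) -> ig.Graph:
    pairs = {(min(g.index_of(e), g.index_of(a)),
              max(g.index_of(e), g.index_of(a)))
             for e, a in g.edges}
    return ig.Graph(n=g.n, edges=sorted(pairs), directed=False)


def betweenness_centrality(g: DirectedCohortGraph) -> dict:
    """Unnormalized shortest-path betweenness on the symmetrized graph.

    Each unordered pair (s, t) contributes sigma_st(v)/sigma_st, splitting
    multiplicity across equally short paths (Freeman/Brandes).  Isolates
    score 0.  The overall scale is irrelevant downstream because metrics
    are z-scored before modeling.
    """
    h = _undirected_igraph(g)
    scores = h.betweenness(directed=False)
    return {v: float(scores[k]) for k, v in enumerate(g.nodes)}


def constraint_all(g: DirectedCohortGraph) -> dict:
    """Burt constraint for every node, on the symmetrized graph.

    Constraint_i = sum over direct contacts j of (P_ij + sum_q P_iq P_qj)^2,
    where P_ij = A_ij / deg(i) and q ranges over mutual contacts of i and j.
    Isolates have undefined constraint and map to NaN.
    """
    a = g.symmetrized_adjacency()
    deg = a.sum(axis=1)
    p = np.divide(a, deg[:, None], out=np.zeros_like(a), where=deg[:, None] > 0)
    m = p + p @ p  # diagonal of P is 0, so q = i, j contribute nothing
    c = ((m * m) * a).sum(axis=1)
    c[deg == 0] = np.nan
    return {v: float(c[k]) for k, v in enumerate(g.nodes)}


def constraint(g: DirectedCohortGraph, node) -> float:
    """Burt constraint of one node (NaN for isolates, with a warning)."""
    val = constraint_all(g)[node]
    if np.isnan(val):
        warnings.warn(
            f"node {node!r} is an isolate: constraint undefined, returning NaN "
            "(subject excluded from constraint-based modeling)",
            stacklevel=2,
        )
    return val


def network_summary(g: DirectedCohortGraph) -> dict:
    """Descriptive summary: mean/median total degree and reciprocity.

    Total degree counts incoming plus outgoing ties per node.  Reciprocity
    is the fraction of directed edges whose reverse edge also exists; it is
    NaN (undefined) on an edgeless graph.
    """
    total = np.zeros(g.n)
    for ego, alter in g.edges:
        total[g.index_of(ego)] += 1
        total[g.index_of(alter)] += 1
    if g.edges:
        recip = sum(1 for e, a in g.edges if (a, e) in g.edges) / len(g.edges)
    else:
        recip = float("nan")
    return {
        "mean_total_degree": float(total.mean()) if g.n else float("nan"),
        "median_total_degree": float(np.median(total)) if g.n else float("nan"),
        "reciprocity": recip,
    }


def position_profiles(g: DirectedCohortGraph) -> pd.DataFrame:
    """Raw position characteristics for every node of one cohort graph.

    Returns a DataFrame indexed by subject id with columns ``cohort``, the
    five metrics, and ``brokerage`` (negated constraint, NaN for isolates).
    """
    a = g.adjacency()
    eig = (eigenvector_centrality(g) if g.edges
           else {v: 0.0 for v in g.nodes})
    bet = betweenness_centrality(g)
    con = constraint_all(g)
    rows = {
        "cohort": [g.cohort_id] * g.n,
        "out_degree": a.sum(axis=1),
        "in_degree": a.sum(axis=0),
        "eigenvector": [eig[v] for v in g.nodes],
        "betweenness": [bet[v] for v in g.nodes],
        "constraint": [con[v] for v in g.nodes],
    }
    df = pd.DataFrame(rows, index=pd.Index(g.nodes, name="subject_id"))
    df["brokerage"] = -df["constraint"]
    return df


def transform_metrics(raw: pd.DataFrame, order: str = "sqrt_then_z",
                      metrics=None) -> pd.DataFrame:
    """Within-cohort transform applied to raw metrics before modeling.

    Default order ``"sqrt_then_z"``: a sign-preserving square root
    (sign(x) * sqrt(|x|), plain sqrt for the nonnegative metrics; for
    brokerage this equals minus the square root of raw constraint) followed
    by a within-cohort z-score (population-sd convention).  The alternative
    ``"z_then_signed_sqrt"`` z-scores first and then applies the signed
    square root; its output is not unit-variance.

    ``raw`` must contain a ``cohort`` column; NaN metric values (isolate
    constraint) are ignored when estimating cohort moments and propagated.

    Raises ``ValueError`` if a metric is constant within a cohort or a
    cohort has fewer than two subjects with observed values.
    """
    if "cohort" not in raw.columns:
        raise ValueError("raw metric table must contain a 'cohort' column")
    if metrics is None:
        metrics = [c for c in raw.columns if c != "cohort"]
    out = raw.copy()

    def _signed_sqrt(v):
        return np.sign(v) * np.sqrt(np.abs(v))

    for metric in metrics:
        col = raw[metric].astype(float)
        for cohort, idx in raw.groupby("cohort").groups.items():
            v = col.loc[idx].to_numpy()
            observed = v[~np.isnan(v)]
            if observed.size < 2:
                raise ValueError(
                    f"metric {metric!r}, cohort {cohort!r}: need >= 2 observed values"
                )
            if np.nanstd(v) == 0:
                raise ValueError(
                    f"metric {metric!r} is constant within cohort {cohort!r}: "
                    "z-score undefined"
                )
            if order == "sqrt_then_z":
                from .stats import zscore
                out.loc[idx, metric] = zscore(_signed_sqrt(v), nan_policy="omit")
            elif order == "z_then_signed_sqrt":
                from .stats import zscore
                out.loc[idx, metric] = _signed_sqrt(zscore(v, nan_policy="omit"))
            else:
                raise ValueError(f"unknown transform order {order!r}")
    return out
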