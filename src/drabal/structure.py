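"""Constraint-based learning of a label-dependency DAG over assay labels.

Dependencies between assay outcomes are modelled as a Bayesian network: a DAG
whose nodes are the assay labels.  The structure is learned from the
(incomplete) label matrix by conditional-independence testing — two labels
y_i, y_j are declared conditionally independent given a conditioning set S
when a stratified G-test (log-likelihood-ratio test summed over the observed
configurations of S, with +0.5 Laplace smoothing of cell counts) fails to
reject at level alpha.  The skeleton search enumerates conditioning subsets of
the full remainder (all labels other than i and j) in increasing size; edges
surviving every test are kept, v-structures are oriented from separating
sets, Meek rules propagate orientations, and any residual undirected edge is
oriented deterministically (lower assay id -> higher) without creating a
cycle.

Rows with a missing value in any label involved in a test are excluded from
that test (pairwise-complete deletion): missingness is never treated as a
third category, so the test never picks up dependence with the missingness
mechanism.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import chi2

from .exceptions import InsufficientDataError, ParameterError, StructureError

logger = logging.getLogger(__name__)

MISSING = 0


@dataclass
class CITestResult:
    """Outcome of one conditional-independence test between two labels."""

    label_i: int
    label_j: int
    conditioning_set: tuple[int, ...]
    statistic: float
    df: int
    p_value: float
    independent: bool
    n_effective: int
    n_skipped_strata: int = 0


@dataclass
class LabelDependencyGraph:
    """DAG over assay labels with the CI-test provenance that produced it."""

    nodes: list[str]
    edges: set[tuple[str, str]] = field(default_factory=set)
    alpha: float | None = None
    provenance: list[CITestResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for parent, child in self.edges:
            if parent not in node_set or child not in node_set:
                raise ParameterError(f"edge ({parent}, {child}) references unknown node")
        if not nx.is_directed_acyclic_graph(self._nx()):
            raise StructureError("label dependency graph must be acyclic")

    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents_of(self, node: str) -> set[str]:
        """Tails of all edges into ``node``."""
        if node not in set(self.nodes):
            raise ParameterError(f"unknown node {node!r}")
        return {p for p, c in self.edges if c == node}

    def topological_order(self) -> list[str]:
        """Parents before children; ties broken by ascending assay id."""
        try:
            return list(nx.lexicographical_topological_sort(self._nx()))
        except nx.NetworkXUnfeasible as exc:  # pragma: no cover - guarded in init
            raise StructureError("cycle detected") from exc

    # ------------------------------------------------------------------ I/O
    def to_files(self, edge_path: str | Path, meta_path: str | Path) -> None:
        with open(edge_path, "w") as fh:
            for parent, child in sorted(self.edges):
                fh.write(f"{parent}\t{child}\n")
        meta = {
            "nodes": self.nodes,
            "alpha": self.alpha,
            "n_tests": len(self.provenance),
            "tests": [
                {
                    "i": t.label_i, "j": t.label_j, "S": list(t.conditioning_set),
                    "G": t.statistic, "df": t.df, "p": t.p_value,
                    "independent": t.independent, "n": t.n_effective,
                    "skipped_strata": t.n_skipped_strata,
                }
                for t in self.provenance
            ],
        }
        Path(meta_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, edge_path: str | Path, meta_path: str | Path | None = None
                   ) -> "LabelDependencyGraph":
        edges = set()
        nodes: list[str] = []
        for line in Path(edge_path).read_text().splitlines():
            if not line.strip():
                continue
            parent, child = line.split("\t")
            edges.add((parent, child))
        alpha = None
        if meta_path is not None:
            meta = json.loads(Path(meta_path).read_text())
            nodes = meta["nodes"]
            alpha = meta.get("alpha")
        if not nodes:
            nodes = sorted({n for e in edges for n in e})
        return cls(nodes=nodes, edges=edges, alpha=alpha)


# --------------------------------------------------------------------------
# G-test machinery
# --------------------------------------------------------------------------

def _g_statistic_2x2(table: np.ndarray, smoothing: float = 0.5) -> float:
    """Log-likelihood-ratio statistic for a 2x2 contingency table.

    ``smoothing`` is added to every cell before computing observed and
    expected counts, which keeps the statistic finite for empty cells.
    """
    obs = np.asarray(table, dtype=float) + smoothing
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return float(2.0 * (obs * np.log(obs / expected)).sum())


def ci_test(
    labels: np.ndarray,
    i: int,
    j: int,
    conditioning_set: Iterable[int] = (),
    alpha: float = 0.05,
    *,
    min_stratum_rows: int = 5,
    min_rows: int = 10,
    smoothing: float = 0.5,
) -> CITestResult:
    """Stratified G-test of conditional independence between label columns.

    The statistic is the sum of per-stratum 2x2 G-statistics over the
    configurations of the conditioning labels, with one degree of freedom per
    stratum used; strata holding fewer than ``min_stratum_rows`` rows are
    skipped and counted.  Rows missing any involved label are excluded.
    """
    labels = np.asarray(labels)
    S = tuple(sorted(set(conditioning_set)))
    if i == j:
        raise ParameterError("i and j must differ")
    if i in S or j in S:
        raise ParameterError("conditioning set must exclude i and j")
    involved = (i, j) + S
    complete = (labels[:, involved] != MISSING).all(axis=1)
    sub = labels[complete][:, involved]
    n_eff = int(sub.shape[0])
    if n_eff < min_rows:
        raise InsufficientDataError(
            f"test ({i},{j}|{S}): only {n_eff} complete rows (< {min_rows})"
        )

    yi = (sub[:, 0] == 1).astype(np.intp)
    yj = (sub[:, 1] == 1).astype(np.intp)
    if S:
        conf = ((sub[:, 2:] == 1).astype(np.intp) * (1 << np.arange(len(S)))).sum(axis=1)
    else:
        conf = np.zeros(n_eff, dtype=np.intp)

    stat, df, skipped = 0.0, 0, 0
    for key in np.unique(conf):
        mask = conf == key
        n_s = int(mask.sum())
        if n_s < min_stratum_rows:
            skipped += 1
            continue
        table = np.bincount(2 * yi[mask] + yj[mask], minlength=4).reshape(2, 2)
        stat += _g_statistic_2x2(table, smoothing)
        df += 1
    if df == 0:
        raise InsufficientDataError(
            f"test ({i},{j}|{S}): all {skipped} strata below {min_stratum_rows} rows"
        )
    if skipped:
        logger.debug("ci_test (%d,%d|%s): skipped %d small strata", i, j, S, skipped)
    p = float(chi2.sf(stat, df))
    return CITestResult(
        label_i=i, label_j=j, conditioning_set=S, statistic=stat, df=df,
        p_value=p, independent=p > alpha, n_effective=n_eff,
        n_skipped_strata=skipped,
    )


# --------------------------------------------------------------------------
# structure learning
# --------------------------------------------------------------------------

def _meek_rules(directed: set[tuple[int, int]], undirected: set[frozenset[int]],
                nodes: Sequence[int]) -> None:
    """Apply Meek's orientation-propagation rules in place until fixpoint."""

    def orient(a: int, b: int) -> bool:
        e = frozenset((a, b))
        if e in undirected:
            undirected.discard(e)
            directed.add((a, b))
            return True
        return False

    def adjacent(a: int, b: int) -> bool:
        return (a, b) in directed or (b, a) in directed or frozenset((a, b)) in undirected

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, z not adjacent y  =>  x -> y
                if any((z, x) in directed and not adjacent(z, y)
                       for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R2: directed path x -> z -> y  =>  x -> y
                if any((x, z) in directed and (z, y) in directed
                       for z in nodes if z not in (x, y)):
                    changed |= orient(x, y)
                    break
                # R3: x - z1 -> y, x - z2 -> y, z1/z2 non-adjacent  =>  x -> y
                zs = [z for z in nodes if z not in (x, y)
                      and frozenset((x, z)) in undirected and (z, y) in directed]
                if any(not adjacent(z1, z2)
                       for z1, z2 in itertools.combinations(zs, 2)):
                    changed |= orient(x, y)
                    break
            if changed:
                break


def learn_structure(
    labels: np.ndarray,
    alpha: float = 0.05,
    *,
    assay_ids: Sequence[str] | None = None,
    max_cond_size: int | None = None,
    min_stratum_rows: int = 5,
    min_rows: int = 10,
) -> LabelDependencyGraph:
    """Learn a label-dependency DAG from an M x N label matrix over {+1,-1,0}.

    Skeleton: an edge i-j is removed as soon as some conditioning subset of
    the remaining labels (enumerated by increasing size, up to
    ``max_cond_size`` or the full remainder) renders i and j independent at
    level ``alpha``.  Orientation: v-structures from separating sets, Meek
    rules, then a deterministic lower-id -> higher-id tie-break for residual
    undirected edges, refusing any orientation that would close a cycle.
    """
    labels = np.asarray(labels)
    N = labels.shape[1]
    if assay_ids is None:
        assay_ids = [str(c) for c in range(N)]
    if len(assay_ids) != N:
        raise ParameterError("assay_ids length must match label columns")
    idx_order = sorted(range(N), key=lambda c: assay_ids[c])

    provenance: list[CITestResult] = []
    if N == 1:
        return LabelDependencyGraph(nodes=list(assay_ids), edges=set(), alpha=alpha)

    max_size = N - 2 if max_cond_size is None else min(max_cond_size, N - 2)
    undirected: set[frozenset[int]] = {
        frozenset(p) for p in itertools.combinations(range(N), 2)
    }
    sepset: dict[frozenset[int], tuple[int, ...]] = {}

    for i, j in itertools.combinations(range(N), 2):
        rest = [c for c in range(N) if c not in (i, j)]
        for size in range(max_size + 1):
            removed = False
            for S in itertools.combinations(rest, size):
                try:
                    res = ci_test(
                        labels, i, j, S, alpha,
                        min_stratum_rows=min_stratum_rows, min_rows=min_rows,
                    )
                except InsufficientDataError:
                    if size == 0:
                        raise  # no usable data for the pair at all
                    continue  # deeper stratification ran dry; no evidence either way
                provenance.append(res)
                if res.independent:
                    undirected.discard(frozenset((i, j)))
                    sepset[frozenset((i, j))] = S
                    removed = True
                    break
            if removed:
                break

    # v-structures: i - k - j with i,j non-adjacent and k outside sepset(i, j)
    directed: set[tuple[int, int]] = set()
    conflicted: set[frozenset[int]] = set()
    for i, j in itertools.combinations(range(N), 2):
        pair = frozenset((i, j))
        if pair not in sepset:
            continue
        S = sepset[pair]
        for k in range(N):
            if k in (i, j) or k in S:
                continue
            if frozenset((i, k)) in undirected and frozenset((j, k)) in undirected:
                for tail in (i, j):
                    if (k, tail) in directed:
                        conflicted.add(frozenset((tail, k)))
                    else:
                        directed.add((tail, k))
    for e in conflicted:  # contradictory collider claims: leave undirected
        a, b = e
        directed.discard((a, b))
        directed.discard((b, a))
        undirected.add(e)
    undirected -= {frozenset((a, b)) for a, b in directed}

    _meek_rules(directed, undirected, idx_order)

    # residual edges: lower assay id -> higher, unless that closes a cycle
    g = nx.DiGraph()
    g.add_nodes_from(range(N))
    g.add_edges_from(directed)
    if not nx.is_directed_acyclic_graph(g):  # collider conflicts can in principle cycle
        raise StructureError("orientation produced a cyclic graph")
    for e in sorted(undirected, key=lambda e: sorted(assay_ids[c] for c in e)):
        a, b = sorted(e, key=lambda c: assay_ids[c])
        if nx.has_path(g, b, a):
            g.add_edge(b, a)
        else:
            g.add_edge(a, b)

    edges = {(assay_ids[a], assay_ids[b]) for a, b in g.edges}
    graph = LabelDependencyGraph(
        nodes=list(assay_ids), edges=edges, alpha=alpha, provenance=provenance
    )
    logger.info("learned structure with %d edge(s): %s", len(edges), sorted(edges))
    return graph


def skeleton(graph: LabelDependencyGraph) -> set[frozenset[str]]:
    """Undirected edge set of a DAG (used for recovery scoring)."""
    return {frozenset(e) for e in graph.edges}


def edge_f1(true: LabelDependencyGraph, learned: LabelDependencyGraph) -> float:
    """F1 of the learned skeleton against the true skeleton."""
    t, l = skeleton(true), skeleton(learned)
    if not t and not l:
        return 1.0
    tp = len(t & l)
    prec = tp / len(l) if l else 0.0
    rec = tp / len(t) if t else 0.0
    return 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)


def topological_order(graph: LabelDependencyGraph) -> list[str]:
    """Module-level alias for :meth:`LabelDependencyGraph.topological_order`."""
    return graph.topological_order()


def parents_of(graph: LabelDependencyGraph, node: str) -> set[str]:
    """Module-level alias for :meth:`LabelDependencyGraph.parents_of`."""
    return graph.parents_of(node)
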