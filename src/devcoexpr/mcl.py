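"""Markov clustering (MCL) of co-expression networks, implemented from scratch.

MCL simulates flow on the graph: the column-stochastic transition matrix
is alternately *expanded* (raised to a matrix power, spreading flow along
paths) and *inflated* (raised to an elementwise power and renormalized,
strengthening strong currents and weakening weak ones), with small entries
pruned, until the flow matrix stops changing.  Clusters are read from the
attractors of the converged matrix: rows with positive diagonal mass mark
attractor nodes, attractors that support each other form one attractor
system, and every remaining node joins the system holding most of its
column mass.

The iteration is dense NumPy with pruning; defaults (expansion 2,
inflation 2.0) are the canonical MCL settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import get_logger
from .types import ValidationError

log = get_logger("devcoexpr.mcl")

# masses are rounded to this many decimals before the argmax assignment so
# that floating-point noise cannot flip a tie-break
_ASSIGN_DECIMALS = 9


@dataclass(frozen=True)
class MCLParams:
    expansion: int = 2
    inflation: float = 2.0
    prune: float = 1e-5
    max_iterations: int = 100
    tolerance: float = 1e-8
    self_loop: float = 1.0

    def __post_init__(self) -> None:
        if self.expansion < 2 or int(self.expansion) != self.expansion:
            raise ValidationError("expansion must be an integer >= 2")
        if self.inflation <= 1:
            raise ValidationError("inflation must be > 1")
        if self.prune < 0:
            raise ValidationError("prune must be >= 0")


@dataclass
class ModuleAssignment:
    """A partition of the network's nodes into MCL clusters.

    ``clusters`` maps cluster id -> member set; ids are assigned in order
    of each cluster's smallest member (nodes sorted as strings), so the
    labelling is deterministic.  ``retained`` is filled by
    :func:`filter_modules`.
    """

    cluster_of: dict[str, int]
    clusters: dict[int, frozenset[str]]
    converged: bool
    iterations: int
    retained: frozenset[int] = frozenset()

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.clusters.items()}


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl_cluster(network: nx.Graph, params: MCLParams = MCLParams()) -> ModuleAssignment:
    """Cluster the network by Markov clustering; every node gets one cluster."""
    nodes = sorted(network.nodes, key=str)
    if not nodes:
        raise ValidationError("cannot cluster an empty network")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v in network.edges():
        if u == v:
            continue
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    a[np.diag_indices(n)] = params.self_loop

    m = _normalize_columns(a)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        new = np.linalg.matrix_power(m, params.expansion)
        new = _normalize_columns(new**params.inflation)
        new[new < params.prune] = 0.0
        new = _normalize_columns(new)
        change = np.abs(new - m).max()
        m = new
        if change < params.tolerance:
            converged = True
            break
    if not converged:
        log.warning("MCL did not converge within %d iterations", params.max_iterations)

    cluster_of, clusters = _extract_clusters(m, nodes)
    return ModuleAssignment(cluster_of, clusters, converged, iterations)


def _extract_clusters(
    m: np.ndarray, nodes: list
) -> tuple[dict, dict[int, frozenset]]:
    """Read the partition off a converged flow matrix.

    Attractors (positive diagonal) are merged into attractor systems when
    one attractor's row supports another attractor; each remaining node is
    assigned to the system with the largest rounded column mass, ties
    broken toward the smallest cluster id.
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    attractor_set = set(attractors)
    for i in attractors:
        for j in np.nonzero(m[i])[0]:
            if j in attractor_set:
                union(i, int(j))

    system_of = {i: find(i) for i in attractors}
    roots = sorted(set(system_of.values()))
    # provisional system ids in order of root index (== smallest attractor)
    sys_id = {root: k for k, root in enumerate(roots)}

    members: dict[int, set] = {k: set() for k in sys_id.values()}
    assigned: dict[int, int] = {}
    mass = np.zeros((len(roots), n))
    for i in attractors:
        mass[sys_id[system_of[i]]] += m[i]
    mass = np.round(mass, _ASSIGN_DECIMALS)
    extra = 0
    for j in range(n):
        col = mass[:, j]
        if col.max() > 0:
            k = int(np.argmax(col))  # argmax takes the smallest id on ties
        else:
            # no attractor support (possible pre-convergence): own singleton
            k = len(roots) + extra
            extra += 1
            members[k] = set()
        members[k].add(nodes[j])
        assigned[j] = k

    # relabel deterministically by each cluster's smallest member
    nonempty = [(min(map(str, ms)), k) for k, ms in members.items() if ms]
    relabel = {k: new for new, (_, k) in enumerate(sorted(nonempty))}
    cluster_of = {nodes[j]: relabel[assigned[j]] for j in range(n)}
    clusters = {
        relabel[k]: frozenset(ms) for k, ms in members.items() if ms
    }
    return cluster_of, clusters


def filter_modules(assignment: ModuleAssignment, min_size: int = 9) -> ModuleAssignment:
    """Fill the retained-module set: clusters with size >= min_size.

    The default of nine follows the published figure caption ("at least
    nine nodes", i.e. strictly more than eight).
    """
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    retained = frozenset(
        cid for cid, m in assignment.clusters.items() if len(m) >= min_size
    )
    return ModuleAssignment(
        assignment.cluster_of,
        assignment.clusters,
        assignment.converged,
        assignment.iterations,
        retained,
    )
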