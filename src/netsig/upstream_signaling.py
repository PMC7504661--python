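"""Upstream signaling cascade extraction, scoring, pruning and merging.

A signaling cascade is a simple directed path in a pathway graph from a
start node (in-degree 0) to an activated TF.  Every such path up to a
length cap is enumerated, scored by the arithmetic mean of its member
genes' up-regulation probabilities, and the top-scoring cascades per
(pathway, TF) pair are retained (default 3).  Retained cascades across all
pathways and TFs are merged into a core signaling network whose nodes are
labelled start / transduction / tf.

Edge signs do not enter enumeration or scoring (cascades are scored on
nodes); they are carried through the merge for the perturbation-factor
stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from netsig.data_io import PathwayGraph

__all__ = [
    "SignalingCascade",
    "CoreSignalingNetwork",
    "start_nodes",
    "enumerate_cascades",
    "score_and_prune",
    "build_core_network",
    "compare_groups",
    "extract_group_cascades",
]

DEFAULT_MAX_LEN = 12
DEFAULT_PATH_BUDGET = 100_000


class PathBudgetExceeded(RuntimeError):
    """Simple-path enumeration exceeded the configured path-count budget."""


@dataclass(frozen=True)
class SignalingCascade:
    """An ordered start-node -> ... -> TF path with its mean-probability score."""

    pathway_id: str
    nodes: tuple[str, ...]
    tf: str
    score: float

    def __post_init__(self) -> None:
        if self.nodes and self.nodes[-1] != self.tf:
            raise ValueError("cascade must terminate at its TF")


@dataclass
class CoreSignalingNetwork:
    """Merged union of retained cascades: signed digraph + node roles."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def genes(self) -> set[str]:
        return set(self.graph.nodes)

    def roles(self) -> dict[str, str]:
        return {n: d["role"] for n, d in self.graph.nodes(data=True)}

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["role"] == role}


def start_nodes(pathway: PathwayGraph) -> set[str]:
    """Signaling start nodes: in-degree-0 genes.

    A pathway whose every node sits on a cycle has no in-degree-0 node; in
    that case the members of source strongly-connected components (SCCs with
    no incoming edge from outside) are used, with a warning.
    """
    g = pathway.graph
    if g.number_of_nodes() == 0:
        raise ValueError(f"pathway {pathway.pathway_id!r} is empty")
    starts = {n for n in g.nodes if g.in_degree(n) == 0}
    if starts:
        return starts
    condensation = nx.condensation(g)
    source_sccs = [n for n in condensation.nodes if condensation.in_degree(n) == 0]
    starts = set()
    for scc in source_sccs:
        starts.update(condensation.nodes[scc]["members"])
    warnings.warn(
        f"pathway {pathway.pathway_id!r} has no in-degree-0 node; "
        f"using {len(starts)} source-SCC members as starts"
    )
    return starts


def enumerate_cascades(
    pathway: PathwayGraph,
    starts: Iterable[str],
    tf: str,
    max_len: int = DEFAULT_MAX_LEN,
    path_budget: int = DEFAULT_PATH_BUDGET,
) -> list[tuple[str, ...]]:
    """All simple paths from any start node to ``tf`` with <= max_len edges.

    Returned in deterministic (lexicographic) order.  Raises
    PathBudgetExceeded past ``path_budget`` paths to keep enumeration on
    dense pathways bounded.
    """
    g = pathway.graph
    if tf not in g:
        raise ValueError(f"TF {tf!r} not in pathway {pathway.pathway_id!r}")
    paths: list[tuple[str, ...]] = []
    for start in sorted(set(starts)):
        if start not in g:
            continue
        if start == tf:
            continue
        for path in nx.all_simple_paths(g, start, tf, cutoff=max_len):
            paths.append(tuple(path))
            if len(paths) > path_budget:
                raise PathBudgetExceeded(
                    f"more than {path_budget} simple paths from starts to {tf!r} "
                    f"in pathway {pathway.pathway_id!r}; raise path_budget or lower max_len"
                )
    return sorted(paths)


def score_and_prune(
    cascades: Sequence[tuple[str, tuple[str, ...]]],
    probabilities: Mapping[str, float],
    top_k: int = 3,
) -> list[SignalingCascade]:
    """Score cascades by mean member-gene probability; keep top_k per (pathway, TF).

    ``cascades`` is a sequence of (pathway_id, node_path).  A node missing
    from ``probabilities`` contributes probability 0 (with a warning).  Ties
    are broken by shorter path, then lexicographic node sequence; the
    retained set is independent of input order.
    """
    missing: set[str] = set()

    def prob(gene: str) -> float:
        if gene in probabilities:
            return float(probabilities[gene])
        missing.add(gene)
        return 0.0

    scored: dict[tuple[str, str], list[SignalingCascade]] = {}
    for pathway_id, nodes in cascades:
        nodes = tuple(nodes)
        score = sum(prob(n) for n in nodes) / len(nodes)
        casc = SignalingCascade(pathway_id=pathway_id, nodes=nodes, tf=nodes[-1], score=score)
        scored.setdefault((pathway_id, casc.tf), []).append(casc)
    if missing:
        warnings.warn(f"{len(missing)} cascade gene(s) had no probability; scored as 0")
    retained: list[SignalingCascade] = []
    for key in sorted(scored):
        group = sorted(scored[key], key=lambda c: (-c.score, len(c.nodes), c.nodes))
        retained.extend(group[:top_k])
    return retained


def build_core_network(
    cascades: Sequence[SignalingCascade],
    tf_set: Iterable[str],
    pathways: Mapping[str, PathwayGraph],
) -> CoreSignalingNetwork:
    """Merge retained cascades into one signed network with node roles.

    Roles: ``tf`` for queried TFs, ``start`` for first nodes of retained
    cascades that are not TFs, ``transduction`` otherwise.  Edge signs come
    from the source pathways; a sign conflict on a merged edge keeps both
    annotations in the provenance and flags the edge.
    """
    if not cascades:
        raise ValueError("no cascades to merge")
    tf_set = set(tf_set)
    net = CoreSignalingNetwork()
    g = net.graph
    starts = {c.nodes[0] for c in cascades}
    for casc in cascades:
        pw = pathways[casc.pathway_id]
        for u, v in zip(casc.nodes[:-1], casc.nodes[1:]):
            sign = pw.graph[u][v]["sign"]
            if g.has_edge(u, v):
                data = g[u][v]
                data["provenance"].append((casc.pathway_id, "->".join(casc.nodes)))
                if data["sign"] != sign:
                    data["sign_conflict"] = True
            else:
                g.add_edge(u, v, sign=sign, provenance=[(casc.pathway_id, "->".join(casc.nodes))],
                           sign_conflict=False)
    for node in g.nodes:
        if node in tf_set:
            role = "tf"
        elif node in starts:
            role = "start"
        else:
            role = "transduction"
        g.nodes[node]["role"] = role
    return net


def compare_groups(networks: Mapping[int, CoreSignalingNetwork]) -> dict:
    """Shared genes and per-group unique genes / unique TFs across group networks."""
    if len(networks) < 2:
        raise ValueError("need >= 2 group networks to compare")
    gene_sets = {g: net.genes for g, net in networks.items()}
    tf_sets = {g: net.nodes_with_role("tf") for g, net in networks.items()}
    shared = set.intersection(*gene_sets.values())
    unique_genes = {}
    unique_tfs = {}
    for g in sorted(networks):
        others = set().union(*(gene_sets[h] for h in networks if h != g))
        other_tfs = set().union(*(tf_sets[h] for h in networks if h != g))
        unique_genes[g] = gene_sets[g] - others
        unique_tfs[g] = tf_sets[g] - other_tfs
    return {"shared": shared, "unique_genes": unique_genes, "unique_tfs": unique_tfs}


def extract_group_cascades(
    pathways: Sequence[PathwayGraph],
    tfs: Iterable[str],
    probabilities: Mapping[str, float],
    top_k: int = 3,
    max_len: int = DEFAULT_MAX_LEN,
    path_budget: int = DEFAULT_PATH_BUDGET,
) -> list[SignalingCascade]:
    """Convenience driver: enumerate + score + prune over all pathways and TFs."""
    raw: list[tuple[str, tuple[str, ...]]] = []
    for pw in pathways:
        starts = start_nodes(pw)
        for tf in sorted(set(tfs)):
            if tf not in pw.graph:
                continue
            for path in enumerate_cascades(pw, starts, tf, max_len=max_len, path_budget=path_budget):
                raw.append((pw.pathway_id, path))
    return score_and_prune(raw, probabilities, top_k=top_k)
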