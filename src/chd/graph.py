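"""Whole-graph discovery, cluster merging, and scoring against a truth graph.

:func:`discover` runs the per-node ancestor engine on every node of a
sample table and assembles the results into a directed dependency
:class:`Hypergraph`.  Edges point ancestor -> node and are annotated
with the kernel family and the final signal-to-noise ratio; discovery
emits *functional* (not causal) dependencies, so cycles and symmetric
pairs are legal output and no acyclicity constraint is imposed.

Nodes are processed independently — the per-node bootstrap RNG is keyed
by the node's position in the sorted name list, never by processing
order — so the recovered graph does not depend on the order in which
nodes are visited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .ancestors import (
    AncestorReport,
    bootstrap_null,
    choose_kernel,
    prune_path,
    select_inflection,
    select_threshold,
    z_score,
)
from .data import DataMatrix, normalize
from .kernels import FAMILIES, GramFactory, KernelSpec

__all__ = [
    "GraphConfig",
    "Hypergraph",
    "RecoveryMetrics",
    "discover",
    "merge_cluster",
    "compare_to_truth",
]


@dataclass(frozen=True)
class GraphConfig:
    """Settings shared by every per-node discovery run.

    ``stop`` chooses the pruning rule: ``"inflection"`` keeps the
    ancestor set preceding the largest surge of the noise ratio (the
    default), ``"threshold"`` keeps the smallest set whose signal ratio
    stays above ``threshold``.  ``candidates`` optionally restricts the
    candidate universe per target (e.g. regress derivatives on states
    only); ``targets`` restricts which nodes are analyzed; ``exclude``
    removes nodes from every candidate set.  Per-node overrides of the
    kernel ladder are given via ``ladder_overrides``.
    """

    ladder: tuple[str, ...] = FAMILIES
    gamma: float | str = 0.01
    stop: str = "inflection"
    threshold: float = 0.5
    n_boot: int = 100
    seed: int = 0
    beta1: float = 0.1
    beta2: float = 0.1
    beta3: float = 0.1
    base_kernel: str = "gaussian"
    targets: tuple[str, ...] | None = None
    candidates: dict[str, tuple[str, ...]] | None = None
    exclude: tuple[str, ...] = ()
    ladder_overrides: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stop not in ("threshold", "inflection"):
            raise ValueError(f"unknown stopping rule {self.stop!r}")
        for fam in self.ladder:
            if fam not in FAMILIES:
                raise ValueError(f"unknown kernel family {fam!r}")


@dataclass(frozen=True)
class Hypergraph:
    """Directed graph of discovered functional dependencies.

    ``edges`` maps (ancestor, node) -> annotation dict with keys
    ``family``, ``ratio`` (final signal-to-noise) and ``zscore``;
    ``reports`` holds the full per-node :class:`AncestorReport`.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], dict]
    reports: dict[str, AncestorReport]

    def __post_init__(self) -> None:
        for src, dst in self.edges:
            if src == dst:
                raise ValueError(f"self-edge on {src!r}")
            if src not in self.nodes or dst not in self.nodes:
                raise ValueError(f"edge ({src!r}, {dst!r}) off the node set")

    def edge_list(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def ancestors_of(self, node: str) -> tuple[str, ...]:
        report = self.reports.get(node)
        return report.final_ancestors if report is not None else ()

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (src, dst), attrs in self.edges.items():
            g.add_edge(src, dst, **attrs)
        return g


def merge_cluster(
    data: DataMatrix, groups: dict[str, set[str] | list[str] | tuple[str, ...]]
) -> DataMatrix:
    """Fuse named groups of variables into multivariate cluster nodes.

    Subsequent discovery treats each group as a single node: its member
    variables enter candidate kernels jointly and are never separated
    during pruning.  Groups must be disjoint; variables not mentioned
    stay singleton nodes.
    """
    named = {name: tuple(sorted(members)) for name, members in groups.items()}
    members = [v for vs in named.values() for v in vs]
    if len(set(members)) != len(members):
        raise ValueError("cluster groups overlap")
    unknown = set(members) - set(data.names)
    if unknown:
        raise ValueError(f"unknown variables in groups: {sorted(unknown)}")
    taken = set(members)
    new_groups: dict[str, tuple[str, ...]] = {}
    for name in data.names:
        if name not in taken:
            new_groups[name] = (name,)
    for name, vs in named.items():
        if name in new_groups:
            raise ValueError(f"cluster name {name!r} collides with a variable")
        new_groups[name] = vs
    return replace(data, groups=new_groups)


def _node_rng(seed: int, node_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, node_index]))


def _discover_member(
    data: DataMatrix,
    target_col: str,
    candidates: tuple[str, ...],
    config: GraphConfig,
    ladder: tuple[str, ...],
    rng: np.random.Generator,
) -> AncestorReport:
    """Ancestor analysis for one scalar target column."""
    if target_col in data.groups and data.groups[target_col] == (target_col,):
        view = data
    else:
        # the target is a member of a cluster node: view it as a
        # singleton next to the candidate nodes
        groups = {c: data.columns_of(c) for c in candidates}
        groups[target_col] = (target_col,)
        view = replace(data, groups=groups)
    kw = dict(
        gamma=config.gamma,
        beta1=config.beta1,
        beta2=config.beta2,
        beta3=config.beta3,
        base_kernel=config.base_kernel,
    )
    family, res = choose_kernel(
        view, target_col, candidates, ladder=ladder,
        threshold=config.threshold, **kw,
    )
    null = None
    zs = float("nan")
    if config.n_boot >= 2 and res.kernel is not None:
        cols = res.kernel.active_variables
        factory = GramFactory(view.matrix(cols), res.kernel)
        null = bootstrap_null(factory.total, config.gamma, config.n_boot, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            zs = z_score(res.noise_ratio, null)
    band = (null.q05, null.q95) if null is not None else None
    if family is None:
        return AncestorReport(
            target=target_col,
            has_ancestors=False,
            kernel_family=None,
            final_ancestors=(),
            final_ratio=res.ratio,
            z_score=zs,
            null_band=band,
        )
    trace = prune_path(view, target_col, candidates, family, **kw)
    if config.stop == "threshold":
        final = select_threshold(trace, config.threshold)
    else:
        final = select_inflection(trace)
    if not final:
        return AncestorReport(
            target=target_col,
            has_ancestors=False,
            kernel_family=None,
            final_ancestors=(),
            final_ratio=res.ratio,
            z_score=zs,
            null_band=band,
            trace=trace,
        )
    final_step = next(
        s for s in trace.steps if set(s.ancestors) == set(final)
    )
    return AncestorReport(
        target=target_col,
        has_ancestors=True,
        kernel_family=family,
        final_ancestors=tuple(sorted(final)),
        final_ratio=1.0 - final_step.noise_ratio,
        z_score=zs,
        null_band=band,
        trace=trace,
    )


def _discover_node(
    data: DataMatrix, node: str, config: GraphConfig, node_index: int
) -> AncestorReport:
    all_nodes = tuple(data.nodes)
    if config.candidates is not None and node in config.candidates:
        cands = tuple(
            c for c in config.candidates[node] if c != node
        )
    else:
        cands = tuple(
            c for c in all_nodes if c != node and c not in config.exclude
        )
    ladder = config.ladder_overrides.get(node, config.ladder)
    rng = _node_rng(config.seed, node_index)
    members = data.columns_of(node)
    if len(members) == 1:
        report = _discover_member(data, members[0], cands, config, ladder, rng)
        return replace(report, target=node)
    # Cluster target: analyze each member against the candidate nodes and
    # merge — the cluster has ancestors as soon as any member does; the
    # union of the member ancestor sets and the strongest member ratio
    # are reported.
    reports = [
        _discover_member(data, m, cands, config, ladder, rng) for m in members
    ]
    hits = [r for r in reports if r.has_ancestors]
    if not hits:
        best = max(reports, key=lambda r: r.final_ratio)
        return replace(best, target=node)
    union = tuple(sorted({a for r in hits for a in r.final_ancestors}))
    fam = next(
        f for f in ladder if any(r.kernel_family == f for r in hits)
    )
    best = max(hits, key=lambda r: r.final_ratio)
    return AncestorReport(
        target=node,
        has_ancestors=True,
        kernel_family=fam,
        final_ancestors=union,
        final_ratio=best.final_ratio,
        z_score=best.z_score,
        null_band=best.null_band,
        trace=best.trace,
    )


def discover(data: DataMatrix, config: GraphConfig | None = None) -> Hypergraph:
    """Run ancestor discovery for every node and assemble the hypergraph.

    The table is standardized first (with a warning if it was not
    already).  For each node the candidate set is every other node minus
    configured exclusions; the kernel ladder decides whether the node
    has ancestors at all, pruning and the configured stopping rule pick
    the final set, and a bootstrap null annotates the verdict with a
    Z-score.
    """
    if config is None:
        config = GraphConfig()
    if data.n_samples < 2 or data.n_variables < 2:
        raise ValueError("discovery needs at least 2 samples and 2 variables")
    if not data.is_normalized:
        warnings.warn(
            "input table is not standardized; normalizing now", stacklevel=2
        )
        data = normalize(data)
    node_order = tuple(data.nodes)
    sorted_nodes = sorted(node_order)
    targets = config.targets if config.targets is not None else node_order
    unknown = set(targets) - set(node_order)
    if unknown:
        raise ValueError(f"unknown target node(s): {sorted(unknown)}")
    reports: dict[str, AncestorReport] = {}
    for node in targets:
        reports[node] = _discover_node(
            data, node, config, sorted_nodes.index(node)
        )
    edges: dict[tuple[str, str], dict] = {}
    for node, report in reports.items():
        for anc in report.final_ancestors:
            edges[(anc, node)] = {
                "family": report.kernel_family,
                "ratio": report.final_ratio,
                "zscore": report.z_score,
            }
    return Hypergraph(nodes=node_order, edges=edges, reports=reports)


# ---------------------------------------------------------------------------
# scoring


@dataclass(frozen=True)
class RecoveryMetrics:
    """Confusion counts and rates of a recovered graph vs a truth graph.

    Rates with undefined denominators are NaN, never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    @property
    def fdr(self) -> float:
        return self.fp / (self.tp + self.fp) if self.tp + self.fp else float("nan")


def compare_to_truth(
    graph: Hypergraph,
    truth: list[tuple[str, str]],
    direction_sensitive: bool = True,
) -> RecoveryMetrics:
    """Score recovered edges against a ground-truth edge list.

    With ``direction_sensitive=False`` edges are compared as unordered
    pairs (a recovered edge in either direction matches).  The possible
    pairs for the TN count are all non-self ordered (or unordered)
    pairs over the graph's nodes.
    """
    nodes = set(graph.nodes)
    for src, dst in truth:
        if src not in nodes or dst not in nodes:
            raise ValueError(f"truth edge ({src!r}, {dst!r}) off the node set")

    def canon(e: tuple[str, str]) -> tuple[str, str]:
        return e if direction_sensitive else tuple(sorted(e))  # type: ignore

    truth_set = {canon(e) for e in truth}
    found_set = {canon(e) for e in graph.edges}
    names = sorted(nodes)
    if direction_sensitive:
        universe = {
            (a, b) for a in names for b in names if a != b
        }
    else:
        universe = {
            (a, b) for i, a in enumerate(names) for b in names[i + 1:]
        }
    tp = len(truth_set & found_set)
    fp = len(found_set - truth_set)
    fn = len(truth_set - found_set)
    tn = len(universe) - tp - fp - fn
    return RecoveryMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
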