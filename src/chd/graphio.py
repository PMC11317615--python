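"""Graph serialization: canonical JSON, DOT, GraphML, edge-list TSV.

JSON is the canonical round-trippable form: nodes carry the full
per-node verdict (family, final ratio, Z-score, null band), edges carry
{source, target, family, ratio, zscore}.  Writing is deterministic
(sorted keys, fixed indentation), so write -> read -> write is
byte-identical.

DOT output maps each edge's signal-to-noise ratio to pen width and gray
level (stronger edges drawn wider and darker); GraphML carries the same
attributes for downstream tools.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import networkx as nx

from .ancestors import AncestorReport
from .graph import Hypergraph

__all__ = ["write_graph", "read_graph", "read_edge_list", "write_edge_list"]


def _num(x: float | None) -> float | None:
    if x is None:
        return None
    if isinstance(x, float) and not math.isfinite(x):
        return None
    return float(x)


def graph_to_dict(graph: Hypergraph) -> dict:
    nodes = []
    for name in graph.nodes:
        rep = graph.reports.get(name)
        entry: dict = {"name": name}
        if rep is not None:
            entry.update(
                has_ancestors=rep.has_ancestors,
                family=rep.kernel_family,
                ancestors=sorted(rep.final_ancestors),
                ratio=_num(rep.final_ratio),
                zscore=_num(rep.z_score),
                null_band=(
                    [_num(rep.null_band[0]), _num(rep.null_band[1])]
                    if rep.null_band is not None
                    else None
                ),
            )
        nodes.append(entry)
    edges = [
        {
            "source": src,
            "target": dst,
            "family": attrs.get("family"),
            "ratio": _num(attrs.get("ratio")),
            "zscore": _num(attrs.get("zscore")),
        }
        for (src, dst), attrs in sorted(graph.edges.items())
    ]
    return {"nodes": nodes, "edges": edges}


def graph_from_dict(payload: dict) -> Hypergraph:
    names = tuple(n["name"] for n in payload["nodes"])
    reports = {}
    for n in payload["nodes"]:
        if "has_ancestors" not in n:
            continue
        band = n.get("null_band")
        reports[n["name"]] = AncestorReport(
            target=n["name"],
            has_ancestors=n["has_ancestors"],
            kernel_family=n.get("family"),
            final_ancestors=tuple(n.get("ancestors", ())),
            final_ratio=n["ratio"] if n.get("ratio") is not None else float("nan"),
            z_score=n["zscore"] if n.get("zscore") is not None else float("nan"),
            null_band=tuple(band) if band is not None else None,
        )
    edges = {
        (e["source"], e["target"]): {
            "family": e.get("family"),
            "ratio": e.get("ratio"),
            "zscore": e.get("zscore"),
        }
        for e in payload["edges"]
    }
    return Hypergraph(nodes=names, edges=edges, reports=reports)


def _dot(graph: Hypergraph) -> str:
    lines = ["digraph dependencies {", "  rankdir=LR;"]
    for name in graph.nodes:
        lines.append(f'  "{name}";')
    for (src, dst), attrs in sorted(graph.edges.items()):
        ratio = attrs.get("ratio")
        if ratio is None or not math.isfinite(ratio):
            ratio = 0.5
        ratio = min(max(ratio, 0.0), 1.0)
        width = 0.5 + 3.0 * ratio
        gray = int(round(80.0 * (1.0 - ratio)))  # strong signal -> darker
        lines.append(
            f'  "{src}" -> "{dst}" [penwidth={width:.2f}, '
            f'color="gray{gray}", label="{ratio:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_graph(graph: Hypergraph, path: str | Path, fmt: str = "json") -> Path:
    """Serialize a hypergraph as JSON (canonical), DOT, or GraphML."""
    path = Path(path)
    if fmt == "json":
        payload = json.dumps(graph_to_dict(graph), indent=2, sort_keys=True)
        path.write_text(payload + "\n")
    elif fmt == "dot":
        path.write_text(_dot(graph))
    elif fmt == "graphml":
        g = nx.DiGraph()
        g.add_nodes_from(graph.nodes)
        for (src, dst), attrs in sorted(graph.edges.items()):
            clean = {
                k: v
                for k, v in attrs.items()
                if v is not None and (not isinstance(v, float) or math.isfinite(v))
            }
            g.add_edge(src, dst, **clean)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    return path


def read_graph(path: str | Path) -> Hypergraph:
    """Read a hypergraph from its canonical JSON form."""
    return graph_from_dict(json.loads(Path(path).read_text()))


def write_edge_list(edges, path: str | Path) -> Path:
    """Write a ground-truth edge list as a two-column TSV with header."""
    path = Path(path)
    lines = ["source\ttarget"]
    lines.extend(f"{src}\t{dst}" for src, dst in edges)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list (header row required)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    edges = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}: line {i} is not a two-column row")
        edges.append((parts[0].strip(), parts[1].strip()))
    return edges
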