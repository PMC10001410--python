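"""Directed miRNA -> mRNA interaction graph with attribute encoding.

Nodes are the miRNAs and mRNAs appearing in supported pairs of either
contrast (KO vs WT, KI vs WT); each node records its kind, its log2 fold
change and direction per contrast, the magnitude of its largest change, and
whether it appeared in both contrasts ("shared").  Each edge runs from a
miRNA to one of its targets and records, per contrast, whether the pair was
supported there and whether it was canonical (opposite LFC signs), plus a
"concordant" flag set when the edge is present in both contrasts with the
same canonical status — the weakest consistent reading of the two mutants
behaving similarly.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import pandas as pd

__all__ = [
    "classify_canonical",
    "build_graph",
    "export_graph",
    "import_graph",
    "render_graph",
]

CONTRASTS = ("ko", "ki")

NODE_ATTRS = ("kind", "lfc_ko", "lfc_ki", "direction_ko", "direction_ki", "magnitude", "shared")
EDGE_ATTRS = ("present_ko", "present_ki", "canonical_ko", "canonical_ki", "concordant")


def classify_canonical(mirna_lfc: float, gene_lfc: float) -> bool:
    """True iff the miRNA and mRNA fold changes have strictly opposite signs.

    A zero fold change on either side is non-canonical: the dichotomy is
    repression-consistent versus not, with no third class.
    """
    if not (math.isfinite(mirna_lfc) and math.isfinite(gene_lfc)):
        raise ValueError("fold changes must be finite")
    return mirna_lfc * gene_lfc < 0


def _contrast_key(label: str) -> str:
    low = label.lower()
    for key in CONTRASTS:
        if low.startswith(key):
            return key
    raise ValueError(f"cannot map contrast label {label!r} onto KO/KI")


def _direction(lfc: float | None) -> str:
    if lfc is None:
        return "absent"
    return "up" if lfc > 0 else ("down" if lfc < 0 else "none")


def build_graph(pairs_ko: list, pairs_ki: list) -> nx.DiGraph:
    """Assemble the attribute-encoded interaction graph from two pair lists.

    Pure function of the two lists: nodes and edges are inserted in
    lexicographic order so the exported document is reproducible regardless
    of input ordering.  Raises if a pair's stored canonical flag contradicts
    its fold-change signs.
    """
    per_contrast: dict[str, dict[tuple[str, str], object]] = {"ko": {}, "ki": {}}
    node_lfc: dict[str, dict[str, float]] = {}
    for pairs in (pairs_ko, pairs_ki):
        for p in pairs:
            key = _contrast_key(p.contrast)
            if p.canonical != classify_canonical(p.mirna_lfc, p.gene_lfc):
                raise ValueError(
                    f"pair ({p.mirna}, {p.gene}) in {p.contrast}: canonical flag "
                    f"contradicts LFC signs ({p.mirna_lfc:+g}, {p.gene_lfc:+g})"
                )
            per_contrast[key][(p.mirna, p.gene)] = p
            node_lfc.setdefault(p.mirna, {})[key] = p.mirna_lfc
            node_lfc.setdefault(p.gene, {})[key] = p.gene_lfc

    mirnas = {p.mirna for c in per_contrast.values() for p in c.values()}
    graph = nx.DiGraph()
    for node in sorted(node_lfc):
        lfcs = node_lfc[node]
        attrs = {
            "kind": "miRNA" if node in mirnas else "mRNA",
            "magnitude": max(abs(v) for v in lfcs.values()),
            "shared": ("ko" in lfcs) and ("ki" in lfcs),
        }
        for c in CONTRASTS:
            if c in lfcs:
                attrs[f"lfc_{c}"] = float(lfcs[c])
            attrs[f"direction_{c}"] = _direction(lfcs.get(c))
        graph.add_node(node, **attrs)

    edges = sorted(set(per_contrast["ko"]) | set(per_contrast["ki"]))
    for mirna, gene in edges:
        attrs = {}
        for c in CONTRASTS:
            pair = per_contrast[c].get((mirna, gene))
            attrs[f"present_{c}"] = pair is not None
            attrs[f"canonical_{c}"] = bool(pair.canonical) if pair is not None else False
        attrs["concordant"] = (
            attrs["present_ko"]
            and attrs["present_ki"]
            and attrs["canonical_ko"] == attrs["canonical_ki"]
        )
        graph.add_edge(mirna, gene, **attrs)
    return graph


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def export_graph(graph: nx.DiGraph, path, format: str = "graphml") -> None:
    """Write the graph as ``graphml``, ``edge-tsv`` or ``dot``.

    GraphML and edge-TSV exports are lossless: re-importing reproduces the
    graph, nodes, edges and attributes.  DOT is a one-way rendering aid.
    """
    if format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "edge-tsv":
        _write_edge_tsv(graph, path)
    elif format == "dot":
        _write_dot(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected graphml, edge-tsv or dot")


def import_graph(path, format: str = "graphml") -> nx.DiGraph:
    if format == "graphml":
        graph = nx.read_graphml(path)
        graph.graph.pop("node_default", None)
        graph.graph.pop("edge_default", None)
        return graph
    if format == "edge-tsv":
        return _read_edge_tsv(path)
    raise ValueError(f"cannot import format {format!r}")


def _node_record(graph: nx.DiGraph, node: str, role: str) -> dict:
    rec = {f"{role}": node}
    data = graph.nodes[node]
    for attr in NODE_ATTRS:
        if attr == "kind":
            continue
        if attr in data:
            rec[f"{role}_{attr}"] = data[attr]
    return rec

def _write_edge_tsv(graph: nx.DiGraph, path) -> None:
    rows = []
    for mirna, gene in sorted(graph.edges):
        row = {**_node_record(graph, mirna, "mirna"), **_node_record(graph, gene, "gene")}
        row.update({attr: graph.edges[mirna, gene][attr] for attr in EDGE_ATTRS})
        rows.append(row)
    columns = (
        ["mirna"]
        + [f"mirna_{a}" for a in NODE_ATTRS if a != "kind"]
        + ["gene"]
        + [f"gene_{a}" for a in NODE_ATTRS if a != "kind"]
        + list(EDGE_ATTRS)
    )
    # %.17g guarantees floats survive the text round trip bit-for-bit
    pd.DataFrame(rows).reindex(columns=columns).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def _read_edge_tsv(path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    graph = nx.DiGraph()
    for _, row in df.iterrows():
        for role, kind in (("mirna", "miRNA"), ("gene", "mRNA")):
            node = row[role]
            if node in graph:
                continue
            attrs = {"kind": kind}
            for attr in NODE_ATTRS:
                if attr == "kind":
                    continue
                val = row.get(f"{role}_{attr}")
                if pd.isna(val):
                    continue
                if attr == "shared":
                    val = bool(val)
                attrs[attr] = val
            graph.add_node(node, **attrs)
        edge_attrs = {attr: bool(row[attr]) for attr in EDGE_ATTRS}
        graph.add_edge(row["mirna"], row["gene"], **edge_attrs)
    return graph


def _dot_quote(s: str) -> str:
    return '"' + str(s).replace('"', '\\"') + '"'


def _write_dot(graph: nx.DiGraph, path) -> None:
    lines = ["digraph mirna_network {"]
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        attrs = ", ".join(f"{k}={_dot_quote(v)}" for k, v in sorted(data.items()))
        lines.append(f"  {_dot_quote(node)} [{attrs}];")
    for u, v in sorted(graph.edges):
        data = graph.edges[u, v]
        attrs = ", ".join(f"{k}={_dot_quote(val)}" for k, val in sorted(data.items()))
        lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)} [{attrs}];")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# rendering (best effort; not part of any quantitative output)
# ---------------------------------------------------------------------------


def render_graph(graph: nx.DiGraph, output_image, max_lfc: float = 4.0) -> None:
    """Draw the network with the visual conventions of the study's figures.

    Red = up vs WT, blue = down, darker = larger |LFC| (clipped at
    ``max_lfc``); solid lines = canonical, dotted = non-canonical; bright red
    lines = concordant in KO and KI; black node outline = shared in both
    contrasts, white = unique to one.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot render an empty graph")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(graph, seed=0)
    node_colors, edge_outline = [], []
    for node in graph.nodes:
        data = graph.nodes[node]
        lfc = data.get("lfc_ko", data.get("lfc_ki", 0.0))
        intensity = min(abs(lfc), max_lfc) / max_lfc
        if lfc > 0:
            node_colors.append((1.0, 1.0 - 0.8 * intensity, 1.0 - 0.8 * intensity))
        elif lfc < 0:
            node_colors.append((1.0 - 0.8 * intensity, 1.0 - 0.8 * intensity, 1.0))
        else:
            node_colors.append((0.9, 0.9, 0.9))
        edge_outline.append("black" if data.get("shared") else "white")

    fig, ax = plt.subplots(figsize=(9, 9))
    nx.draw_networkx_nodes(
        graph, pos, ax=ax, node_color=node_colors, edgecolors=edge_outline, node_size=350
    )
    for u, v in graph.edges:
        data = graph.edges[u, v]
        canonical = data.get("canonical_ko") or data.get("canonical_ki")
        style = "solid" if canonical else "dotted"
        color = "red" if data.get("concordant") else "black"
        nx.draw_networkx_edges(
            graph, pos, ax=ax, edgelist=[(u, v)], style=style, edge_color=color, width=1.6
        )
    nx.draw_networkx_labels(graph, pos, ax=ax, font_size=6)
    ax.set_axis_off()
    fig.savefig(output_image, dpi=150, bbox_inches="tight")
    plt.close(fig)
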