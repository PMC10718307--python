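"""Anchor-loop graphs and their module (connected-component) structure.

Vertices are loop anchors, edges are loops weighted by normalized counts.
"Modules" are connected components: the fragmentation of large components
after TF loss is the network-level readout of hub disassembly.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from hubweaver.defs import MOTIF_NONE


def build_network(
    loops: pd.DataFrame,
    weight_col: str,
    min_count: float = 0.0,
    motif_col: str = "anchor_pair_class",
) -> nx.Graph:
    """Graph with one vertex per distinct anchor and one edge per loop.

    Loops with weight <= ``min_count`` are dropped; duplicate rows for the
    same anchor pair are merged into a single edge with summed weight.
    Self-edges (identical anchors) are skipped. Node attributes: chrom, mid
    (anchor midpoint) and motif_class when the loop table is classified.
    """
    g = nx.Graph()
    if "anchor1_id" not in loops.columns:
        raise ValueError("loop table must be classified (anchor ids missing)")
    have_motif = "motif1" in loops.columns
    mids1 = (loops["start1"].to_numpy() + loops["end1"].to_numpy()) // 2
    mids2 = (loops["start2"].to_numpy() + loops["end2"].to_numpy()) // 2
    for i, row in enumerate(loops.itertuples(index=False)):
        w = getattr(row, weight_col)
        if w <= min_count:
            continue
        u, v = row.anchor1_id, row.anchor2_id
        if u == v:
            continue
        for node, chrom, mid in ((u, row.chrom1, mids1[i]), (v, row.chrom2, mids2[i])):
            if node not in g:
                g.add_node(node, chrom=chrom, mid=int(mid))
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return g


def set_node_motifs(g: nx.Graph, anchor_classes: pd.Series) -> None:
    """Attach motif_class node attributes (anchor_id -> class mapping)."""
    for node in g.nodes:
        g.nodes[node]["motif_class"] = anchor_classes.get(node, MOTIF_NONE)


def module_decomposition(g: nx.Graph) -> pd.DataFrame:
    """Connected components with size, edge count, genomic span and repeat flag.

    Span is the distance between the extreme anchor midpoints of the
    component (cis loops make components single-chromosome). Sorted by size
    descending; component ids are assigned in that order.
    """
    rows = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        mids = [g.nodes[n]["mid"] for n in comp]
        chroms = {g.nodes[n]["chrom"] for n in comp}
        has_repeat = any(g.nodes[n].get("motif_class") == "repeat" for n in comp)
        rows.append(
            dict(n_anchors=len(comp), n_edges=sub.number_of_edges(),
                 span_bp=int(max(mids) - min(mids)) if len(chroms) == 1 else -1,
                 chrom=sorted(chroms)[0] if len(chroms) == 1 else "trans",
                 contains_repeat_anchor=has_repeat,
                 anchors=tuple(sorted(comp)))
        )
    df = pd.DataFrame(
        rows, columns=["n_anchors", "n_edges", "span_bp", "chrom",
                       "contains_repeat_anchor", "anchors"],
    )
    df = df.sort_values(
        ["n_anchors", "n_edges", "anchors"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.index.name = "component_id"
    return df


def compare_fractionation(g_on: nx.Graph, g_off: nx.Graph) -> dict:
    """Paired component summaries and off - on deltas for two graphs.

    Also returns, for every anchor present in both graphs, the mapping from
    its TF-on component to its TF-off component (ids per
    :func:`module_decomposition` ordering).
    """
    out = {}
    decomp = {}
    for name, g in (("on", g_on), ("off", g_off)):
        d = module_decomposition(g)
        decomp[name] = d
        spans = d.loc[d["span_bp"] >= 0, "span_bp"]
        rep = d[d["contains_repeat_anchor"]]
        rep_spans = rep.loc[rep["span_bp"] >= 0, "span_bp"]
        out[name] = dict(
            n_components=len(d),
            n_vertices=g.number_of_nodes(),
            n_edges=g.number_of_edges(),
            median_component_size=float(d["n_anchors"].median()) if len(d) else float("nan"),
            max_component_size=int(d["n_anchors"].max()) if len(d) else 0,
            median_span_bp=float(spans.median()) if len(spans) else float("nan"),
            max_span_bp=int(spans.max()) if len(spans) else 0,
            # hub-module view: components that contain a repeat-class anchor
            n_repeat_components=int(len(rep)),
            median_repeat_component_size=float(rep["n_anchors"].median()) if len(rep) else float("nan"),
            median_repeat_span_bp=float(rep_spans.median()) if len(rep_spans) else float("nan"),
        )
    out["delta"] = {
        k: out["off"][k] - out["on"][k]
        for k in ("n_components", "median_component_size", "max_component_size",
                  "max_span_bp")
    }
    member = {}
    comp_of = {}
    for name in ("on", "off"):
        comp_of[name] = {
            a: cid for cid, anchors in decomp[name]["anchors"].items() for a in anchors
        }
    shared = set(comp_of["on"]) & set(comp_of["off"])
    for a in sorted(shared):
        member[a] = (comp_of["on"][a], comp_of["off"][a])
    out["component_mapping"] = member
    return out
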