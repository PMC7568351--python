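"""Directed disease network built from the (verified) rule base.

Nodes are generalized disease items, colored by ICD-10 chapter; each rule
contributes one directed edge antecedent -> consequent weighted by its
confidence and tagged with its verification class.  Exports target external
viewers (Cytoscape-compatible SIF, GraphML, and a plain edge-list CSV).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from ._icd import chapter_of
from .mining import AssociationRule
from .verification import VerificationRecord


class NetworkAssemblyError(ValueError):
    pass


def build_network(rules: Sequence[AssociationRule] | Sequence[VerificationRecord],
                  ) -> nx.DiGraph:
    """One node per distinct item, one directed conf-weighted edge per rule.

    Accepts plain rules or verification records (whose class is stored on
    the edge).  Duplicate directed pairs are an assembly error.
    """
    if not rules:
        raise NetworkAssemblyError("cannot build a network from zero rules")
    g = nx.DiGraph()
    for entry in rules:
        if isinstance(entry, VerificationRecord):
            rule, vclass = entry.rule, entry.final_class
        else:
            rule, vclass = entry, "unchecked"
        if g.has_edge(rule.antecedent, rule.consequent):
            raise NetworkAssemblyError(
                f"duplicate directed pair {rule.antecedent}->{rule.consequent}")
        for item in (rule.antecedent, rule.consequent):
            if item not in g:
                g.add_node(item, chapter=chapter_of(item))
        g.add_edge(rule.antecedent, rule.consequent,
                   conf=float(rule.conf), lift=float(rule.lift),
                   sup=float(rule.sup), verification=vclass)
    return g


def node_statistics(g: nx.DiGraph, anchor: str | None = None,
                    n_hubs: int = 4) -> pd.DataFrame:
    """Per-node degrees, hub flags, and weakly-connected-component labels.

    Hubs are the ``n_hubs`` highest-total-degree nodes excluding the anchor
    (the anchor is connected to almost everything by construction); nodes of
    total degree <= 2 are flagged as "single" nodes outside any subnetwork.
    """
    components = list(nx.weakly_connected_components(g))
    comp_of = {node: idx for idx, comp in enumerate(
        sorted(components, key=lambda c: (-len(c), min(c)))) for node in comp}
    rows = []
    for node in g.nodes:
        indeg, outdeg = g.in_degree(node), g.out_degree(node)
        rows.append({"item": node, "chapter": g.nodes[node]["chapter"],
                     "indegree": indeg, "outdegree": outdeg,
                     "degree": indeg + outdeg,
                     "component": comp_of[node],
                     "is_single": indeg + outdeg <= 2})
    df = pd.DataFrame(rows).sort_values(["degree", "item"],
                                        ascending=[False, True]).reset_index(drop=True)
    hub_pool = df[df["item"] != anchor] if anchor is not None else df
    hub_items = set(hub_pool.head(n_hubs)["item"])
    df["is_hub"] = df["item"].isin(hub_items)
    if anchor is not None and anchor in g:
        df.attrs["anchor_edge_count"] = g.in_degree(anchor) + g.out_degree(anchor)
    return df


def export_network(g: nx.DiGraph, out_prefix: str | Path,
                   formats: Iterable[str] = ("sif", "graphml", "csv")) -> list[Path]:
    """Write the network in the requested formats; returns the paths written."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "sif":
            path = out_prefix.with_suffix(".sif")
            with open(path, "w") as fh:
                for u, v in g.edges:
                    fh.write(f"{u}\tcomorbid\t{v}\n")
        elif fmt == "graphml":
            path = out_prefix.with_suffix(".graphml")
            nx.write_graphml(g, path)
        elif fmt == "csv":
            path = out_prefix.with_suffix(".edges.csv")
            rows = [{"antecedent": u, "consequent": v, **data}
                    for u, v, data in g.edges(data=True)]
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
        else:
            raise ValueError(f"unknown export format {fmt!r}")
        written.append(path)
    return written


def import_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(path)


def import_edge_csv(path: str | Path) -> nx.DiGraph:
    df = pd.read_csv(path, dtype={"antecedent": str, "consequent": str})
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        d = row._asdict()
        u, v = d.pop("antecedent"), d.pop("consequent")
        for item in (u, v):
            if item not in g:
                g.add_node(item, chapter=chapter_of(item))
        g.add_edge(u, v, **d)
    return g
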