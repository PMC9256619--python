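"""Co-occurrence network construction and topology.

Edges are significant positive Spearman correlations (rho > 0.6 with
BH-FDR q < 0.05 by default); vertices are the endpoints of retained edges,
so isolated taxa never appear.  Modules come from greedy modularity
maximization (Clauset-Newman-Moore); per-node topology is the
within-module degree z-score Zi and the participation coefficient Pi,
which classify nodes into peripherals, module hubs (Zi > 2.5), connectors
(Pi > 0.62) and network hubs (both) following the Guimera-Amaral / Olesen
convention.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "build_network",
    "size_stats",
    "greedy_modules",
    "zi_pi",
    "classify_roles",
    "guild_edge_composition",
    "new_edges",
    "amf_subnetwork",
    "compare_networks",
    "export_network",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


def build_network(
    records: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    rho_min: float = 0.6,
    q_max: float = 0.05,
) -> nx.Graph:
    """Graph of significant positive correlations.

    Keeps records with rho > rho_min (strict) and q < q_max; nodes are the
    endpoints of kept edges, annotated from ``taxonomy`` (kingdom, phylum,
    family, guild, amf) when given.  An empty network is permitted.
    """
    if "q" not in records.columns:
        raise ValueError("records must carry FDR q-values")
    kept = records.loc[(records["rho"] > rho_min) & (records["q"] < q_max)]
    g = nx.Graph(rho_min=rho_min, q_max=q_max)
    for rec in kept.itertuples(index=False):
        g.add_edge(
            rec.taxon_a,
            rec.taxon_b,
            rho=float(rec.rho),
            q=float(rec.q),
            link_class=getattr(rec, "link_class", ""),
        )
    if taxonomy is not None:
        for node in g.nodes:
            if node not in taxonomy.index:
                raise ValueError(f"taxon {node!r} missing from taxonomy")
            row = taxonomy.loc[node]
            g.nodes[node].update(
                kingdom=row.get("kingdom", ""),
                phylum=row.get("phylum", ""),
                family=row.get("family", ""),
                guild=row.get("guild", ""),
                amf=bool(row.get("amf", False)),
            )
    return g


def size_stats(net: nx.Graph) -> dict:
    """Vertex counts per kingdom and edge counts per link class."""
    v_king = {"bacteria": 0, "fungi": 0, "unknown": 0}
    for _, d in net.nodes(data=True):
        v_king[d.get("kingdom") or "unknown"] = v_king.get(d.get("kingdom") or "unknown", 0) + 1
    e_cls = {"BB": 0, "FF": 0, "BF": 0, "unknown": 0}
    for _, _, d in net.edges(data=True):
        e_cls[d.get("link_class") or "unknown"] = e_cls.get(d.get("link_class") or "unknown", 0) + 1
    return {
        "n_vertices": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "vertices_per_kingdom": v_king,
        "edges_per_class": e_cls,
    }


def greedy_modules(net: nx.Graph, weighted: bool = False) -> tuple[dict, float]:
    """Greedy modularity-maximizing partition and its Q.

    Q = sum_c [e_c/m - (d_c/2m)^2] on the unweighted graph by default
    (edge rho is metadata only); ``weighted=True`` uses rho as weight.
    Deterministic: nodes are processed in sorted order and modules are
    numbered by their lexicographically smallest member.
    """
    if net.number_of_edges() == 0:
        raise ValueError("modularity undefined on an empty graph")
    h = nx.Graph()
    h.add_nodes_from(sorted(net.nodes))
    h.add_edges_from(
        sorted((min(u, v), max(u, v), d) for u, v, d in net.edges(data=True))
    )
    weight = "rho" if weighted else None
    comms = nx.community.greedy_modularity_communities(h, weight=weight)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    partition = {node: i for i, c in enumerate(comms) for node in c}
    q = nx.community.modularity(h, [set(c) for c in comms], weight=weight)
    return partition, float(q)


def zi_pi(net: nx.Graph, partition: dict) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi = (kappa_i - mean(kappa | module)) / sd(kappa | module) where
    kappa_i is the node's number of neighbors inside its own module (Zi = 0
    by convention when the module's kappa values have zero spread, flagged);
    Pi = 1 - sum_t (kappa_it / k_i)^2 over that node's links into each
    module t.
    """
    missing = [n for n in net.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:10]}")
    nodes = sorted(net.nodes)
    kappa_own = {}
    pi = {}
    for node in nodes:
        k = net.degree(node)
        per_module: dict[int, int] = {}
        for nb in net.neighbors(node):
            per_module[partition[nb]] = per_module.get(partition[nb], 0) + 1
        kappa_own[node] = per_module.get(partition[node], 0)
        pi[node] = 1.0 - sum((c / k) ** 2 for c in per_module.values())
    rows = []
    for node in nodes:
        mod = partition[node]
        kappas = np.array([kappa_own[n] for n in nodes if partition[n] == mod], float)
        sd = kappas.std()
        zi = 0.0 if sd == 0 else (kappa_own[node] - kappas.mean()) / sd
        rows.append(
            {
                "node": node,
                "module": mod,
                "degree": net.degree(node),
                "within_module_degree": kappa_own[node],
                "Zi": float(zi),
                "Pi": float(pi[node]),
                "zi_degenerate": bool(sd == 0),
            }
        )
    return pd.DataFrame(rows).set_index("node")


def classify_roles(
    topology: pd.DataFrame,
    zi_threshold: float = ZI_THRESHOLD,
    pi_threshold: float = PI_THRESHOLD,
) -> pd.DataFrame:
    """Assign peripheral / module_hub / connector / network_hub roles."""
    out = topology.copy()
    hi_z = out["Zi"] > zi_threshold
    hi_p = out["Pi"] > pi_threshold
    out["role"] = np.select(
        [hi_z & hi_p, hi_z, hi_p],
        ["network_hub", "module_hub", "connector"],
        default="peripheral",
    )
    return out


def guild_edge_composition(
    net: nx.Graph, annotation_level: str = "guild", edges=None
) -> dict:
    """Proportions of edges within vs between annotation groups.

    ``edges`` restricts the tally to a subset (e.g. the edge-set
    difference between two networks, the "new" correlations); endpoints
    without an annotation fall into an unassigned bucket, reported but
    excluded from the within/between proportions.
    """
    if annotation_level not in ("guild", "phylum", "family"):
        raise ValueError(f"unknown annotation level {annotation_level!r}")
    if edges is None:
        edges = list(net.edges)
    within = between = unassigned = 0
    for u, v in edges:
        au = net.nodes[u].get(annotation_level, "")
        av = net.nodes[v].get(annotation_level, "")
        if not au or not av:
            unassigned += 1
        elif au == av:
            within += 1
        else:
            between += 1
    total = within + between
    return {
        "n_edges": len(list(edges)),
        "within": within,
        "between": between,
        "unassigned": unassigned,
        "proportion_within": within / total if total else None,
        "proportion_between": between / total if total else None,
    }


def new_edges(net_before: nx.Graph, net_after: nx.Graph) -> list:
    """Edges present in ``net_after`` but not in ``net_before``."""
    return [e for e in net_after.edges if not net_before.has_edge(*e)]


def amf_subnetwork(net: nx.Graph) -> tuple[nx.Graph, nx.Graph, int]:
    """AMF-fungus and AMF-bacterium subnetworks.

    Network A keeps edges joining an arbuscular-mycorrhizal fungus to a
    non-AMF fungus; network B those joining an AMF to a bacterium.
    AMF-AMF edges belong to neither and their count is returned
    separately.  Warns when no taxa carry the AMF flag.
    """
    has_amf = any(d.get("amf") for _, d in net.nodes(data=True))
    if not has_amf:
        logger.warning("amf_subnetwork: no AMF-flagged taxa in network")
    a, b = nx.Graph(**net.graph), nx.Graph(**net.graph)
    amf_amf = 0
    for u, v, d in net.edges(data=True):
        du, dv = net.nodes[u], net.nodes[v]
        if du.get("amf") and dv.get("amf"):
            amf_amf += 1
            continue
        if not (du.get("amf") or dv.get("amf")):
            continue
        other = dv if du.get("amf") else du
        target = a if other.get("kingdom") == "fungi" else b
        target.add_edge(u, v, **d)
        target.nodes[u].update(du)
        target.nodes[v].update(dv)
    return a, b, amf_amf


def compare_networks(net_control: nx.Graph, net_treatment: nx.Graph) -> pd.DataFrame:
    """Signed per-link-class deltas (treatment - control) with a
    disrupted/enhanced/unchanged call from the edge-count sign."""
    for key in ("rho_min", "q_max"):
        if net_control.graph.get(key) != net_treatment.graph.get(key):
            raise ValueError(f"networks built with different {key}")
    sc, st = size_stats(net_control), size_stats(net_treatment)
    rows = []
    for cls in ("BB", "FF", "BF"):
        delta = st["edges_per_class"][cls] - sc["edges_per_class"][cls]
        rows.append(
            {
                "link_class": cls,
                "edges_control": sc["edges_per_class"][cls],
                "edges_treatment": st["edges_per_class"][cls],
                "delta_edges": delta,
                "status": "enhanced" if delta > 0 else ("disrupted" if delta < 0 else "unchanged"),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["delta_vertices"] = st["n_vertices"] - sc["n_vertices"]
    out.attrs["vertices_per_kingdom_control"] = sc["vertices_per_kingdom"]
    out.attrs["vertices_per_kingdom_treatment"] = st["vertices_per_kingdom"]

    def _q_and_roles(g: nx.Graph) -> tuple[float | None, dict]:
        if g.number_of_edges() == 0:
            return None, {}
        partition, q = greedy_modules(g)
        roles = classify_roles(zi_pi(g, partition))["role"].value_counts().to_dict()
        return q, roles

    q_c, roles_c = _q_and_roles(net_control)
    q_t, roles_t = _q_and_roles(net_treatment)
    out.attrs["modularity"] = {"control": q_c, "treatment": q_t}
    out.attrs["role_counts"] = {"control": roles_c, "treatment": roles_t}
    return out


def export_network(net: nx.Graph, prefix) -> None:
    """Write GraphML plus edge-list and node-table TSVs."""
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net, f"{prefix}.graphml")
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, "rho": d.get("rho"), "link_class": d.get("link_class")}
            for u, v, d in net.edges(data=True)
        ]
    )
    edges.to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)
    if net.number_of_edges() > 0:
        partition, q = greedy_modules(net)
        topo = classify_roles(zi_pi(net, partition))
        topo.attrs["modularity"] = q
        topo.to_csv(f"{prefix}_nodes.tsv", sep="\t")
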