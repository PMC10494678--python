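"""Origin-destination displacement graphs.

Each node is a municipality placed at its seat coordinates; each directed
edge carries the outflow (number of admissions from its origin occurring
at its destination) of one biennium.  Node size in the published maps is
proportional to in-degree (number of distinct municipalities served by a
destination) and node colour encodes the destination's macroregion; edge
colour encodes the origin's macroregion.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from neonet.errors import DataValidationError
from neonet.metrics import percent_variation

#: Macroregion colour palette of the published network maps.
MACROREGION_COLORS = {
    "leste": "red",
    "noroeste": "blue",
    "norte": "green",
    "oeste": "yellow",
}


def build_graph(od: pd.DataFrame, registry: pd.DataFrame) -> nx.DiGraph:
    """Build the directed displacement graph of a single biennium.

    Nodes are the municipalities appearing as an endpoint of at least one
    flow, with seat coordinates, macroregion colour, in-degree and inflow
    as attributes; edges carry the flow as ``weight`` and the origin's
    macroregion colour.  Pure function of (pairs, registry).
    """
    g = nx.DiGraph()
    if len(od) == 0:
        g.graph["biennium"] = ""
        return g
    labels = od["biennium_label"].unique()
    if len(labels) != 1:
        raise DataValidationError("build_graph expects OD pairs of one biennium")
    g.graph["biennium"] = str(labels[0])

    info = registry.set_index("code")
    codes = set(od["origin_code"]).union(od["destination_code"])
    missing = codes - set(info.index)
    if missing:
        raise DataValidationError(
            f"OD endpoints absent from registry: {sorted(missing)[:5]}")
    destinations = set(od["destination_code"])
    for code in sorted(codes):
        row = info.loc[code]
        g.add_node(int(code),
                   name=str(row["name"]),
                   region_id=int(row["region_id"]),
                   macroregion=str(row["macroregion"]),
                   color=MACROREGION_COLORS[row["macroregion"]],
                   lat=float(row["seat_lat"]),
                   lon=float(row["seat_lon"]),
                   is_destination=bool(code in destinations))
    for row in od.itertuples(index=False):
        if row.origin_code == row.destination_code:
            raise DataValidationError("self-loop in OD table")
        g.add_edge(int(row.origin_code), int(row.destination_code),
                   weight=int(row.flow),
                   color=MACROREGION_COLORS[info.loc[row.origin_code, "macroregion"]])
    for code in g.nodes:
        g.nodes[code]["in_degree"] = g.in_degree(code)
        g.nodes[code]["inflow"] = in_degree_weight(g, code)
    return g


def in_degree(graph: nx.DiGraph, destination: int) -> int:
    """Number of distinct origin municipalities served by a destination."""
    if destination not in graph:
        raise KeyError(f"node {destination} not in graph")
    return int(graph.in_degree(destination))


def in_degree_weight(graph: nx.DiGraph, destination: int) -> int:
    return sum(d["weight"] for _, _, d in graph.in_edges(destination, data=True))


def inflow(graph: nx.DiGraph, destination: int) -> int:
    """Total admissions at a destination of residents of other municipalities."""
    if destination not in graph:
        raise KeyError(f"node {destination} not in graph")
    return int(in_degree_weight(graph, destination))


def rank_destinations(graph_a: nx.DiGraph, graph_b: nx.DiGraph,
                      registry: pd.DataFrame,
                      inflow_threshold: int = 100) -> pd.DataFrame:
    """Compare the most frequent destinations across two biennial graphs.

    Selected destinations are all region seats plus any municipality whose
    inflow reaches ``inflow_threshold`` in either biennium.  For each, the
    in-degree ("grau de entrada") and inflow ("fluxo de entrada") of both
    biennia are reported with their percent variation; a destination absent
    from a biennium counts 0 there and its variations are missing.
    """
    info = registry.set_index("code")
    seats = set(info.index[info["is_region_seat"]])

    def metrics(g: nx.DiGraph, code: int) -> tuple[int, int]:
        if code not in g:
            return 0, 0
        return in_degree(g, code), inflow(g, code)

    candidates = seats | set(graph_a.nodes) | set(graph_b.nodes)
    rows = []
    for code in sorted(candidates):
        deg_a, flow_a = metrics(graph_a, code)
        deg_b, flow_b = metrics(graph_b, code)
        if code not in seats and max(flow_a, flow_b) < inflow_threshold:
            continue
        row = info.loc[code]
        rows.append({
            "destination_code": int(code),
            "name": str(row["name"]),
            "region_id": int(row["region_id"]),
            "macroregion": str(row["macroregion"]),
            "is_region_seat": bool(row["is_region_seat"]),
            "in_degree_a": deg_a, "in_degree_b": deg_b,
            "vp_in_degree": percent_variation(deg_a, deg_b),
            "inflow_a": flow_a, "inflow_b": flow_b,
            "vp_inflow": percent_variation(flow_a, flow_b),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["macroregion", "region_id", "destination_code"],
                              ignore_index=True)
    return out


def graph_to_edgelist(graph: nx.DiGraph) -> pd.DataFrame:
    """Flat edge-list table: origin, destination, biennium, flow."""
    rows = [(u, v, graph.graph.get("biennium"), d["weight"])
            for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["origin_code", "destination_code",
                                       "biennium_label", "flow"])


def export_graph(graph: nx.DiGraph, path: str, fmt: str = "gexf") -> None:
    """Write the graph as GEXF, GraphML, or a flat edge-list CSV.

    GEXF/GraphML exports round-trip all node and edge attributes through
    ``networkx`` readers (node identifiers come back as strings).
    """
    fmt = fmt.lower()
    if fmt == "gexf":
        nx.write_gexf(graph, path)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "csv":
        graph_to_edgelist(graph).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported graph format: {fmt!r}")
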