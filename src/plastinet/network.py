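"""Three-layer plastic regulatory networks with histone-mark overlay.

The inner layer holds miRNAs with altered transcriptional regulation, the
middle layer their predicted target genes that are themselves differentially
expressed, and the outer layer interaction partners recruited from a gene-gene
interaction table -- but only partners interacting with more than one miRNA
target.  Gene (and miRNA-locus) nodes can be annotated with the histone marks
whose differential peaks lie within the gene-assignment window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

LAYERS = ("mirna", "target", "partner")
HISTONE_MARKS = ("H3K4me1", "H3K4me3", "H3K9ac")


@dataclass
class PlasticNetwork:
    """Tripartite miRNA / target / partner graph."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def nodes_in_layer(self, layer: str) -> set[str]:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        return {n for n, d in self.graph.nodes(data=True) if d.get("layer") == layer}

    @property
    def mirnas(self) -> set[str]:
        return self.nodes_in_layer("mirna")

    @property
    def targets(self) -> set[str]:
        return self.nodes_in_layer("target")

    @property
    def partners(self) -> set[str]:
        return self.nodes_in_layer("partner")

    def marks_of(self, node: str) -> tuple[str, ...]:
        return tuple(self.graph.nodes[node].get("marks", ()))

    def validate(self, min_partner_links: int = 2) -> None:
        """Check the layer invariants (disjoint layers, partner degree)."""
        for node, data in self.graph.nodes(data=True):
            if data.get("layer") not in LAYERS:
                raise ValueError(f"node {node!r} has no layer")
        targets = self.targets
        for p in self.partners:
            t_neighbors = {n for n in self.graph.neighbors(p) if n in targets}
            if len(t_neighbors) < min_partner_links:
                raise ValueError(f"partner {p!r} has fewer than {min_partner_links} target links")
        for t in targets:
            if not any(n in self.mirnas for n in self.graph.neighbors(t)):
                raise ValueError(f"target {t!r} has no miRNA neighbor")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlasticNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        for n in self.graph.nodes:
            a, b = self.graph.nodes[n], other.graph.nodes[n]
            if a.get("layer") != b.get("layer"):
                return False
            if tuple(a.get("marks", ())) != tuple(b.get("marks", ())):
                return False
        mine = {tuple(sorted(e)): self.graph.edges[e].get("relation") for e in self.graph.edges}
        theirs = {tuple(sorted(e)): other.graph.edges[e].get("relation") for e in other.graph.edges}
        return mine == theirs


def build_network(
    plastic_mirnas: set[str],
    target_map: pd.DataFrame,
    plastic_genes: set[str],
    interactions: pd.DataFrame,
    min_partner_links: int = 2,
) -> PlasticNetwork:
    """Assemble the three-layer network for one contrast.

    Target layer: predicted targets of the plastic miRNAs that are themselves
    differentially expressed.  Partner layer: interaction neighbors of the
    target layer linked to >= ``min_partner_links`` distinct targets (the
    "more than one miRNA target" rule); genes already in the target layer are
    never demoted to partners.  Interactions are undirected and self-loops are
    dropped.
    """
    net = PlasticNetwork()
    g = net.graph

    pairs = target_map[
        target_map["mirna"].isin(plastic_mirnas) & target_map["target"].isin(plastic_genes)
    ][["mirna", "target"]].drop_duplicates()
    targets = set(pairs["target"])
    for m in sorted(set(pairs["mirna"])):
        g.add_node(m, layer="mirna", marks=())
    for t in sorted(targets):
        g.add_node(t, layer="target", marks=())
    for row in pairs.itertuples():
        g.add_edge(row.mirna, row.target, relation="targets")

    partner_links: dict[str, set[str]] = {}
    for row in interactions.itertuples():
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            continue
        for partner, target in ((a, b), (b, a)):
            if target in targets and partner not in targets and partner not in set(pairs["mirna"]):
                partner_links.setdefault(partner, set()).add(target)
    for partner in sorted(partner_links):
        links = partner_links[partner]
        if len(links) >= min_partner_links:
            g.add_node(partner, layer="partner", marks=())
            for t in sorted(links):
                g.add_edge(partner, t, relation="interacts")
    return net


def overlay_histone_marks(
    network: PlasticNetwork,
    peak2gene_by_mark: dict[str, pd.DataFrame],
    diff_peaks_by_mark: dict[str, set[str]],
) -> PlasticNetwork:
    """Annotate gene and miRNA-locus nodes with differential histone marks.

    A node gets mark M iff some differential M peak is assigned to it by that
    mark's peak->gene map.  Gene ids in the maps that are absent from the
    network are ignored with a warning; multi-mark annotation accumulates.
    """
    g = network.graph
    unknown: set[str] = set()
    per_node: dict[str, set[str]] = {n: set(g.nodes[n].get("marks", ())) for n in g.nodes}
    for mark, mapping in peak2gene_by_mark.items():
        diff_peaks = diff_peaks_by_mark.get(mark, set())
        hits = mapping[mapping["peak_id"].isin(diff_peaks)]
        for gid in hits["gene_id"]:
            if gid in per_node:
                per_node[gid].add(mark)
            else:
                unknown.add(gid)
    if unknown:
        warnings.warn(f"{len(unknown)} mapped gene ids are not network nodes; ignored")
    for node, marks in per_node.items():
        g.nodes[node]["marks"] = tuple(sorted(marks))
    return network


def export_network(network: PlasticNetwork, prefix: str, fmt: str = "tsv") -> list[str]:
    """Write the network as ``tsv`` (nodes+edges), ``graphml`` or ``sif``.

    tsv and graphml round-trip losslessly through :func:`import_network`;
    sif carries typed edges only (``targets`` / ``interacts``).
    Returns the list of written paths.
    """
    g = network.graph
    if fmt == "tsv":
        nodes = pd.DataFrame(
            {
                "node": list(g.nodes),
                "layer": [g.nodes[n]["layer"] for n in g.nodes],
                "marks": [",".join(g.nodes[n].get("marks", ())) for n in g.nodes],
            }
        )
        edges = pd.DataFrame(
            [
                {"source": a, "target": b, "relation": g.edges[a, b].get("relation", "")}
                for a, b in g.edges
            ],
            columns=["source", "target", "relation"],
        )
        paths = [f"{prefix}.nodes.tsv", f"{prefix}.edges.tsv"]
        nodes.to_csv(paths[0], sep="\t", index=False)
        edges.to_csv(paths[1], sep="\t", index=False)
        return paths
    if fmt == "graphml":
        h = nx.Graph()
        for n, d in g.nodes(data=True):
            h.add_node(n, layer=d["layer"], marks=",".join(d.get("marks", ())))
        for a, b, d in g.edges(data=True):
            h.add_edge(a, b, relation=d.get("relation", ""))
        path = f"{prefix}.graphml"
        nx.write_graphml(h, path)
        return [path]
    if fmt == "sif":
        path = f"{prefix}.sif"
        with open(path, "w") as fh:
            for a, b, d in g.edges(data=True):
                fh.write(f"{a}\t{d.get('relation', 'interacts')}\t{b}\n")
        return [path]
    raise ValueError(f"unknown format {fmt!r}")


def import_network(prefix: str, fmt: str = "tsv") -> PlasticNetwork:
    """Read a network written by :func:`export_network` (tsv or graphml)."""
    net = PlasticNetwork()
    g = net.graph
    if fmt == "tsv":
        nodes = pd.read_csv(f"{prefix}.nodes.tsv", sep="\t", keep_default_na=False)
        edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t", keep_default_na=False)
        for row in nodes.itertuples():
            marks = tuple(m for m in str(row.marks).split(",") if m)
            g.add_node(str(row.node), layer=row.layer, marks=marks)
        for row in edges.itertuples():
            g.add_edge(str(row.source), str(row.target), relation=row.relation)
        return net
    if fmt == "graphml":
        h = nx.read_graphml(f"{prefix}.graphml")
        for n, d in h.nodes(data=True):
            marks = tuple(m for m in str(d.get("marks", "")).split(",") if m)
            g.add_node(str(n), layer=d["layer"], marks=marks)
        for a, b, d in h.edges(data=True):
            g.add_edge(str(a), str(b), relation=d.get("relation", ""))
        return net
    raise ValueError(f"unknown format {fmt!r}")
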