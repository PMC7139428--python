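"""Signed bipartite miRNA-target network and hub statistics.

Each interaction between a differentially expressed miRNA and a target
gene becomes an edge weighted +1 (regulating miRNA upregulated) or -1
(downregulated).  For every target gene the degree is its number of
incident edges and the node strength is the sum of the incident
weights, so ``|strength| <= degree`` and strength has the parity of the
degree.  Targets at the maximal observed degree are the "target hubs":
genes under the densest combinatorial regulation by the DE miRNAs and
therefore the most likely to shift in expression themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from mirhub.de import DEResult
from mirhub.targets import InteractionRecord, normalize_gene_name, normalize_mirna_name

__all__ = ["SignedNetwork", "HubReport", "build_network", "node_strength", "find_hubs"]


@dataclass
class SignedNetwork:
    """Bipartite graph of DE miRNAs (with direction) and target genes."""

    graph: nx.Graph

    @property
    def mirna_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "mirna")

    @property
    def gene_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "gene")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        g = normalize_gene_name(gene)
        if g not in self.graph or self.graph.nodes[g]["kind"] != "gene":
            raise KeyError(f"unknown gene {gene!r}")
        return int(self.graph.degree(g))

    def strength(self, gene: str) -> int:
        g = normalize_gene_name(gene)
        if g not in self.graph or self.graph.nodes[g]["kind"] != "gene":
            raise KeyError(f"unknown gene {gene!r}")
        return int(sum(d["weight"] for _, _, d in self.graph.edges(g, data=True)))

    def gene_table(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "degree": self.degree(g), "strength": self.strength(g)}
            for g in self.gene_nodes
        ]
        return pd.DataFrame(rows, columns=["gene", "degree", "strength"])

    # --- exports

    def to_sif(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m, g, d in sorted(self.graph.edges(data=True)):
                if self.graph.nodes[m]["kind"] != "mirna":
                    m, g = g, m
                fh.write(f"{m}\tregulates\t{g}\n")

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)

    def write_gene_table(self, path: str | Path) -> None:
        self.gene_table().to_csv(path, sep="\t", index=False)


@dataclass
class HubReport:
    """Target genes at (or above) the hub-defining degree."""

    max_degree: int
    hubs: list[tuple[str, int, int]]  # (gene, degree, strength)

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.hubs]


def build_network(interactions: Sequence[InteractionRecord], de: Sequence[DEResult]) -> SignedNetwork:
    """Assemble the signed bipartite graph from integrated interactions.

    Every interaction's miRNA must carry a significant DE direction;
    a miRNA without one is an upstream contract violation and raises.
    """
    directions = {
        normalize_mirna_name(r.mirna): r.direction
        for r in de
        if r.direction in ("up", "down")
    }
    graph = nx.Graph()
    for rec in interactions:
        mirna = normalize_mirna_name(rec.mirna)
        gene = normalize_gene_name(rec.gene)
        if mirna not in directions:
            raise ValueError(f"interaction miRNA {rec.mirna!r} is not significantly DE")
        direction = directions[mirna]
        weight = 1 if direction == "up" else -1
        graph.add_node(mirna, kind="mirna", direction=direction, bipartite=0)
        graph.add_node(gene, kind="gene", bipartite=1)
        graph.add_edge(mirna, gene, weight=weight)
    return SignedNetwork(graph)


def node_strength(net: SignedNetwork, gene: str) -> int:
    """Sum of signed incident edge weights of a target gene."""
    return net.strength(gene)


def find_hubs(net: SignedNetwork, policy: str = "max_degree", k: int | None = None) -> HubReport:
    """Identify target hubs.

    ``max_degree`` (default) returns every gene at the maximal observed
    degree, mirroring the definition of a target hub as a gene regulated
    by the highest number of DE miRNAs; ``threshold`` returns genes with
    degree >= ``k``.
    """
    genes = net.gene_nodes
    if not genes:
        raise ValueError("network has no gene nodes")
    degrees = {g: net.degree(g) for g in genes}
    max_degree = max(degrees.values())
    if policy == "max_degree":
        cut = max_degree
    elif policy == "threshold":
        if k is None or k < 1:
            raise ValueError("threshold policy needs k >= 1")
        cut = k
    else:
        raise ValueError(f"unknown hub policy {policy!r}")
    hubs = [(g, degrees[g], net.strength(g)) for g in genes if degrees[g] >= cut]
    hubs.sort(key=lambda t: (-t[1], t[0]))
    return HubReport(max_degree=max_degree, hubs=hubs)
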