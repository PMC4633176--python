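"""Anti-correlated bipartite miRNA:mRNA regulatory network construction.

The network intersects three consensus layers: selected miRNAs (with a
deregulation direction), consensus predicted targets, and consensus
differentially expressed genes (with a direction).  An edge (miRNA,
gene) is kept only when the pair is a consensus target, both endpoints
survived their consensus filters, and the directions are *opposite* —
the signature of repression (miRNA up / target down, or miRNA down /
target up).  Concordant pairs are excluded but preserved in a discard
log for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

EDGE_COLUMNS = ["mirna", "gene", "mirna_direction", "gene_direction", "vote_count"]


@dataclass
class RegulatoryNetwork:
    """Bipartite edge set between deregulated miRNAs and their targets."""

    tumor_type: str
    edges: pd.DataFrame
    discarded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna", "gene", "reason"])
    )

    @property
    def mirna_nodes(self) -> list[str]:
        return sorted(self.edges["mirna"].unique())

    @property
    def gene_nodes(self) -> list[str]:
        return sorted(self.edges["gene"].unique())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_node(row.mirna, kind="mirna", direction=row.mirna_direction,
                       bipartite=0)
            g.add_node(row.gene, kind="gene", direction=row.gene_direction,
                       bipartite=1)
            g.add_edge(row.mirna, row.gene, vote_count=int(row.vote_count))
        return g


def build_network(
    selected: pd.DataFrame,
    targets: pd.DataFrame,
    genes: pd.DataFrame,
    tumor_type: str,
) -> RegulatoryNetwork:
    """Join the three consensus layers into an anti-correlated network.

    Parameters
    ----------
    selected
        Tally table from :func:`mirconsensus.literature.select_consensus`;
        only rows with ``status == "selected"`` and the given tumor type
        enter the join.
    targets
        Consensus target table (``mirna gene vote_count``).
    genes
        Per-gene consensus DE table from
        :func:`mirconsensus.expression.call_consensus`; only
        ``status == "consensus"`` rows enter.
    """
    sel = selected[
        (selected["status"] == "selected")
        & (selected["tumor_type"] == tumor_type)
    ][["mirna", "direction"]].rename(columns={"direction": "mirna_direction"})
    if sel.empty:
        warnings.warn(
            f"no selected miRNAs for tumor type {tumor_type}; network is empty",
            stacklevel=2,
        )
    de = genes[genes["status"] == "consensus"][["gene", "direction"]].rename(
        columns={"direction": "gene_direction"}
    )
    cand = (
        targets[["mirna", "gene", "vote_count"]]
        .merge(sel, on="mirna")
        .merge(de, on="gene")
    )
    anti = cand["mirna_direction"] != cand["gene_direction"]
    edges = cand.loc[anti, EDGE_COLUMNS].sort_values(
        ["mirna", "gene"], ignore_index=True
    )
    discarded = cand.loc[~anti, ["mirna", "gene"]].assign(reason="concordant")
    return RegulatoryNetwork(
        tumor_type=tumor_type,
        edges=edges,
        discarded=discarded.reset_index(drop=True),
    )


def target_gene_list(network: RegulatoryNetwork) -> list[str]:
    """De-duplicated, sorted gene nodes — the query list for enrichment."""
    return network.gene_nodes


def write_sif(network: RegulatoryNetwork, path) -> None:
    """Write ``mirna represses gene`` triples (Cytoscape SIF)."""
    with open(path, "w") as fh:
        for row in network.edges.itertuples(index=False):
            fh.write(f"{row.mirna}\trepresses\t{row.gene}\n")


def write_graphml(network: RegulatoryNetwork, path) -> None:
    nx.write_graphml(network.to_networkx(), path)


def write_gene_list(network: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        for gene in target_gene_list(network):
            fh.write(gene + "\n")
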