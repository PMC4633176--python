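"""End-to-end run of the consensus pipeline on synthetic inputs.

Chains the generators and the analysis stages — literature selection,
target-vote consensus, cross-dataset DE consensus, anti-correlated
network, enrichment — and scores the recovered structure against the
planted truth.  Used by the test suite and as a worked example.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import enrichment, expression, literature, network, simulate, targets


@dataclass
class PipelineResult:
    selected: pd.DataFrame
    consensus_targets: pd.DataFrame
    consensus_genes: pd.DataFrame
    net: network.RegulatoryNetwork
    enrichment_table: pd.DataFrame
    truth: dict
    metrics: dict


def _precision_recall(found: set, expected: set) -> tuple[float, float]:
    if not found:
        return (1.0 if not expected else 0.0), (1.0 if not expected else 0.0)
    tp = len(found & expected)
    return tp / len(found), tp / len(expected) if expected else 1.0


def run_synthetic_pipeline(cfg: simulate.SimulationConfig) -> PipelineResult:
    calls, call_truth = simulate.gen_call_matrix(cfg)
    tallies = literature.select_consensus(literature.tally(calls), m=3)
    sel = tallies[tallies["status"] == literature.STATUS_SELECTED]
    selected_mirnas = dict(zip(sel["mirna"], sel["direction"]))

    votes, vote_truth = simulate.gen_votes(cfg, call_truth["expected_selected"])
    counts = targets.count_votes(
        votes, simulate._algorithm_names(cfg.n_algorithms)
    )
    cons_targets = targets.consensus_targets(
        counts, a=cfg.min_votes, n_algorithms=cfg.n_algorithms
    )

    de, de_truth = simulate.gen_de_tables(cfg, vote_truth["target_directions"])
    cons_genes = expression.call_consensus(de, f=cfg.de_support_fraction)

    net = network.build_network(tallies, cons_targets, cons_genes, cfg.tumor_type)
    query = network.target_gene_list(net)
    sets, planted_set = simulate.gen_gene_sets(cfg, query)
    background = sorted(de["gene"].unique())
    enr = enrichment.enrich(query, sets, background)

    truth = {
        **call_truth,
        **vote_truth,
        **de_truth,
        "planted_set": planted_set,
        "planted_edges": sorted(
            (m, g)
            for m, gs in vote_truth["planted_targets"].items()
            for g in gs
        ),
    }

    mirna_p, mirna_r = _precision_recall(
        set(selected_mirnas), set(call_truth["expected_selected"])
    )
    found_edges = set(map(tuple, net.edges[["mirna", "gene"]].itertuples(index=False)))
    edge_p, edge_r = _precision_recall(found_edges, set(map(tuple, truth["planted_edges"])))
    metrics = {
        "mirna_precision": mirna_p,
        "mirna_recall": mirna_r,
        "edge_precision": edge_p,
        "edge_recall": edge_r,
        "planted_set_rank": int(
            enr.index[enr["set_name"] == planted_set][0] + 1
        ),
        "n_edges": len(net.edges),
    }
    return PipelineResult(
        selected=tallies,
        consensus_targets=cons_targets,
        consensus_genes=cons_genes,
        net=net,
        enrichment_table=enr,
        truth=truth,
        metrics=metrics,
    )
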