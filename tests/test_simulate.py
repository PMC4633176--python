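"""Synthetic-data generators: determinism and planted-structure contracts."""

import numpy as np
import pytest
from scipy import stats

from mirconsensus import literature, targets
from mirconsensus.simulate import (
    SimulationConfig,
    gen_call_matrix,
    gen_cohort,
    gen_de_tables,
    gen_gene_sets,
    gen_votes,
)
from mirconsensus.clinical import zscore_classify
from mirconsensus.expression import call_consensus

SMALL = dict(n_mirnas=40, n_planted_mirnas=8, n_genes=300,
             planted_targets_per_mirna=5, cohort_n=60)


def test_same_seed_gives_identical_outputs_everywhere():
    cfg = SimulationConfig(seed=42, **SMALL)
    for gen in (gen_call_matrix, gen_cohort):
        a, _ = gen(cfg)
        b, _ = gen(SimulationConfig(seed=42, **SMALL))
        if hasattr(a, "to_csv"):
            assert a.to_csv() == b.to_csv()
        else:
            assert a.expression.to_csv() == b.expression.to_csv()
            assert a.clinical.to_csv() == b.clinical.to_csv()


def test_substreams_are_independent_of_other_sections():
    # resizing the cohort must not perturb the call matrix
    a, _ = gen_call_matrix(SimulationConfig(seed=3, **SMALL))
    resized = dict(SMALL, cohort_n=200)
    b, _ = gen_call_matrix(SimulationConfig(seed=3, **resized))
    assert a.to_csv() == b.to_csv()


def test_noise_free_calls_recover_exactly_the_planted_panel():
    cfg = SimulationConfig(seed=5, noise_call_rate=0.0,
                           inconsistent_fraction=0.0, **SMALL)
    calls, truth = gen_call_matrix(cfg)
    out = literature.select_consensus(literature.tally(calls), m=3)
    selected = dict(
        zip(out.loc[out.status == "selected", "mirna"],
            out.loc[out.status == "selected", "direction"])
    )
    assert selected == truth["expected_selected"]


def test_planted_inconsistents_get_mixed_directions():
    cfg = SimulationConfig(seed=6, noise_call_rate=0.0,
                           inconsistent_fraction=0.5, **SMALL)
    calls, truth = gen_call_matrix(cfg)
    out = literature.select_consensus(literature.tally(calls), m=3)
    inconsistent = set(out.loc[out.status == "inconsistent", "mirna"])
    assert inconsistent == set(truth["planted_inconsistent"])


def test_background_free_votes_recover_exactly_the_planted_targets():
    cfg = SimulationConfig(seed=7, background_vote_prob=0.0, **SMALL)
    mirnas = {f"miR-syn{i:03d}": "up" for i in range(4)}
    votes, truth = gen_votes(cfg, mirnas)
    counts = targets.count_votes(votes)
    cons = targets.consensus_targets(counts, a=cfg.min_votes)
    found = {(m, g) for m, g in cons[["mirna", "gene"]].values}
    expected = {(m, g) for m, gs in truth["planted_targets"].items() for g in gs}
    assert found == expected


def test_spurious_vote_rate_matches_binomial_tail():
    cfg = SimulationConfig(seed=8, n_genes=1500, n_planted_mirnas=8,
                           planted_targets_per_mirna=5,
                           background_vote_prob=0.2)
    mirnas = {f"miR-syn{i:03d}": "up" for i in range(8)}  # 12000 pairs
    votes, truth = gen_votes(cfg, mirnas)
    counts = targets.count_votes(votes)
    planted = {(m, g) for m, gs in truth["planted_targets"].items() for g in gs}
    mask = [
        (m, g) not in planted for m, g in counts[["mirna", "gene"]].values
    ]
    n_pairs = 8 * cfg.n_genes - len(planted)
    n_spurious = int((counts.loc[mask, "vote_count"] >= 5).sum())
    expected_rate = stats.binom.sf(4, 8, 0.2)
    se = np.sqrt(expected_rate * (1 - expected_rate) / n_pairs)
    assert abs(n_spurious / n_pairs - expected_rate) < 4 * se


def test_planted_de_genes_all_reach_consensus_when_nulls_cannot_veto():
    cfg = SimulationConfig(seed=9, **SMALL)
    planted = {f"G{i:04d}": ("up" if i % 2 else "down") for i in range(30)}
    de, truth = gen_de_tables(cfg, planted)
    # restrict to planted support rows: alpha above planted but below any veto
    out = call_consensus(de, alpha=0.05, f=0.5).set_index("gene")
    ok = sum(
        out.loc[g, "status"] == "consensus" and out.loc[g, "direction"] == d
        for g, d in planted.items()
    )
    # a planted gene can only fail via a significant opposite null draw
    assert ok >= 0.85 * len(planted)
    assert truth["n_support"] == 3


def test_gene_set_collection_has_planted_overlap():
    cfg = SimulationConfig(seed=10, **SMALL)
    query = [f"G{i:04d}" for i in range(60)]
    sets, planted_name = gen_gene_sets(cfg, query)
    assert len(sets) == cfg.n_gene_sets
    assert len(sets[planted_name] & set(query)) >= cfg.planted_set_overlap
    assert all(len(s) == cfg.gene_set_size for s in sets.values())


class TestGenCohort:
    def test_bad_hazard_ratio_rejected(self):
        with pytest.raises(ValueError, match="hazard_ratio"):
            SimulationConfig(hazard_ratio=0.0)

    def test_zscore_recall_on_planted_alterations(self):
        # diploid-style reference (the unaltered samples): a 3-sd shift in
        # two genes leaves a sample undetected at |z| >= 2 only when both
        # baselines fall below -1 sd, i.e. ~(1 - 0.159^2) recall
        hits = total = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, cohort_n=300)
            cohort, truth = gen_cohort(cfg)
            unaltered = cohort.samples.difference(truth["altered_samples"])
            calls = zscore_classify(
                cohort, truth["gene_list"], reference_samples=unaltered
            )
            flagged = set(calls.loc[calls["altered"], "sample_id"])
            hits += len(flagged & set(truth["altered_samples"]))
            total += len(truth["altered_samples"])
        assert hits / total >= 0.95

    def test_censoring_rate_roughly_respected(self):
        cfg = SimulationConfig(seed=11, cohort_n=3000, altered_fraction=0.0,
                               censoring_rate=0.25)
        cohort, _ = gen_cohort(cfg)
        censored = 1 - cohort.clinical["os_event"].mean()
        assert censored == pytest.approx(0.25, abs=0.04)

    def test_strong_hazard_ratio_separates_survival(self):
        from mirconsensus.clinical import logrank

        cfg = SimulationConfig(seed=12, cohort_n=200, hazard_ratio=3.0)
        cohort, truth = gen_cohort(cfg)
        altered = cohort.clinical.index.isin(truth["altered_samples"])
        clin = cohort.clinical
        res = logrank(
            clin.loc[altered, "os_time"], clin.loc[altered, "os_event"],
            clin.loc[~altered, "os_time"], clin.loc[~altered, "os_event"],
        )
        assert res.p < 0.05
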