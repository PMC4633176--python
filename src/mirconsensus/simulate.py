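"""Synthetic inputs with planted, recoverable structure.

Every stage of the consensus pipeline gets a generator that emulates
the statistical shape of its real-world input and returns the planted
ground truth alongside:

* :func:`gen_call_matrix` — multi-study deregulation calls with planted
  consensus miRNAs, optional planted inconsistents, and sparse noise;
* :func:`gen_votes` — 8-algorithm target-prediction votes where planted
  pairs receive >= 5 votes and background pairs draw Binomial votes;
* :func:`gen_de_tables` — per-dataset differential-expression tables in
  which planted anti-correlated genes are significant in enough
  datasets to clear the concordance rule;
* :func:`gen_gene_sets` — a GMT-style collection with one set planted
  to overlap the anti-correlated targets far beyond chance;
* :func:`gen_cohort` — a TCGA-style cohort where altered samples carry
  large expression shifts and an elevated exponential hazard.

All generators are pure functions of ``(config, seed)``.  Each draws
from its own substream (``numpy.random.SeedSequence(seed).spawn``, one
child per generator in a fixed order), so resizing the cohort never
perturbs the call matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clinical import ClinicalCohort
from .targets import DEFAULT_ALGORITHMS

_STREAMS = {"calls": 0, "votes": 1, "de": 2, "gene_sets": 3, "cohort": 4}


@dataclass
class SimulationConfig:
    """Knobs for all generators; defaults give clear desk-scale recovery.

    Study-design defaults mirror the shape of the real inputs: ~10
    profiling studies with a handful of strongly replicated miRNAs, an
    8-algorithm prediction panel with a 5-vote consensus bar, 5
    expression datasets under the half-or-more concordance rule, and a
    388-sample cohort with about a third of samples altered.  Effect
    sizes (3-sd expression shifts, hazard ratio 3) are deliberately
    large so that recovery failures indicate pipeline defects, not
    borderline power.
    """

    seed: int = 0
    # literature layer
    n_studies: int = 10
    n_mirnas: int = 200
    n_planted_mirnas: int = 20
    planted_report_count: int = 4
    noise_call_rate: float = 0.05
    inconsistent_fraction: float = 0.1
    tumor_type: str = "PTC"
    # target-prediction layer
    n_algorithms: int = 8
    n_genes: int = 2000
    planted_targets_per_mirna: int = 10
    background_vote_prob: float = 0.2
    min_votes: int = 5
    # expression layer
    n_datasets: int = 5
    de_effect_lfc: float = 2.0
    de_alpha_planted: float = 0.01
    de_support_fraction: float = 0.5
    # enrichment layer
    n_gene_sets: int = 20
    gene_set_size: int = 40
    planted_set_overlap: int = 25
    # clinical layer
    cohort_n: int = 388
    cohort_n_genes: int = 10
    altered_fraction: float = 0.33
    alteration_shift_sd: float = 3.0
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        counts = {
            "n_studies": self.n_studies,
            "n_mirnas": self.n_mirnas,
            "n_planted_mirnas": self.n_planted_mirnas,
            "planted_report_count": self.planted_report_count,
            "n_algorithms": self.n_algorithms,
            "n_genes": self.n_genes,
            "planted_targets_per_mirna": self.planted_targets_per_mirna,
            "n_datasets": self.n_datasets,
            "n_gene_sets": self.n_gene_sets,
            "gene_set_size": self.gene_set_size,
            "cohort_n": self.cohort_n,
            "cohort_n_genes": self.cohort_n_genes,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("noise_call_rate", "inconsistent_fraction", "background_vote_prob",
                     "altered_fraction", "de_support_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0,1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.n_planted_mirnas > self.n_mirnas:
            raise ValueError("more planted miRNAs than miRNAs")
        if self.planted_report_count >= self.n_studies:
            raise ValueError(
                "planted_report_count must leave at least one study free "
                "for planted-inconsistent opposite calls"
            )
        if self.planted_report_count < 3:
            raise ValueError("planted miRNAs need >= 3 concordant reports")
        if self.n_planted_mirnas * self.planted_targets_per_mirna > self.n_genes:
            raise ValueError("not enough genes for disjoint planted target blocks")
        if not 1 <= self.min_votes <= self.n_algorithms:
            raise ValueError("min_votes outside [1, n_algorithms]")
        if self.planted_set_overlap > self.gene_set_size:
            raise ValueError("planted_set_overlap exceeds gene_set_size")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(cfg: SimulationConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _mirna_names(n: int) -> list[str]:
    return [f"miR-syn{i:03d}" for i in range(n)]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _algorithm_names(n: int) -> tuple[str, ...]:
    if n == len(DEFAULT_ALGORITHMS):
        return DEFAULT_ALGORITHMS
    return tuple(f"alg{i:02d}" for i in range(n))


def gen_call_matrix(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Multi-study call table with planted consensus miRNAs among noise.

    Planted miRNAs receive ``planted_report_count`` unanimous calls from
    distinct studies; a fraction of them additionally receive one
    opposite call (planted inconsistents).  Noise calls land on free
    (study, miRNA) cells at ``noise_call_rate`` — concordant for planted
    miRNAs, random direction for the rest — so planted recovery is
    limited only by spurious unanimous runs among null miRNAs.
    """
    rng = _rng(cfg, "calls")
    mirnas = _mirna_names(cfg.n_mirnas)
    studies = [f"study{j:02d}" for j in range(cfg.n_studies)]
    planted_idx = rng.choice(cfg.n_mirnas, cfg.n_planted_mirnas, replace=False)
    directions = rng.choice(["up", "down"], cfg.n_planted_mirnas)
    n_inc = int(round(cfg.n_planted_mirnas * cfg.inconsistent_fraction))
    inconsistent_idx = set(rng.choice(planted_idx, n_inc, replace=False).tolist())

    called = np.zeros((cfg.n_studies, cfg.n_mirnas), dtype=bool)
    rows: list[tuple[str, str, str, str]] = []
    planted_dir = {int(i): d for i, d in zip(planted_idx, directions)}
    for i, direction in planted_dir.items():
        support = rng.choice(cfg.n_studies, cfg.planted_report_count, replace=False)
        for j in support:
            rows.append((studies[j], cfg.tumor_type, mirnas[i], direction))
            called[j, i] = True
        if i in inconsistent_idx:
            free = np.flatnonzero(~called[:, i])
            j = int(rng.choice(free))
            opposite = "down" if direction == "up" else "up"
            rows.append((studies[j], cfg.tumor_type, mirnas[i], opposite))
            called[j, i] = True

    noise = (rng.random((cfg.n_studies, cfg.n_mirnas)) < cfg.noise_call_rate) & ~called
    for j, i in zip(*np.nonzero(noise)):
        if int(i) in planted_dir:
            direction = planted_dir[int(i)]
        else:
            direction = str(rng.choice(["up", "down"]))
        rows.append((studies[j], cfg.tumor_type, mirnas[i], direction))

    calls = pd.DataFrame(
        rows, columns=["study_id", "tumor_type", "mirna", "direction"]
    ).sort_values(["mirna", "study_id"], ignore_index=True)
    truth = {
        "planted": {mirnas[i]: d for i, d in sorted(planted_dir.items())},
        "planted_inconsistent": sorted(mirnas[i] for i in inconsistent_idx),
        "expected_selected": {
            mirnas[i]: d
            for i, d in sorted(planted_dir.items())
            if i not in inconsistent_idx
        },
    }
    return calls, truth


def gen_votes(
    cfg: SimulationConfig, mirna_directions: dict[str, str]
) -> tuple[pd.DataFrame, dict]:
    """Prediction votes over (given miRNAs) x (all genes).

    Planted pairs — ``planted_targets_per_mirna`` disjoint genes per
    miRNA — get a uniform vote count in [min_votes, n_algorithms];
    every other pair draws Binomial(n_algorithms, background_vote_prob)
    votes.  Which algorithms cast the votes is uniformly random.
    """
    rng = _rng(cfg, "votes")
    mirnas = list(mirna_directions)
    genes = _gene_names(cfg.n_genes)
    algorithms = _algorithm_names(cfg.n_algorithms)
    k = cfg.planted_targets_per_mirna
    block = rng.permutation(cfg.n_genes)[: len(mirnas) * k]
    planted: dict[str, list[str]] = {
        m: sorted(genes[g] for g in block[i * k:(i + 1) * k])
        for i, m in enumerate(mirnas)
    }

    n_pairs = len(mirnas) * cfg.n_genes
    counts = rng.binomial(cfg.n_algorithms, cfg.background_vote_prob, size=n_pairs)
    counts = counts.reshape(len(mirnas), cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for i, m in enumerate(mirnas):
        cols = [gene_pos[g] for g in planted[m]]
        counts[i, cols] = rng.integers(cfg.min_votes, cfg.n_algorithms + 1,
                                       size=len(cols))
    counts = counts.ravel()
    # choose which algorithms voted: the `count` lowest of a random key per pair
    keys = rng.random((n_pairs, cfg.n_algorithms))
    ranks = keys.argsort(axis=1).argsort(axis=1)
    mask = ranks < counts[:, None]
    pair_idx, alg_idx = np.nonzero(mask)
    votes = pd.DataFrame(
        {
            "mirna": np.repeat(mirnas, cfg.n_genes)[pair_idx],
            "gene": np.tile(genes, len(mirnas))[pair_idx],
            "algorithm": np.asarray(algorithms)[alg_idx],
        }
    )
    truth = {
        "planted_targets": planted,
        "target_directions": {
            g: ("down" if mirna_directions[m] == "up" else "up")
            for m, gs in planted.items()
            for g in gs
        },
    }
    return votes, truth


def gen_de_tables(
    cfg: SimulationConfig, gene_directions: dict[str, str]
) -> tuple[pd.DataFrame, dict]:
    """Per-dataset DE tables with planted concordant significant genes.

    Planted genes (``gene_directions``) are significant with the stated
    sign in ``ceil(n_datasets * de_support_fraction)`` randomly chosen
    datasets and behave as nulls elsewhere; null genes draw uniform
    adjusted p-values and small symmetric log fold-changes everywhere.
    """
    rng = _rng(cfg, "de")
    genes = _gene_names(cfg.n_genes)
    datasets = [f"DS{d:02d}" for d in range(cfg.n_datasets)]
    n_support = math.ceil(cfg.n_datasets * cfg.de_support_fraction)

    adj_p = rng.uniform(0, 1, size=(cfg.n_datasets, cfg.n_genes))
    log_fc = rng.normal(0, 0.3, size=(cfg.n_datasets, cfg.n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, direction in gene_directions.items():
        i = gene_pos[g]
        support = rng.choice(cfg.n_datasets, n_support, replace=False)
        sign = 1.0 if direction == "up" else -1.0
        adj_p[support, i] = rng.uniform(0, cfg.de_alpha_planted, size=n_support)
        log_fc[support, i] = sign * cfg.de_effect_lfc * rng.uniform(
            0.75, 1.25, size=n_support
        )
    results = pd.DataFrame(
        {
            "dataset_id": np.repeat(datasets, cfg.n_genes),
            "gene": np.tile(genes, cfg.n_datasets),
            "log_fc": log_fc.ravel(),
            "adj_p": adj_p.ravel(),
        }
    )
    truth = {"planted_de": dict(sorted(gene_directions.items())),
             "n_support": n_support}
    return results, truth


def gen_gene_sets(
    cfg: SimulationConfig, query_genes: list[str]
) -> tuple[dict[str, set[str]], str]:
    """GMT-style collection with one set planted to overlap the query.

    The planted set takes ``planted_set_overlap`` genes from the query
    list (fewer when the query is shorter) topped up with background
    genes; the remaining sets are uniform draws from the background.
    Returns the collection and the planted set's name.
    """
    rng = _rng(cfg, "gene_sets")
    background = _gene_names(cfg.n_genes)
    n_overlap = min(cfg.planted_set_overlap, len(query_genes))
    planted = set(rng.choice(sorted(query_genes), n_overlap, replace=False))
    fill_pool = sorted(set(background) - set(query_genes))
    planted |= set(rng.choice(fill_pool, cfg.gene_set_size - n_overlap,
                              replace=False))
    sets: dict[str, set[str]] = {"pathway_planted": planted}
    for s in range(cfg.n_gene_sets - 1):
        sets[f"pathway_{s:03d}"] = set(
            rng.choice(background, cfg.gene_set_size, replace=False)
        )
    return sets, "pathway_planted"


def gen_cohort(cfg: SimulationConfig) -> tuple[ClinicalCohort, dict]:
    """TCGA-style cohort with planted altered samples and a survival gap.

    Altered samples (``altered_fraction`` of the cohort) carry a shift
    of ``alteration_shift_sd`` standard deviations, random sign, in one
    or two of the listed genes, and draw exponential survival at
    ``hazard_ratio`` times the baseline rate (baseline median 60
    months).  Censoring is an independent exponential time tuned so
    that roughly ``censoring_rate`` of baseline subjects are censored.
    """
    rng = _rng(cfg, "cohort")
    samples = [f"S{i:04d}" for i in range(cfg.cohort_n)]
    genes = [f"CG{i:02d}" for i in range(cfg.cohort_n_genes)]
    expr = rng.normal(0, 1, size=(cfg.cohort_n, len(genes)))
    n_altered = int(round(cfg.cohort_n * cfg.altered_fraction))
    altered_idx = rng.choice(cfg.cohort_n, n_altered, replace=False)
    for i in altered_idx:
        # two co-altered genes per sample, as gene-set level deregulation
        # tends to move co-members together
        hit = rng.choice(len(genes), 2, replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(hit))
        expr[i, hit] += signs * cfg.alteration_shift_sd

    altered = np.zeros(cfg.cohort_n, dtype=bool)
    altered[altered_idx] = True
    base_rate = math.log(2) / 60.0  # baseline median survival 60 months
    rate = np.where(altered, base_rate * cfg.hazard_ratio, base_rate)
    event_time = rng.exponential(1.0 / rate)
    if cfg.censoring_rate > 0:
        cens_rate = base_rate * cfg.censoring_rate / (1 - cfg.censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=cfg.cohort_n)
    else:
        cens_time = np.full(cfg.cohort_n, np.inf)
    os_time = np.minimum(event_time, cens_time)
    os_event = (event_time <= cens_time).astype(int)

    def _biased_flag(p_altered: float, p_other: float) -> np.ndarray:
        p = np.where(altered, p_altered, p_other)
        return rng.random(cfg.cohort_n) < p

    clinical = pd.DataFrame(
        {
            "risk_group": np.where(_biased_flag(0.8, 0.2), "high", "low"),
            "ete": _biased_flag(0.7, 0.2),
            "lnm": _biased_flag(0.7, 0.25),
            "os_time": os_time,
            "os_event": os_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    cohort = ClinicalCohort(
        expression=pd.DataFrame(expr, index=clinical.index, columns=genes),
        clinical=clinical,
    )
    truth = {
        "altered_samples": sorted(samples[i] for i in altered_idx),
        "gene_list": genes,
    }
    return cohort, truth
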