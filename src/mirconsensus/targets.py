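"""Consensus filtering of multi-algorithm miRNA target predictions.

Target-prediction servers in the miRWalk mold run a panel of independent
algorithms (seed matching, conservation, thermodynamics...) and report,
per (miRNA, gene) pair, which algorithms predict the interaction.  A
pair is retained as a *consensus target* when at least ``a`` of the
``A`` declared algorithms agree (defaults 5 of 8).
"""

from __future__ import annotations

import pandas as pd

# Panel of the comparative predictors a miRWalk-style query aggregates.
DEFAULT_ALGORITHMS = (
    "miRWalk",
    "miRanda",
    "miRDB",
    "PICTAR",
    "PITA",
    "RNA22",
    "RNAhybrid",
    "TargetScan",
)

VOTE_COLUMNS = ["mirna", "gene", "algorithm"]


def load_votes(path) -> pd.DataFrame:
    """Read a tab-separated vote table ``mirna gene algorithm``."""
    votes = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in VOTE_COLUMNS if c not in votes.columns]
    if missing:
        raise ValueError(f"vote table lacks columns: {missing}")
    return votes[VOTE_COLUMNS]


def count_votes(
    votes: pd.DataFrame, algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
) -> pd.DataFrame:
    """Collapse raw votes to one row per (miRNA, gene) with a vote count.

    Votes from algorithms outside the declared roster, and duplicated
    (miRNA, gene, algorithm) rows, are rejected — both indicate a
    misjoined input rather than something safely ignorable.
    """
    missing = [c for c in VOTE_COLUMNS if c not in votes.columns]
    if missing:
        raise ValueError(f"vote table lacks columns: {missing}")
    votes = votes[VOTE_COLUMNS]
    unknown = sorted(set(votes["algorithm"]) - set(algorithms))
    if unknown:
        raise ValueError(f"votes from undeclared algorithms: {unknown}")
    if votes.duplicated().any():
        dups = votes[votes.duplicated()]
        raise ValueError(
            "duplicate (mirna, gene, algorithm) votes:\n" + dups.to_string(index=False)
        )
    if votes.empty:
        return pd.DataFrame(columns=["mirna", "gene", "vote_count"])
    return (
        votes.groupby(["mirna", "gene"], as_index=False)
        .agg(vote_count=("algorithm", "size"))
        .sort_values(["mirna", "gene"], ignore_index=True)
    )


def consensus_targets(
    vote_counts: pd.DataFrame, a: int = 5, n_algorithms: int = len(DEFAULT_ALGORITHMS)
) -> pd.DataFrame:
    """Retain (miRNA, gene) pairs predicted by at least ``a`` algorithms."""
    if not 1 <= a <= n_algorithms:
        raise ValueError(f"threshold a={a} outside [1, {n_algorithms}]")
    if (vote_counts["vote_count"] > n_algorithms).any():
        raise ValueError("vote_count exceeds the declared algorithm roster size")
    kept = vote_counts[vote_counts["vote_count"] >= a]
    return kept.reset_index(drop=True)
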