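"""Cross-dataset concordance calls for tumor-vs-normal differential expression.

Each input dataset contributes, per gene, a log2 fold-change and an
adjusted p-value (the standard GEO2R/limma export).  A dataset
*supports* a direction for a gene when ``adj_p < alpha`` and the
fold-change sign matches.  A gene reaches *consensus* when the
supporting fraction is at least ``f`` (default: half or more of the
datasets) and no dataset significantly supports the opposite direction;
significant support in both directions marks it *conflicting*; anything
else is *unsupported*.

No effect sizes are pooled — this is vote counting, chosen because the
input datasets come from heterogeneous platforms whose fold-changes are
not directly comparable.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

DE_COLUMNS = ["dataset_id", "gene", "log_fc", "adj_p"]
# GEO2R column spellings accepted on input.
_COLUMN_ALIASES = {
    "logFC": "log_fc",
    "adj.P.Val": "adj_p",
    "Gene.symbol": "gene",
    "SYMBOL": "gene",
}

STATUS_CONSENSUS = "consensus"
STATUS_CONFLICTING = "conflicting"
STATUS_UNSUPPORTED = "unsupported"


def load_de_table(path, dataset_id: str) -> pd.DataFrame:
    """Read one per-dataset DE table (``gene logFC adj.P.Val`` or snake_case)."""
    df = pd.read_csv(path, sep="\t").rename(columns=_COLUMN_ALIASES)
    missing = [c for c in ("gene", "log_fc", "adj_p") if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {path} lacks columns: {missing}")
    df = df[["gene", "log_fc", "adj_p"]].assign(dataset_id=dataset_id)
    if df.duplicated(["gene"]).any():
        dups = df.loc[df.duplicated(["gene"]), "gene"].unique()
        raise ValueError(
            f"DE table {path} has multiple rows per gene (collapse probes "
            f"to genes upstream): {list(dups[:5])}"
        )
    return df[DE_COLUMNS]


def load_manifest(path) -> pd.DataFrame:
    """Read and concatenate the datasets listed in a manifest.

    The manifest is a TSV with columns ``dataset_id``, ``path`` and
    optionally ``tumor_type``; relative paths resolve against the
    manifest's directory.
    """
    from pathlib import Path

    manifest = pd.read_csv(path, sep="\t", dtype=str)
    base = Path(path).parent
    tables = [
        load_de_table(base / row["path"], row["dataset_id"])
        for _, row in manifest.iterrows()
    ]
    return pd.concat(tables, ignore_index=True)


def call_consensus(
    results: pd.DataFrame,
    alpha: float = 0.05,
    f: float = 0.5,
    min_datasets: int = 1,
    denominator: str = "measured",
) -> pd.DataFrame:
    """Combine per-dataset DE rows into one consensus status per gene.

    Parameters
    ----------
    results
        Long table with columns ``dataset_id, gene, log_fc, adj_p``;
        one row per gene per dataset.
    alpha
        Per-dataset adjusted-p significance cutoff (strict ``<``).
    f
        Minimum supporting fraction of datasets.
    min_datasets
        Genes measured in fewer datasets than this cannot reach consensus.
    denominator
        ``"measured"`` divides by the number of datasets in which the
        gene appears (platforms differ in coverage); ``"all"`` divides
        by the total number of datasets in ``results``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if not 0 < f <= 1:
        raise ValueError(f"fraction f must lie in (0,1], got {f}")
    if denominator not in ("measured", "all"):
        raise ValueError(f"denominator must be 'measured' or 'all': {denominator}")
    missing = [c for c in DE_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"DE results lack columns: {missing}")
    if results.duplicated(["dataset_id", "gene"]).any():
        raise ValueError("duplicate (dataset, gene) rows in DE results")
    if ((results["adj_p"] < 0) | (results["adj_p"] > 1)).any():
        raise ValueError("adjusted p-values outside [0,1]")

    out_cols = ["gene", "status", "direction", "n_sig_up", "n_sig_down", "n_measured"]
    if results.empty:
        return pd.DataFrame(columns=out_cols)

    sig = results["adj_p"] < alpha
    zero_lfc = sig & (results["log_fc"] == 0)
    if zero_lfc.any():
        # significant but directionless: cannot support either direction
        logger.warning(
            "%d significant rows with log_fc == 0 treated as non-supporting",
            int(zero_lfc.sum()),
        )
    per_gene = (
        results.assign(
            sig_up=(sig & (results["log_fc"] > 0)).astype(int),
            sig_down=(sig & (results["log_fc"] < 0)).astype(int),
        )
        .groupby("gene", as_index=False)
        .agg(
            n_sig_up=("sig_up", "sum"),
            n_sig_down=("sig_down", "sum"),
            n_measured=("dataset_id", "size"),
        )
    )
    denom = (
        per_gene["n_measured"]
        if denominator == "measured"
        else results["dataset_id"].nunique()
    )
    support = per_gene[["n_sig_up", "n_sig_down"]].max(axis=1)
    both = (per_gene["n_sig_up"] > 0) & (per_gene["n_sig_down"] > 0)
    consensus = (
        ~both
        & (support / denom >= f)
        & (support > 0)
        & (per_gene["n_measured"] >= min_datasets)
    )
    per_gene["status"] = STATUS_UNSUPPORTED
    per_gene.loc[both, "status"] = STATUS_CONFLICTING
    per_gene.loc[consensus, "status"] = STATUS_CONSENSUS
    per_gene["direction"] = pd.NA
    per_gene.loc[consensus, "direction"] = (
        per_gene.loc[consensus, "n_sig_up"].gt(0).map({True: "up", False: "down"})
    )
    return per_gene[out_cols].sort_values("gene", ignore_index=True)


def write_consensus(consensus: pd.DataFrame, path) -> None:
    consensus.to_csv(path, sep="\t", index=False)
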