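"""Overlap-based gene-set enrichment (hypergeometric / EASE) with fold change.

Given a query gene list (the anti-correlated network targets), a GMT
collection and a background universe of size ``N``, each set of size
``K`` overlapping the query (size ``n``) in ``k`` genes is scored with

* the one-sided upper-tail hypergeometric probability ``P(X >= k)``;
* optionally DAVID's conservative EASE variant, which removes one
  overlapping gene before the tail computation (``P(X >= k-1)``);
* fold enrichment ``(k/n) / (K/N)`` and the percent column ``100*k/n``.

Despite the field's habit of calling this "GSEA", these are overlap
statistics on a fixed gene list, not running-sum enrichment scores.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = [
    "set_name", "k", "n", "K", "N", "percent", "fold", "p", "adj_p", "significant",
]


def _check_config(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= min(n, K) and n <= N and K <= N and N >= 1):
        raise ValueError(f"impossible hypergeometric configuration k={k} n={n} K={K} N={N}")


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) drawing n genes from N with K marked.

    Evaluated in log space and clamped into (0, 1] so extreme overlaps
    do not underflow to an exact zero.
    """
    _check_config(k, n, K, N)
    if k == 0:
        return 1.0
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, max(math.exp(logp), 5e-324)))


def ease_p(k: int, n: int, K: int, N: int) -> float:
    """DAVID's EASE score: the hypergeometric tail after removing one hit."""
    _check_config(k, n, K, N)
    return hypergeom_p(max(k - 1, 0), n, K, N)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection into ``{name: member set}``."""
    from gseapy.parser import read_gmt as _read_gmt  # deferred: heavy import

    return {name: set(members) for name, members in _read_gmt(str(path)).items()}


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def enrich(
    query,
    sets: dict[str, set[str]],
    background,
    method: str = "ease",
    correct: str = "none",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every gene set against the query list.

    Query genes outside the background are dropped (with a logged
    count); set members are intersected with the background before
    sizing.  Rows are sorted by ascending p then set name.  When
    ``correct="BH"`` the significance flag applies to the adjusted p.
    """
    if method not in ("hypergeom", "ease"):
        raise ValueError(f"unknown method {method!r}")
    if correct not in ("none", "BH"):
        raise ValueError(f"unknown correction {correct!r}")
    background = set(background)
    if not background:
        raise ValueError("background gene universe is empty")
    query = set(query)
    outside = query - background
    if outside:
        logger.warning("%d query genes outside the background dropped", len(outside))
        query &= background

    pfun = hypergeom_p if method == "hypergeom" else ease_p
    n, N = len(query), len(background)
    rows = []
    for name, members in sets.items():
        in_bg = members & background
        K = len(in_bg)
        k = len(query & in_bg)
        percent = 100.0 * k / n if n else 0.0
        fold = (k / n) / (K / N) if k > 0 else 0.0
        p = pfun(k, n, K, N) if K > 0 else 1.0
        rows.append((name, k, n, K, N, percent, fold, p))
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "n", "K", "N", "percent", "fold", "p"]
    )
    out["adj_p"] = bh_adjust(out["p"]) if correct == "BH" else pd.NA
    flag_col = out["adj_p"] if correct == "BH" else out["p"]
    out["significant"] = flag_col < alpha
    return out.sort_values(["p", "set_name"], ignore_index=True)


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
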