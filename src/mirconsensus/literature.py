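"""Vote-counting consensus over literature miRNA deregulation calls.

Multiple profiling studies report miRNAs as up- or down-regulated in a
tumor type versus normal tissue.  This module normalizes reported miRNA
names against a miRBase-style alias table, tallies the per-study calls
for each (miRNA, tumor type), and applies the selection rule: a miRNA is
part of the consensus panel when at least ``m`` distinct studies report
it with a unanimous direction.  Any opposite-direction report among
``>= m`` reports marks the miRNA *inconsistent*; fewer than ``m``
reports marks it *insufficient*.

The package ships a digitized multi-study call table for papillary
(PTC) and anaplastic (ATC) thyroid carcinoma as a worked fixture, see
:func:`load_packaged_calls`.
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

TUMOR_TYPES = ("PTC", "ATC")
DIRECTIONS = ("up", "down")
CALL_COLUMNS = ["study_id", "tumor_type", "mirna", "direction"]
TALLY_COLUMNS = ["mirna", "tumor_type", "n_up", "n_down", "n_reports"]

STATUS_SELECTED = "selected"
STATUS_INCONSISTENT = "inconsistent"
STATUS_INSUFFICIENT = "insufficient"


class MirnaNameError(ValueError):
    """Raised for miRNA names missing from the alias table in strict mode."""


class DirectionConflictError(ValueError):
    """Raised when one study reports both directions for one miRNA."""


def _validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CALL_COLUMNS if c not in calls.columns]
    if missing:
        raise ValueError(f"call table lacks columns: {missing}")
    calls = calls[CALL_COLUMNS].copy()
    bad_tt = set(calls["tumor_type"]) - set(TUMOR_TYPES)
    if bad_tt:
        raise ValueError(f"unknown tumor types: {sorted(bad_tt)}")
    bad_dir = set(calls["direction"]) - set(DIRECTIONS)
    if bad_dir:
        raise ValueError(f"unknown directions: {sorted(bad_dir)}")
    dup = calls.duplicated(["study_id", "tumor_type", "mirna"])
    if dup.any():
        rows = calls.loc[dup, ["study_id", "tumor_type", "mirna"]]
        raise ValueError(
            "duplicate (study, tumor_type, miRNA) calls:\n"
            + rows.to_string(index=False)
        )
    return calls


def load_calls(path) -> pd.DataFrame:
    """Read a tab-separated call table ``study_id tumor_type mirna direction``."""
    return _validate_calls(pd.read_csv(path, sep="\t", dtype=str))


def load_aliases(path) -> dict[str, str]:
    """Read a two-column alias table mapping reported names to canonical ones.

    Canonical names always map to themselves; any canonical target absent
    from the ``reported`` column is added as an identity entry so the
    mapping is idempotent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("alias table must have exactly two columns")
    df.columns = ["reported", "canonical"]
    if df["reported"].duplicated().any():
        dups = df.loc[df["reported"].duplicated(), "reported"].tolist()
        raise ValueError(f"alias table maps a name twice: {dups}")
    mapping = dict(zip(df["reported"], df["canonical"]))
    for canon in list(mapping.values()):
        existing = mapping.setdefault(canon, canon)
        if existing != canon:
            raise ValueError(
                f"canonical name {canon!r} is itself aliased to {existing!r}"
            )
    return mapping


def _packaged(name: str):
    return resources.files("mirconsensus").joinpath("data", name)


def load_packaged_calls() -> pd.DataFrame:
    """The digitized multi-study PTC/ATC deregulation call table."""
    with resources.as_file(_packaged("table1_calls.tsv")) as p:
        return load_calls(p)


def load_packaged_aliases() -> dict[str, str]:
    """Alias table covering the names in the packaged call table."""
    with resources.as_file(_packaged("mirna_aliases.tsv")) as p:
        return load_aliases(p)


def normalize_names(
    calls: pd.DataFrame, aliases: dict[str, str], strict: bool = True
) -> pd.DataFrame:
    """Rewrite miRNA names to canonical form and collapse duplicates.

    Calls that become identical after renaming are merged when their
    directions agree; a within-study direction conflict is an error.
    Unknown names raise :class:`MirnaNameError` in strict mode and pass
    through with a warning otherwise.
    """
    calls = _validate_calls(calls)
    unknown = sorted(set(calls["mirna"]) - aliases.keys())
    if unknown:
        if strict:
            raise MirnaNameError(f"names not in the alias table: {unknown}")
        warnings.warn(
            f"passing through {len(unknown)} unrecognized miRNA names: {unknown}",
            stacklevel=2,
        )
    calls = calls.assign(mirna=calls["mirna"].map(lambda n: aliases.get(n, n)))
    ndir = calls.groupby(["study_id", "tumor_type", "mirna"])["direction"].nunique()
    conflicts = ndir[ndir > 1]
    if not conflicts.empty:
        raise DirectionConflictError(
            "opposite directions within one study after renaming:\n"
            + conflicts.reset_index()[["study_id", "tumor_type", "mirna"]].to_string(
                index=False
            )
        )
    return calls.drop_duplicates(CALL_COLUMNS, ignore_index=True)


def tally(calls: pd.DataFrame) -> pd.DataFrame:
    """Count up/down reports per (miRNA, tumor type) over distinct studies."""
    calls = _validate_calls(calls)
    if calls.empty:
        return pd.DataFrame(columns=TALLY_COLUMNS)
    grouped = (
        calls.assign(
            is_up=(calls["direction"] == "up").astype(int),
            is_down=(calls["direction"] == "down").astype(int),
        )
        .groupby(["mirna", "tumor_type"], as_index=False)
        .agg(n_up=("is_up", "sum"), n_down=("is_down", "sum"))
    )
    grouped["n_reports"] = grouped["n_up"] + grouped["n_down"]
    return grouped[TALLY_COLUMNS]


def select_consensus(tallies: pd.DataFrame, m: int = 3) -> pd.DataFrame:
    """Assign a status to every tallied miRNA under the m-study rule.

    ``selected``: >= m reports, unanimous direction (the consensus panel);
    ``inconsistent``: >= m reports but both directions reported;
    ``insufficient``: fewer than m reports.  The result carries a
    ``direction`` only for selected rows and is sorted by tumor type,
    then descending report count, then name — a stable, documented order.
    """
    if m < 1:
        raise ValueError(f"minimum study count m must be >= 1, got {m}")
    tallies = tallies.copy()
    if tallies.empty:
        for col in ("status", "direction"):
            tallies[col] = pd.Series(dtype=str)
        return tallies
    enough = tallies["n_reports"] >= m
    unanimous = (tallies["n_up"] == 0) | (tallies["n_down"] == 0)
    tallies["status"] = STATUS_INSUFFICIENT
    tallies.loc[enough & unanimous, "status"] = STATUS_SELECTED
    tallies.loc[enough & ~unanimous, "status"] = STATUS_INCONSISTENT
    tallies["direction"] = pd.NA
    sel = tallies["status"] == STATUS_SELECTED
    tallies.loc[sel, "direction"] = (
        tallies.loc[sel, "n_up"].gt(0).map({True: "up", False: "down"})
    )
    return tallies.sort_values(
        ["tumor_type", "n_reports", "mirna"],
        ascending=[True, False, True],
        kind="mergesort",
        ignore_index=True,
    )


def shared_mirnas(tallies: pd.DataFrame) -> list[str]:
    """miRNAs reported at least once in each of the two tumor types."""
    if tallies.empty:
        return []
    by_type = {
        tt: set(tallies.loc[tallies["tumor_type"] == tt, "mirna"])
        for tt in TUMOR_TYPES
    }
    return sorted(by_type["PTC"] & by_type["ATC"])


def write_tallies(tallies: pd.DataFrame, path) -> None:
    cols = ["mirna", "tumor_type", "n_up", "n_down", "status", "direction"]
    tallies[cols].to_csv(path, sep="\t", index=False)
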