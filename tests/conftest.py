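import numpy as np
import pandas as pd
import pytest

from mirconsensus import literature


@pytest.fixture(scope="session")
def table1_calls() -> pd.DataFrame:
    """The packaged digitized multi-study PTC/ATC call table, normalized."""
    calls = literature.load_packaged_calls()
    return literature.normalize_names(calls, literature.load_packaged_aliases())


@pytest.fixture(scope="session")
def table1_tallies(table1_calls) -> pd.DataFrame:
    return literature.select_consensus(literature.tally(table1_calls), m=3)


def random_call_matrix(rng: np.random.Generator, n_studies=8, n_mirnas=30,
                       rate=0.25) -> pd.DataFrame:
    """Dense-ish random call matrix for oracle-equivalence tests."""
    rows = []
    for j in range(n_studies):
        for i in range(n_mirnas):
            for tt in ("PTC", "ATC"):
                if rng.random() < rate:
                    rows.append(
                        (f"s{j}", tt, f"m{i}", rng.choice(["up", "down"]))
                    )
    return pd.DataFrame(rows, columns=literature.CALL_COLUMNS)
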