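"""Clinical association of target-gene alteration in a tumor cohort.

Three pieces, mirroring how cBioPortal-style cohort exports are usually
analyzed:

* **Z-score alteration calls** — a sample counts as *altered* when the
  expression of at least one gene from a list deviates from the cohort
  mean by ``z*`` standard deviations or more (default |z| >= 2.0).
* **Two-group comparison with a normality gate** — each group is checked
  with a Kolmogorov–Smirnov normality test; Student's t-test fires when
  both groups look Gaussian, the Mann–Whitney U test otherwise.  For
  small samples (combined n <= 12) the Mann–Whitney p is computed by
  exact enumeration of the rank-sum distribution (midranks under ties).
* **Survival contrast** — Kaplan–Meier product-limit curves and the
  two-group log-rank test, via ``lifelines``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ["risk_group", "ete", "lnm", "os_time", "os_event"]


@dataclass
class ClinicalCohort:
    """Expression matrix (samples x genes) plus per-sample clinical attributes.

    ``clinical`` carries ``risk_group`` (low/high), the boolean
    aggressiveness markers ``ete`` (extra-thyroidal extension) and
    ``lnm`` (lymph-node metastasis), and right-censored overall survival
    (``os_time`` in the cohort's declared unit, ``os_event`` 1=death
    observed, 0=censored).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.clinical.index):
            raise ValueError("expression and clinical sample ids do not match")
        missing = [c for c in CLINICAL_COLUMNS if c not in self.clinical.columns]
        if missing:
            raise ValueError(f"clinical table lacks columns: {missing}")
        if (self.clinical["os_time"] < 0).any():
            raise ValueError("negative survival times")
        if not self.clinical["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0 (censored) or 1 (death)")

    @property
    def samples(self) -> pd.Index:
        return self.expression.index


def load_cohort(expr_path, clin_path, time_unit: str = "months") -> ClinicalCohort:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    clin = pd.read_csv(clin_path, sep="\t", index_col=0)
    return ClinicalCohort(expr, clin.loc[expr.index], time_unit)


def zscore_classify(
    cohort: ClinicalCohort, gene_list, z_star: float = 2.0, reference_samples=None
) -> pd.DataFrame:
    """Flag samples whose expression is extreme in any listed gene.

    Z-scores are computed against a reference population: by default the
    full cohort (mean and sample standard deviation over all samples);
    pass ``reference_samples`` to standardize against a subset instead,
    emulating the diploid-reference convention of cBioPortal-style
    z-scores.  The threshold is inclusive: |z| >= z*.  Genes missing
    from the matrix or with zero variance in the reference are skipped
    with a log message.  Returns one row per sample: ``altered`` plus
    the list of triggering genes.
    """
    if z_star <= 0:
        raise ValueError(f"z_star must be positive, got {z_star}")
    ref = (
        cohort.expression
        if reference_samples is None
        else cohort.expression.loc[list(reference_samples)]
    )
    genes = list(dict.fromkeys(gene_list))
    missing = [g for g in genes if g not in cohort.expression.columns]
    if missing:
        logger.warning("genes absent from the cohort skipped: %s", missing)
    usable = []
    for g in genes:
        if g in missing:
            continue
        if ref[g].std(ddof=1) == 0 or ref[g].isna().all():
            logger.warning("zero-variance gene skipped: %s", g)
            continue
        usable.append(g)
    triggering: dict[str, list[str]] = {s: [] for s in cohort.samples}
    if usable:
        sub = cohort.expression[usable]
        z = (sub - ref[usable].mean()) / ref[usable].std(ddof=1)
        hits = z.abs() >= z_star
        for g in usable:
            for s in cohort.samples[hits[g].to_numpy(dtype=bool)]:
                triggering[s].append(g)
    out = pd.DataFrame(
        {
            "sample_id": list(cohort.samples),
            "triggering_genes": [triggering[s] for s in cohort.samples],
        }
    )
    out["altered"] = out["triggering_genes"].map(bool)
    return out[["sample_id", "altered", "triggering_genes"]]


def altered_fraction(calls: pd.DataFrame) -> float:
    return float(calls["altered"].mean()) if len(calls) else 0.0


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparisonResult:
    test_used: str  # "t_test" or "mann_whitney"
    statistic: float
    p: float
    stars: str


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (statistic for the first sample).

    Exact when the combined sample size is at most 12: the U statistic
    is enumerated over all assignments of the pooled midranks, so ties
    are handled without approximation.  Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    if na + nb <= 12:
        ranks = stats.rankdata(np.concatenate([a, b]))
        u_obs = ranks[:na].sum() - na * (na + 1) / 2
        mu = na * nb / 2
        count = total = 0
        for idx in combinations(range(na + nb), na):
            u = ranks[list(idx)].sum() - na * (na + 1) / 2
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        return float(u_obs), count / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values_a,
    values_b,
    alpha_normal: float = 0.05,
    lilliefors: bool = False,
    force: str | None = None,
) -> GroupComparisonResult:
    """Normality-gated two-group comparison.

    Each group is tested against a normal distribution with its own
    sample mean and standard deviation (Kolmogorov–Smirnov by default;
    the Lilliefors-corrected variant behind ``lilliefors=True``).  When
    both groups pass at ``alpha_normal`` the two-sided Student's t-test
    is used, otherwise the two-sided Mann–Whitney test.  ``force`` pins
    the branch ("t_test" or "mann_whitney") regardless of the gate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    if force is None:
        gaussian = all(_normal_p(x, lilliefors) >= alpha_normal for x in (a, b))
        test = "t_test" if gaussian else "mann_whitney"
    elif force in ("t_test", "mann_whitney"):
        test = force
    else:
        raise ValueError(f"force must be 't_test' or 'mann_whitney': {force}")
    if test == "t_test":
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        statistic, p = mann_whitney(a, b)
    if math.isnan(p):  # identical constant groups degenerate the t-test
        p = 1.0
    return GroupComparisonResult(test, statistic, p, _stars(p))


def _normal_p(x: np.ndarray, lilliefors: bool) -> float:
    if np.std(x, ddof=1) == 0:
        return 0.0  # a point mass is as non-Gaussian as it gets
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as _lf

        return float(_lf(x, dist="norm")[1])
    return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)


def km_estimate(times, events=None) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve as a (time, survival, at_risk) table.

    ``events=None`` treats every time as an observed event.  The curve
    starts at S(0)=1 and steps only at observed event times; an
    all-censored input therefore stays flat at 1.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival times")
    events = np.ones_like(times) if events is None else np.asarray(events, dtype=float)
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    out = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": table["at_risk"].reindex(kmf.survival_function_.index)
            .to_numpy(dtype=float),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class SurvivalComparison:
    km_a: pd.DataFrame
    km_b: pd.DataFrame
    logrank_chi2: float
    p: float


def logrank(times_a, events_a, times_b, events_b) -> SurvivalComparison:
    """Two-group log-rank test with the per-group Kaplan–Meier curves."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=float)
    eb = np.asarray(events_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    km_a = km_estimate(ta, ea)
    km_b = km_estimate(tb, eb)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("no events in either group; log-rank is undefined, p=1",
                      stacklevel=2)
        return SurvivalComparison(km_a, km_b, 0.0, 1.0)
    from lifelines.statistics import logrank_test

    res = logrank_test(ta, tb, ea, eb)
    return SurvivalComparison(km_a, km_b, float(res.test_statistic),
                              float(res.p_value))
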