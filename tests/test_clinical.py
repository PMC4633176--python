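"""Z-score alteration calls, gated group comparison, KM and log-rank."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirconsensus.clinical import (
    ClinicalCohort,
    compare_groups,
    km_estimate,
    logrank,
    mann_whitney,
    zscore_classify,
)


def _cohort(expr: np.ndarray, genes=None) -> ClinicalCohort:
    n = expr.shape[0]
    samples = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    genes = genes or [f"g{j}" for j in range(expr.shape[1])]
    clinical = pd.DataFrame(
        {
            "risk_group": ["low"] * n,
            "ete": [False] * n,
            "lnm": [False] * n,
            "os_time": np.ones(n),
            "os_event": np.ones(n, dtype=int),
        },
        index=samples,
    )
    return ClinicalCohort(pd.DataFrame(expr, index=samples, columns=genes), clinical)


class TestZscoreClassify:
    def test_constant_genes_are_skipped_nobody_altered(self):
        cohort = _cohort(np.ones((10, 3)))
        calls = zscore_classify(cohort, ["g0", "g1", "g2"])
        assert not calls["altered"].any()

    def test_large_shift_flags_the_sample(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(0, 1, size=(50, 4))
        expr[7, 2] += 5 * expr[:, 2].std(ddof=1)
        calls = zscore_classify(_cohort(expr), ["g2"]).set_index("sample_id")
        assert calls.loc["s7", "altered"]
        assert calls.loc["s7", "triggering_genes"] == ["g2"]

    def test_threshold_is_inclusive_at_exactly_two_sd(self):
        # [1, -1, 0 x 7]: mean 0, sample sd exactly 0.5, so z = +/-2.0 exactly
        expr = np.zeros((9, 1))
        expr[0, 0], expr[1, 0] = 1.0, -1.0
        calls = zscore_classify(_cohort(expr), ["g0"]).set_index("sample_id")
        assert calls.loc["s0", "altered"] and calls.loc["s1", "altered"]
        assert not calls.loc["s2", "altered"]

    def test_fraction_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(10)
        expr = rng.normal(0, 1, size=(60, 5))
        a = zscore_classify(_cohort(expr), [f"g{j}" for j in range(5)])
        b = zscore_classify(_cohort(expr * 7.5 - 3.0), [f"g{j}" for j in range(5)])
        assert a["altered"].tolist() == b["altered"].tolist()

    def test_missing_genes_skipped_and_empty_list_unaltered(self):
        cohort = _cohort(np.random.default_rng(11).normal(size=(10, 2)))
        calls = zscore_classify(cohort, ["nope"])
        assert not calls["altered"].any()
        assert not zscore_classify(cohort, [])["altered"].any()


class TestCompareGroups:
    def test_forced_mann_whitney_on_separated_triples(self):
        res = compare_groups([1, 2, 3], [4, 5, 6], force="mann_whitney")
        assert res.test_used == "mann_whitney"
        assert res.statistic == 0.0
        assert res.p == pytest.approx(0.1)
        assert res.stars == "ns"

    def test_identical_groups_are_not_different(self):
        res = compare_groups([1, 2, 3], [1, 2, 3])
        assert res.p == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_gaussian_samples_take_the_t_branch(self):
        rng = np.random.default_rng(7)
        res = compare_groups(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
        assert res.test_used == "t_test"

    def test_symmetric_in_its_arguments(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 20)
        assert compare_groups(a, b).p == pytest.approx(compare_groups(b, a).p)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_groups([1, 2], [3, 4, 5])

    def test_star_codes_track_p_thresholds(self):
        rng = np.random.default_rng(13)
        res = compare_groups(rng.normal(0, 1, 200), rng.normal(3, 1, 200))
        assert res.stars == "***"


def _oracle_mw_p(a, b):
    """Two-sided exact p by enumerating all labelings of the pooled values."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(xs, ys):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in xs for y in ys
        )

    mu = na * len(b) / 2
    u_obs = u_stat(a, b)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def test_exact_mann_whitney_matches_labeling_enumeration():
    rng = np.random.default_rng(14)
    for _ in range(25):
        na = int(rng.integers(3, 7))
        nb = int(rng.integers(3, 13 - na))
        a = rng.integers(0, 6, size=na).astype(float)  # integer grid forces ties
        b = rng.integers(0, 6, size=nb).astype(float)
        _, p = mann_whitney(a, b)
        assert p == pytest.approx(_oracle_mw_p(a, b), abs=1e-12)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 3]).set_index("time")["survival"]
        assert km.loc[2.0] == pytest.approx((1 - 1 / 3) * (1 - 1 / 2))

    def test_all_censored_is_flat_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_subject_drops_to_zero(self):
        km = km_estimate([5.0]).set_index("time")["survival"]
        assert km.loc[5.0] == 0.0

    def test_curve_is_a_valid_survivor_function(self):
        rng = np.random.default_rng(15)
        km = km_estimate(rng.exponential(10, 40), rng.integers(0, 2, 40))
        s = km["survival"].to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()
        assert ((s >= 0) & (s <= 1)).all()

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0])


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        t = [1, 2, 3, 4, 5]
        res = logrank(t, [1] * 5, t, [1] * 5)
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_observed_expected_table(self):
        # group a events at 1,2; group b at 3,4; no censoring:
        # O_a=2, E_a=1/2+1/3, V=1/4+2/9 -> chi2=(7/6)^2/(17/36)
        res = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.logrank_chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36))

    def test_no_events_anywhere_warns_with_p_one(self):
        with pytest.warns(UserWarning, match="no events"):
            res = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert res.p == 1.0
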