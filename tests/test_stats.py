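"""Responder labeling and the group-comparison statistical battery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eegsync import (
    SeizureDiary,
    chi_square_or_fisher,
    compare_clinical_by_group,
    compare_sync_by_group,
    fdr_bh,
    ks_normality,
    label_responder,
    mann_whitney_u,
    sync_feature_names,
)

from conftest import feature_cohort


# ---------------------------------------------------------------- labeling

class TestLabelResponder:
    @pytest.mark.parametrize("baseline,followup,category,responder", [
        (100, 0, "R100", True),
        (100, 20, "R80", True),       # 80 % boundary inclusive
        (100, 50, "R50", True),       # 50 % boundary inclusive
        (100, 60, "NR50", False),
        (100, 150, "NR50", False),    # worsening allowed
        (100, 10, "R80", True),
        (4, 1.9, "R50", True),
    ])
    def test_categories(self, baseline, followup, category, responder):
        lab = label_responder(SeizureDiary(baseline, followup))
        assert lab.category == category
        assert lab.responder is responder

    def test_reduction_fraction_value(self):
        lab = label_responder(SeizureDiary(100, 60))
        assert lab.reduction_fraction == pytest.approx(0.4)


# --------------------------------------------------------------- normality

class TestKsNormality:
    def test_normal_draws_rarely_rejected(self):
        rng = np.random.default_rng(0)
        hits = sum(ks_normality(rng.standard_normal(1000)) > 0.05 for _ in range(100))
        assert hits >= 90

    def test_exponential_draws_rejected(self):
        rng = np.random.default_rng(1)
        hits = sum(ks_normality(rng.exponential(size=1000)) < 0.05 for _ in range(100))
        assert hits >= 95

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])
        with pytest.raises(ValueError):
            ks_normality([3.0, 3.0, 3.0])


# ------------------------------------------------------------ Mann-Whitney

def mwu_exact_enumeration(x, y):
    """Oracle: exact two-sided p by enumerating all group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)

    def ustat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = ustat(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        us.append(ustat(pooled[mask], pooled[~mask]))
    us = np.array(us)
    p_le = (us <= u_obs + 1e-9).mean()
    p_ge = (us >= u_obs - 1e-9).mean()
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_fully_separated_samples(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1)   # 2/20 rank assignments

    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = mann_whitney_u(x, x)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for nx, ny in [(3, 3), (4, 4), (5, 3), (6, 6), (5, 5)]:
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            U, p = mann_whitney_u(x, y)
            U_o, p_o = mwu_exact_enumeration(x, y)
            assert U == pytest.approx(U_o)
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_and_asymptotic_agree(self):
        from scipy.stats import mannwhitneyu as sp_mwu

        rng = np.random.default_rng(6)
        for _ in range(100):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p_exact = mann_whitney_u(x, y)  # pooled n = 12 -> exact path
            p_asym = sp_mwu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# -------------------------------------------------------- chi2 / Fisher

def fisher_oracle_2x2(table):
    """Two-sided Fisher p as a hypergeometric tail sum over all tables
    with the observed margins, summing probabilities <= P(observed)."""
    from math import comb
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = r2 - c_
        if min(b_, c_, d_) < 0:
            return 0.0
        return comb(r1, a_) * comb(r2, c_) / comb(ntot, c1)

    p_obs = prob(a)
    return sum(p for a_ in range(0, min(r1, c1) + 1)
               if (p := prob(a_)) <= p_obs * (1 + 1e-9))


class TestChiSquareOrFisher:
    def test_homogeneous_table_p_one(self):
        name, p = chi_square_or_fisher([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0)
        assert name == "chi_square"

    def test_sparse_2x2_uses_fisher_matching_oracle(self):
        table = [[8, 2], [1, 9]]
        name, p = chi_square_or_fisher(table)
        assert name == "fisher"
        assert p == pytest.approx(fisher_oracle_2x2(table), abs=1e-12)

    def test_gender_table_fisher_oracle(self):
        """The published gender comparison (25/12 vs 19/14, p = 0.46)
        is reproduced by Fisher's exact on that table."""
        table = [[25, 12], [19, 14]]
        assert fisher_oracle_2x2(table) == pytest.approx(0.4611, abs=5e-4)
        # expected counts all exceed 5, so the decision rule runs chi-square
        name, _ = chi_square_or_fisher(table)
        assert name == "chi_square"

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            chi_square_or_fisher([[0, 0], [0, 0]])

    def test_sparse_wide_table_warns(self):
        with pytest.warns(UserWarning):
            chi_square_or_fisher([[1, 30, 2], [2, 28, 1]])


# ----------------------------------------------------------------- BH-FDR

def bh_stepup_oracle(p):
    """Direct evaluation of the Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return adj


class TestFdrBh:
    def test_textbook_vector(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(adj, 0.05)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.037])[0] == pytest.approx(0.037)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            m = int(rng.integers(1, 9))
            p = rng.uniform(size=m)
            assert np.allclose(fdr_bh(p), bh_stepup_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=50)
        assert (fdr_bh(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])


# --------------------------------------------------- group comparisons

def _sync_table(n, seed, effect_band=None, effect=0.0):
    rng = np.random.default_rng(seed)
    labels = np.array([True] * (n // 2) + [False] * (n - n // 2))
    cols = {}
    for name in sync_feature_names():
        v = np.clip(rng.normal(0.3, 0.05, n), 0, 1)
        if effect_band and name == effect_band:
            v = v + effect * labels
        cols[name] = v
    return pd.DataFrame(cols), labels


class TestCompareSyncByGroup:
    def test_planted_band_flagged_others_not(self):
        table, labels = _sync_table(70, seed=1, effect_band="pli_high_beta", effect=0.08)
        res = {r.band: r for r in compare_sync_by_group(table, labels, "pli")}
        assert res["high_beta"].significant
        for band in ("delta", "theta", "alpha", "low_beta"):
            assert not res[band].significant

    def test_subject_permutation_invariance(self):
        table, labels = _sync_table(40, seed=2)
        perm = np.random.default_rng(0).permutation(40)
        r1 = compare_sync_by_group(table, labels, "wpli")
        r2 = compare_sync_by_group(table.iloc[perm].reset_index(drop=True), labels[perm], "wpli")
        for a, b in zip(r1, r2):
            assert a.p_raw == pytest.approx(b.p_raw, abs=1e-12)
            assert a.p_adjusted == pytest.approx(b.p_adjusted, abs=1e-12)

    def test_adjusted_p_dominates_raw(self):
        table, labels = _sync_table(30, seed=3)
        for r in compare_sync_by_group(table, labels, "plv"):
            assert r.p_adjusted >= r.p_raw

    def test_tiny_groups_rejected(self):
        table, labels = _sync_table(10, seed=4)
        with pytest.raises(ValueError):
            compare_sync_by_group(table, np.array([True] + [False] * 9), "plv")


class TestCompareClinicalByGroup:
    @staticmethod
    def _table(n=60, seed=0, bmi_shift=0.0):
        clinical, _, labels = feature_cohort(n=n, seed=seed)
        rows = []
        lab = []
        for sid, rec in clinical.items():
            d = rec.to_dict()
            if labels[sid] and bmi_shift:
                d["bmi"] += bmi_shift
            rows.append(d)
            lab.append(labels[sid])
        return pd.DataFrame(rows), np.array(lab)

    def test_null_cohort_mostly_nonsignificant(self):
        table, labels = self._table(seed=7)
        res = compare_clinical_by_group(table, labels)
        assert len(res) >= 12
        assert sum(r.significant for r in res) <= 2

    def test_planted_shift_flagged(self):
        table, labels = self._table(seed=8, bmi_shift=4.0)
        res = {r.variable: r for r in compare_clinical_by_group(table, labels)}
        assert res["bmi"].significant

    def test_single_category_variable_skipped_with_warning(self):
        table, labels = self._table(seed=9)
        table["mri"] = "negative"
        with pytest.warns(UserWarning, match="mri"):
            res = compare_clinical_by_group(table, labels)
        assert "mri" not in {r.variable for r in res}
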