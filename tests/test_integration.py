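"""Unit and property tests for the meta-integration statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crossomics import (ConfigurationError, DegenerateDataError, OmicsMatrix,
                        bh_fdr, collapse_probes, combined_pvalue, combined_score,
                        integrate, permutation_sd, standardize, two_group_t)


class TestTwoGroupT:
    def test_identical_groups_give_zero(self):
        assert two_group_t([1, 2, 3, 1, 2, 3], [1, 1, 1, 0, 0, 0]) == pytest.approx(0.0)

    def test_hand_computed_pooled_t(self):
        # groups (1,2,3) vs (4,5,6): sp^2 = 1, se = sqrt(2/3)
        t = two_group_t([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        assert t == pytest.approx(-3 / math.sqrt(2 / 3), abs=1e-12)
        assert t == pytest.approx(-3.674, abs=5e-4)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        labels = np.array([1] * 5 + [0] * 7, dtype=bool)
        ours = two_group_t(x, labels)
        ref = stats.ttest_ind(x[labels], x[~labels], equal_var=True).statistic
        assert ours == pytest.approx(ref, rel=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            two_group_t([5, 5, 5, 5, 5, 5], [1, 1, 1, 0, 0, 0])

    def test_small_group_is_an_error(self):
        with pytest.raises(ConfigurationError):
            two_group_t([1, 2, 3], [1, 0, 0])


class TestPermutationSd:
    def test_exhaustive_equals_bruteforce_3plus3(self):
        """Independent C(6,3) enumeration oracle, computed from scratch."""
        x = np.array([1.2, 0.3, 2.1, 4.0, 5.5, 3.3])
        ts = []
        for idx in itertools.combinations(range(6), 3):
            a = x[list(idx)]
            b = np.delete(x, list(idx))
            sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
            ts.append((a.mean() - b.mean()) / math.sqrt(sp2 * (2 / 3)))
        assert len(ts) == 20
        oracle = float(np.std(ts, ddof=0))
        ours = permutation_sd(x, [1, 1, 1, 0, 0, 0], scheme="exhaustive")
        assert ours == pytest.approx(oracle, rel=1e-12)

    def test_invariant_to_group_label_swap(self):
        x = np.random.default_rng(3).normal(size=8)
        m = [1, 1, 1, 1, 0, 0, 0, 0]
        a = permutation_sd(x, m)
        b = permutation_sd(x, [1 - v for v in m])
        assert a == pytest.approx(b, rel=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(DegenerateDataError):
            permutation_sd([2.0] * 6, [1, 1, 1, 0, 0, 0])

    def test_sampled_scheme_is_seeded(self):
        x = np.random.default_rng(4).normal(size=20)
        m = [1] * 10 + [0] * 10
        a = permutation_sd(x, m, scheme="sampled", n_perm=500, seed=9)
        b = permutation_sd(x, m, scheme="sampled", n_perm=500, seed=9)
        assert a == b


class TestStandardizeAndScore:
    @pytest.mark.parametrize("s, sd, expect", [
        (2.0, 1.0, 2.0), (0.0, 5.0, 0.0), (-3.674, 1.155, -3.181),
    ])
    def test_standardize(self, s, sd, expect):
        assert standardize(s, sd) == pytest.approx(expect, abs=5e-4)

    def test_standardize_requires_positive_sd(self):
        with pytest.raises(ConfigurationError):
            standardize(1.0, 0.0)

    @pytest.mark.parametrize("z, expect", [
        ((0.0, 0.0), 0.0), ((1.0, -1.0), 2.0), ((2.74, 3.07), 5.81),
    ])
    def test_combined_score(self, z, expect):
        assert combined_score(z) == pytest.approx(expect, abs=1e-12)

    def test_combined_score_empty_is_an_error(self):
        with pytest.raises(ConfigurationError):
            combined_score([])


class TestCombinedPvalue:
    def test_zero_score_gives_one(self):
        for method in ("paper_eq2", "exact_convolution", "monte_carlo"):
            assert combined_pvalue(0.0, 2, method=method) == 1.0

    def test_closed_form_at_s2(self):
        # 1 - [2*Phi(sqrt(2)) - 1]^2 = 1 - 0.8427^2
        assert combined_pvalue(2.0, 2, method="paper_eq2") == pytest.approx(
            1 - math.erf(1.0) ** 2, abs=1e-12)
        assert combined_pvalue(2.0, 2, method="paper_eq2") == pytest.approx(0.2898, abs=1e-4)

    def test_closed_form_requires_two_layers(self):
        with pytest.raises(ConfigurationError):
            combined_pvalue(1.0, 3, method="paper_eq2")

    def test_negative_score_is_an_error(self):
        with pytest.raises(ConfigurationError):
            combined_pvalue(-0.1, 2)

    def test_convolution_d1_equals_half_normal_tail(self):
        for s in [0.1, 0.5, 1.0, 2.5, 4.0]:
            assert combined_pvalue(s, 1) == pytest.approx(
                2 * stats.norm.sf(s), abs=1e-9)

    @pytest.mark.parametrize("method", ["paper_eq2", "exact_convolution"])
    def test_strictly_decreasing_in_s(self, method):
        grid = np.linspace(0.1, 6.0, 40)
        p = [combined_pvalue(s, 2, method=method) for s in grid]
        assert all(a > b for a, b in zip(p, p[1:]))

    def test_monte_carlo_agrees_with_convolution(self):
        p_mc = combined_pvalue(2.0, 2, method="monte_carlo", mc_reps=400_000, seed=0)
        p_ex = combined_pvalue(2.0, 2)
        se = math.sqrt(p_ex * (1 - p_ex) / 400_000)
        assert abs(p_mc - p_ex) < 4 * se


def _brute_force_bh(p):
    """Literal step-up definition: q_i = min over ranks >= rank(i) of p*m/rank."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(min(p[order[j]] * m / (j + 1) for j in range(pos, m)), 1.0)
    return q


class TestBhFdr:
    def test_hand_oracle(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_identity(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_is_an_error(self):
        with pytest.raises(ConfigurationError):
            bh_fdr([0.5, 1.5])

    def test_q_never_below_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        assert (bh_fdr(p) >= p - 1e-15).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=30))
    def test_matches_bruteforce_definition(self, p):
        assert bh_fdr(p) == pytest.approx(_brute_force_bh(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 80))
            ref = multipletests(p, method="fdr_bh")[1]
            assert bh_fdr(p) == pytest.approx(ref, abs=1e-12)


class TestCollapseProbes:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["probe", "feature", "p", "score"])

    def test_keeps_most_significant_probe(self):
        out = collapse_probes(self._table([("p1", "g1", 0.3, 1.0), ("p2", "g1", 0.01, 0.5)]))
        assert out.loc["g1", "probe"] == "p2"

    def test_single_probe_identity(self):
        out = collapse_probes(self._table([("p1", "g1", 0.2, 1.0)]))
        assert out.loc["g1", "p"] == 0.2

    def test_tie_breaks_by_larger_abs_score(self):
        out = collapse_probes(self._table(
            [("p1", "g1", 0.05, 1.0), ("p2", "g1", 0.05, -2.0)]))
        assert out.loc["g1", "probe"] == "p2"

    def test_unmapped_probe_dropped(self):
        out = collapse_probes(self._table(
            [("p1", "g1", 0.2, 1.0), ("p2", None, 0.01, 3.0)]))
        assert list(out.index) == ["g1"]


class TestIntegrate:
    def test_single_layer_half_normal_tail(self, toy_matrix):
        tbl = integrate({"exp": toy_matrix}, seed=0)
        z = tbl["z_exp"]
        assert tbl["p_inte"].to_numpy() == pytest.approx(
            2 * stats.norm.sf(np.abs(z)), abs=1e-9)

    def test_s_meta_is_sum_of_abs_z(self, small_dataset):
        tbl = integrate({"exp": small_dataset.expression,
                         "methy": small_dataset.methylation}, seed=1)
        expect = tbl["z_exp"].abs() + tbl["z_methy"].abs()
        assert tbl["s_meta"].to_numpy() == pytest.approx(expect.to_numpy(), abs=1e-12)
        assert (tbl["s_meta"] >= 0).all()
        assert ((tbl["p_inte"] > 0) & (tbl["p_inte"] <= 1)).all()
        assert (tbl["q_inte"] >= tbl["p_inte"] - 1e-15).all()

    def test_planted_genes_rank_above_null(self, small_dataset):
        tbl = integrate({"exp": small_dataset.expression,
                         "methy": small_dataset.methylation}, seed=1)
        ranks = pd.Series(np.arange(len(tbl)), index=tbl.index)
        planted = set(small_dataset.truth["diff_genes"])
        med_planted = ranks[ranks.index.isin(planted)].median()
        med_null = ranks[~ranks.index.isin(planted)].median()
        assert med_planted < med_null

    def test_sorted_by_p(self, small_dataset):
        tbl = integrate({"exp": small_dataset.expression}, seed=0)
        assert (np.diff(tbl["p_inte"].to_numpy()) >= -1e-15).all()

    def test_permutation_method_null_uniform(self):
        """Pooled permutation p-values are uniform under the global null."""
        from crossomics import SyntheticConfig, generate_dataset
        ds = generate_dataset(SyntheticConfig(n_genes=2000, frac_diff_genes=0.0, seed=77))
        tbl = integrate({"exp": ds.expression, "methy": ds.methylation},
                        method="permutation", seed=2)
        ks = stats.kstest(tbl["p_inte"], "uniform")
        assert ks.pvalue > 0.01
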