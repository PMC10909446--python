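import itertools

import numpy as np
import pytest
from scipy import stats

from rewardlist.permutation_inference import (
    PowerSpec,
    compare_observed_to_null,
    interaction_signflip_test,
    permute_output_orders,
    power_paired_t,
    required_sample_size,
    rm_anova_oneway,
    wilcoxon_signed_rank,
)
from rewardlist.recall_dynamics import organization_score, prob_first_recall_high
from rewardlist.synthetic_data import BehaviorSimParams, generate_design, simulate_recall

from conftest import single_list_log
from test_recall_dynamics import oracle_transition_scores


def exhaustive_null(log, statistic):
    """Exact permutation-null mean by enumerating all k! output orders of the
    single list in ``log`` (independent pure-python oracle)."""
    from rewardlist.recall_dynamics import list_arrays

    ((_s, _b, _lt, serial, is_high, ridx),) = list(list_arrays(log))
    values = []
    for order in itertools.permutations(ridx):
        if statistic == "pfr_high":
            values.append(float(is_high[order[0]]))
        else:
            scores = oracle_transition_scores(list(order), serial, is_high, "reward")
            if scores:
                values.append(float(np.mean(scores)))
    return float(np.mean(values))


class TestPermuteOutputOrders:
    def test_two_high_one_low_first_recall_chance(self):
        """Recalled set {H, H, L}: exact P(first output high) = 2/3."""
        log = single_list_log(["high", "high", "low", "low"], [1, 2, 3])
        null = permute_output_orders(log, "pfr_high", n_perm=10_000, seed=1)
        se = np.sqrt((2 / 3) * (1 / 3) / 10_000)
        assert abs(null.per_subject_mean["s1"] - 2 / 3) < 3 * se

    @pytest.mark.parametrize("statistic", ["pfr_high", "reward_clustering"])
    def test_monte_carlo_matches_exhaustive_enumeration(self, statistic):
        rng = np.random.default_rng(2)
        for trial in range(4):
            rewards = list(rng.choice(["high", "low"], size=8))
            if len(set(rewards)) == 1:
                rewards[0] = "high" if rewards[0] == "low" else "low"
            k = int(rng.integers(3, 7))
            recall = list(rng.permutation(np.arange(1, 9))[:k])
            log = single_list_log(rewards, recall)
            exact = exhaustive_null(log, statistic)
            null = permute_output_orders(log, statistic, n_perm=10_000, seed=3 + trial)
            mc = null.per_subject_mean["s1"]
            se = max(0.5 / np.sqrt(10_000), 1e-3)
            assert abs(mc - exact) < 3 * se

    def test_all_same_reward_pfr_degenerate(self):
        log = single_list_log(
            ["high"] * 4 + ["low"] * 4, [1, 3, 2], list_type="mixed"
        )
        null = permute_output_orders(log, "pfr_high", n_perm=200, seed=4)
        assert null.per_subject_mean["s1"] == 1.0

    def test_undefined_statistic_propagates_missing(self):
        log = single_list_log(["high", "high", "low", "low"], [2])
        null = permute_output_orders(log, "reward_clustering", n_perm=50, seed=5)
        assert np.isnan(null.per_subject_mean["s1"])


class TestWilcoxon:
    def test_three_positive_diffs(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.V == 6 and res.method == "exact"
        assert res.p_two_sided == pytest.approx(0.25)

    def test_symmetric_pair_gives_p_one(self):
        res = wilcoxon_signed_rank([1.5, -1.5])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_matches_brute_force_enumeration(self, n):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(n)
        d = np.where(d == 0, 0.1, d)
        res = wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        vs = [
            sum(r for r, s in zip(ranks, signs) if s > 0)
            for signs in itertools.product([-1, 1], repeat=n)
        ]
        vs = np.array(vs)
        p_le = np.mean(vs <= res.V)
        p_ge = np.mean(vs >= res.V)
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        d = rng.standard_normal(12)
        ours = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue)

    def test_exact_and_normal_agree_near_boundary(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            d = rng.standard_normal(20)
            exact = wilcoxon_signed_rank(d, exact_max_n=25)
            approx = wilcoxon_signed_rank(d, exact_max_n=0)
            assert approx.method == "normal_approx"
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.02


class TestCompareObservedToNull:
    def test_degenerate_identical_values(self, small_log):
        obs = prob_first_recall_high(small_log)
        null = permute_output_orders(small_log, "pfr_high", n_perm=100, seed=9)
        null.per_subject_mean = obs.copy()
        with pytest.raises(ValueError):
            compare_observed_to_null(obs, null)

    def test_detects_first_recall_bias_at_study_scale(self):
        """A strong generative first-recall bias is detected (observed mean
        above the permuted chance level, p < .05)."""
        designs = generate_design(43, seed=10)
        params = BehaviorSimParams(n_subjects=43, beta_first=1.5, seed=11)
        log = simulate_recall(designs, params)
        obs = prob_first_recall_high(log)
        null = permute_output_orders(log, "pfr_high", n_perm=2000, seed=12)
        res = compare_observed_to_null(obs, null)
        assert obs.mean() > null.group_mean
        assert res.p_two_sided < 0.05

    def test_power_of_first_recall_bias_detection(self):
        """>= 80% rejection across replicates under a strong bias."""
        hits = 0
        R = 25
        for rep in range(R):
            designs = generate_design(43, seed=600 + rep)
            params = BehaviorSimParams(n_subjects=43, beta_first=1.5, seed=700 + rep)
            log = simulate_recall(designs, params)
            obs = prob_first_recall_high(log)
            null = permute_output_orders(log, "pfr_high", n_perm=500, seed=rep)
            res = compare_observed_to_null(obs, null)
            hits += res.p_two_sided < 0.05 and obs.mean() > null.group_mean
        assert hits >= 0.8 * R


class TestRmAnova:
    def test_identical_columns_zero_f(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = rm_anova_oneway(X)
        assert res.F == 0.0 and res.partial_eta_sq == 0.0

    def test_degrees_of_freedom_at_study_scale(self):
        X = np.random.default_rng(13).random((43, 3))
        res = rm_anova_oneway(X)
        assert (res.df1, res.df2) == (2, 84)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(14)
        X = rng.random((6, 3))
        res = rm_anova_oneway(X)
        long = pd.DataFrame(
            {
                "y": X.ravel(),
                "subj": np.repeat(np.arange(6), 3),
                "cond": np.tile(np.arange(3), 6),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj", detailed=True)
        assert res.F == pytest.approx(float(ref.loc[0, "F"]))
        assert res.p == pytest.approx(float(ref.loc[0, "p_unc"]))
        ss_cond = float(ref.loc[0, "SS"])
        ss_err = float(ref.loc[1, "SS"])
        assert res.partial_eta_sq == pytest.approx(ss_cond / (ss_cond + ss_err))

    def test_invariant_to_subject_shift(self):
        rng = np.random.default_rng(15)
        X = rng.random((8, 3))
        shifted = X + rng.random((8, 1)) * 10
        assert rm_anova_oneway(X).F == pytest.approx(rm_anova_oneway(shifted).F)

    def test_missing_cells_rejected(self):
        X = np.random.default_rng(16).random((5, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova_oneway(X)


class TestInteractionSignFlip:
    def test_all_zero_differences_p_one(self):
        import pandas as pd

        data = pd.DataFrame(
            {c: [0.4, 0.5, 0.6] for c in ("mixed_high", "mixed_low", "pure_high", "pure_low")}
        )
        res = interaction_signflip_test(data, n_perm=500, seed=17)
        assert res.p == pytest.approx(1.0)

    def test_detects_mixed_only_boost(self):
        from rewardlist.recall_dynamics import recall_proportion

        hits = 0
        R = 10
        for rep in range(R):
            designs = generate_design(43, seed=800 + rep)
            params = BehaviorSimParams(
                n_subjects=43, boost_mixed=0.2, boost_pure=0.0, seed=900 + rep
            )
            props = recall_proportion(simulate_recall(designs, params))
            res = interaction_signflip_test(props, n_perm=1000, seed=rep)
            hits += res.p < 0.05 and res.statistic > 0
        assert hits >= 9


class TestPowerAnalysis:
    def test_study_effect_size_reproduces_reported_n(self):
        assert required_sample_size(eta_p_sq=0.203, power=0.90, alpha=0.05) == 43

    def test_monotone_in_effect_size(self):
        ns = [
            required_sample_size(eta_p_sq=e, power=0.90, alpha=0.05)
            for e in (0.1, 0.2, 0.3, 0.5)
        ]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_conservative_guarantees_power(self):
        n = required_sample_size(
            eta_p_sq=0.203, power=0.90, alpha=0.05, conservative=True
        )
        dz = PowerSpec(eta_p_sq=0.203).effect_dz()
        assert power_paired_t(n, dz) >= 0.90
        assert power_paired_t(n - 1, dz) < 0.90

    def test_matches_grid_search_oracle(self):
        """dz = 0.5, 80% power: compare to a brute-force noncentral-t scan."""
        target = None
        for n in range(2, 200):
            df = n - 1
            tc = stats.t.ppf(0.975, df)
            pw = 1 - stats.nct.cdf(tc, df, 0.5 * np.sqrt(n)) + stats.nct.cdf(
                -tc, df, 0.5 * np.sqrt(n)
            )
            if pw >= 0.80:
                target = n
                break
        ours = required_sample_size(dz=0.5, power=0.80, alpha=0.05, conservative=True)
        assert ours == target
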