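import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from plastinet import diffstat
from plastinet.design import make_design
from plastinet.simulate import SimulationConfig, simulate_counts


class TestQuantileNormalize:
    def test_two_column_hand_example(self, design2):
        m = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 3.0, 5.0]})
        out = diffstat.quantile_normalize(m)
        expected = [1.5, 3.5, 5.5]
        assert out["a"].tolist() == expected
        assert out["b"].tolist() == expected

    def test_identical_columns_are_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 7.0], "b": [3.0, 1.0, 7.0]})
        pd.testing.assert_frame_equal(diffstat.quantile_normalize(m), m)

    def test_constant_column_gets_mean_of_rank_means(self):
        # reference distribution = mean of sorted columns; a constant column
        # is one big tie and must receive the mean of all reference values
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        out = diffstat.quantile_normalize(m)
        ref = [(1 + 5) / 2, (2 + 5) / 2, (3 + 5) / 2]
        assert out["a"].tolist() == ref
        assert np.allclose(out["b"], np.mean(ref))

    def test_columns_share_one_sorted_vector(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        out = diffstat.quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for col in out:
            assert np.allclose(np.sort(out[col].to_numpy()), ref)

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        once = diffstat.quantile_normalize(m)
        twice = diffstat.quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_missing_values_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            diffstat.quantile_normalize(m)


class TestPermutationAnova:
    def test_constant_feature_has_p_one(self, design2):
        r = diffstat.permutation_anova(np.ones(8), design2)
        assert r.p_perm == 1.0
        assert r.f_obs == 0.0

    def test_exhaustive_space_size(self, design2):
        r = diffstat.permutation_anova(np.arange(8.0), design2)
        assert r.exhaustive
        assert r.n_assignments == 2520  # 8! / (2!)^4

    def test_group_relabeling_tie_floor(self, design2, rng):
        # F is invariant to permuting group labels, so even an arbitrarily
        # strong single-condition shift ties with its 4! relabelings at least
        vals = rng.normal(size=8)
        vals[2:4] += 1e6
        r = diffstat.permutation_anova(vals, design2)
        assert r.p_perm >= 24 / 2520

    def test_monte_carlo_converges_to_exhaustive(self, design2, rng):
        vals = rng.normal(size=8)
        vals[4:6] += 2.0
        exact = diffstat.permutation_anova(vals, design2).p_perm
        mc = diffstat.permutation_anova(
            vals, design2, n_perm=40_000, seed=3, exhaustive_cap=0
        ).p_perm
        assert abs(mc - exact) < 0.01

    def test_length_mismatch_rejected(self):
        design = make_design(2)
        with pytest.raises(ValueError):
            diffstat.permutation_anova(np.arange(6.0), design)


class TestPooledSD:
    def test_zero_within_variance(self, design2):
        vals = np.repeat([5.0, 9.0, 2.0, 7.0], 2)
        assert diffstat.pooled_sd(vals, design2) == 0.0

    def test_hand_mse_example(self, design2):
        # every condition has replicates (0, 2): each group variance is 2,
        # pooled MSE = 2, pooled SD = sqrt(2)
        vals = np.array([0.0, 2.0] * 4)
        assert diffstat.pooled_sd(vals, design2) == pytest.approx(math.sqrt(2))

    def test_scaling_homogeneity(self, design2, rng):
        vals = rng.normal(size=8)
        sd = diffstat.pooled_sd(vals, design2)
        assert diffstat.pooled_sd(vals * -3.5, design2) == pytest.approx(3.5 * sd)


class TestFdrAdjust:
    def test_single_p_is_identity(self):
        assert diffstat.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_by_example(self):
        # m=3, c(3)=11/6; raw q_j = p_j * 3 * (11/6) / j = 0.055 for all three,
        # and step-up monotonicity keeps them equal
        q = diffstat.fdr_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.055, 0.055, 0.055])

    def test_empty_vector(self):
        assert diffstat.fdr_adjust([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            diffstat.fdr_adjust([0.0, 0.5])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40)
    )
    def test_monotone_and_upper_bounds_bh(self, pvals):
        p = np.array(pvals)
        q_by = diffstat.fdr_adjust(p)
        assert (q_by >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q_by[order]) >= -1e-12).all()
        q_bh = multipletests(p, method="fdr_bh")[1]
        assert (q_by >= q_bh - 1e-12).all()


class TestDifferentialAnalysis:
    def test_column_mismatch_rejected(self, design2, rng):
        m = pd.DataFrame(rng.poisson(50, size=(5, 8)), columns=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError):
            diffstat.differential_analysis(m, design2)

    def test_alpha_zero_calls_nothing(self, design2, rng):
        m = pd.DataFrame(
            rng.poisson(50, size=(10, 8)), columns=design2.sample_ids
        )
        diff = diffstat.differential_analysis(m, design2, alpha=1e-12)
        sig_cols = [c for c in diff if c.endswith("_sig")]
        assert not diff[sig_cols].any().any()

    def test_contrast_diffs_match_means(self, design2, rng):
        m = pd.DataFrame(rng.poisson(80, size=(12, 8)), columns=design2.sample_ids)
        diff = diffstat.differential_analysis(m, design2)
        assert np.allclose(diff["young_mating_diff"], diff["mean_YM"] - diff["mean_YV"])
        assert np.allclose(diff["virgin_aging_diff"], diff["mean_AV"] - diff["mean_YV"])
        assert np.allclose(diff["mated_aging_diff"], diff["mean_AM"] - diff["mean_YM"])
        assert np.allclose(diff["aged_mating_diff"], diff["mean_AM"] - diff["mean_AV"])
        assert (diff["q"] >= diff["p"] - 1e-12).all()

    def test_effect_flag_matches_pooled_sd_gate(self, design2, rng):
        m = pd.DataFrame(rng.poisson(80, size=(12, 8)), columns=design2.sample_ids)
        diff = diffstat.differential_analysis(m, design2)
        for name in ("young_mating", "virgin_aging"):
            gate = diff[f"{name}_diff"].abs() > diff["pooled_sd"]
            assert (diff[f"{name}_effect"] == gate).all()

    def test_onoff_feature_calls_mating_contrasts_only(self, design5):
        # maternal-cluster-like pattern: expressed in mated conditions only.
        # Both mating contrasts must be called; virgin aging must not.
        cfg = SimulationConfig(seed=3, n_replicates=5, n_features=40,
                               frac_plastic=0.0, n_onoff=1)
        counts, truth = simulate_counts(cfg, design=design5)
        diff = diffstat.differential_analysis(counts, design5, n_perm=20_000, seed=9)
        row = diff.set_index("feature").loc["mirna_onoff0"]
        assert row["young_mating_sig"] and row["young_mating_diff"] > 0
        assert row["aged_mating_sig"] and row["aged_mating_diff"] > 0
        assert not row["virgin_aging_sig"]
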