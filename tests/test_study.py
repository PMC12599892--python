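"""Nonparametric tests, normalization, and the longitudinal study report."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from spheromech import study, synth
from spheromech.errors import ConfigurationError


def brute_force_exact_p(a, b):
    """Independent oracle: full enumeration of all C(n+m, n) labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, N = len(a), len(a) + len(b)
    ranks = sps.rankdata(pooled)
    obs = ranks[:n].sum() - n * (n + 1) / 2
    null = np.array(
        [ranks[list(idx)].sum() - n * (n + 1) / 2 for idx in itertools.combinations(range(N), n)]
    )
    p_le = np.mean(null <= obs + 1e-9)
    p_ge = np.mean(null >= obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_textbook_example(self):
        """a={1,2}, b={3,4}: U=0, exact two-sided p = 2/6."""
        gc = study.mann_whitney_u([1, 2], [3, 4])
        assert gc.statistic == 0.0
        assert gc.p_value == pytest.approx(1 / 3)
        assert gc.method == "exact"

    def test_identical_multisets_give_p_one_under_forced_exact(self):
        gc = study.mann_whitney_u([1, 2, 3], [1, 2, 3], mode="exact")
        assert gc.p_value == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        """Exact p equals brute-force enumeration for random tie-free inputs."""
        for _ in range(100):
            n = rng.integers(2, 6)
            m = rng.integers(2, 9 - n)
            vals = rng.normal(size=n + m)
            gc = study.mann_whitney_u(vals[:n], vals[n:], mode="exact")
            assert gc.p_value == pytest.approx(brute_force_exact_p(vals[:n], vals[n:]), abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        """Cross-check against the independent scipy implementation."""
        for _ in range(50):
            vals = rng.normal(size=10)
            gc = study.mann_whitney_u(vals[:5], vals[5:], mode="exact")
            ref = sps.mannwhitneyu(vals[:5], vals[5:], alternative="two-sided", method="exact")
            assert gc.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_fall_back_to_normal_in_auto(self):
        gc = study.mann_whitney_u([1, 1, 2], [2, 3, 3], mode="auto")
        assert gc.method == "normal_approx"
        assert gc.extra["ties"]

    def test_normal_approx_matches_scipy_with_continuity(self, rng):
        vals = rng.normal(size=40)
        gc = study.mann_whitney_u(vals[:20], vals[20:], mode="normal")
        ref = sps.mannwhitneyu(vals[:20], vals[20:], alternative="two-sided", method="asymptotic")
        assert gc.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ConfigurationError):
            study.mann_whitney_u([], [1, 2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=10, unique=True))
    def test_exact_p_valid_and_label_symmetric(self, values):
        n = len(values) // 2
        a, b = values[:n], values[n:]
        p_ab = study.mann_whitney_u(a, b, mode="exact").p_value
        p_ba = study.mann_whitney_u(b, a, mode="exact").p_value
        assert 0 < p_ab <= 1
        assert p_ab == pytest.approx(p_ba, abs=1e-12)


class TestKruskalWallis:
    def test_all_equal_values_give_h_zero_p_one(self):
        gc = study.kruskal_wallis([[5, 5, 5], [5, 5], [5, 5, 5]])
        assert gc.statistic == 0.0 and gc.p_value == 1.0

    def test_hand_computed_rank_formula(self):
        """Groups {1,2,3},{4,5,6},{7,8,9}: H = 12/(9*10) * 3*((2-5)^2+0+(8-5)^2)... = 7.2."""
        gc = study.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert gc.statistic == pytest.approx(7.2)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            g = [rng.integers(0, 6, size=rng.integers(3, 8)).astype(float) for _ in range(3)]
            if np.ptp(np.concatenate(g)) == 0:
                continue
            gc = study.kruskal_wallis(g)
            ref = sps.kruskal(*g)
            assert gc.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert gc.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_groups_equal_squared_z_of_u_test(self, rng):
        """Known equivalence: KW H on 2 groups = z^2 of the (tie-corrected,
        no continuity correction) normal-approximation U test."""
        for _ in range(25):
            a = rng.integers(0, 10, size=6).astype(float)
            b = rng.integers(0, 10, size=8).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            h = study.kruskal_wallis([a, b]).statistic
            z = study.mann_whitney_u(a, b, mode="normal", continuity=False).extra["z"]
            assert h == pytest.approx(z**2, rel=1e-9, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        g = [rng.normal(size=5) for _ in range(3)]
        h1 = study.kruskal_wallis(g).statistic
        h2 = study.kruskal_wallis([np.exp(x) for x in g]).statistic
        assert h1 == pytest.approx(h2)

    def test_exact_permutation_small_n(self):
        g = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        gc = study.kruskal_wallis(g, method="exact")
        assert gc.method == "exact"
        assert 0 < gc.p_value <= 1
        # chi2 and exact must broadly agree in ordering of evidence
        assert gc.p_value < 0.2

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigurationError):
            study.kruskal_wallis([[1.0, 2.0], []])


class TestNormalization:
    def test_identical_conditions_give_unit_ratios(self):
        spec = synth.default_study_spec(cv=0.0)
        for key, f in spec.day_factors.items():
            if key[1] == "treated":
                f.update(spec.day_factors[(key[0], "control")])
        table = synth.make_study_dataset(
            synth.StudyEffectSpec(spec.baselines, spec.day_factors, cv=0.0, n_replicates=3)
        )
        norm = study.normalize_treated_to_control(table, "wave_speed_mps")
        assert np.allclose(norm["ratio"], 1.0)

    def test_known_effect_ratio_recovered_at_zero_cv(self):
        spec = synth.default_study_spec(cv=0.0)
        table = synth.make_study_dataset(spec)
        norm = study.normalize_treated_to_control(table, "wave_speed_mps")
        day7 = norm[(norm.group == "LN229") & (norm.day == 7)].iloc[0]
        assert day7["ratio"] == pytest.approx(0.5 / 0.9)
        assert day7["ratio_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_condition_flagged_not_dropped(self):
        table = synth.make_study_dataset(synth.default_study_spec(cv=0.0, n_replicates=3))
        table = table[~((table.group == "HA") & (table.condition == "treated") & (table.day == 7))]
        norm = study.normalize_treated_to_control(table, "wave_speed_mps")
        row = norm[(norm.group == "HA") & (norm.day == 7)].iloc[0]
        assert not row["valid"] and np.isnan(row["ratio"])
        assert norm["valid"].sum() == len(norm) - 1

    def test_day0_ratio_reported_not_rebased(self):
        table = synth.make_study_dataset(synth.default_study_spec(seed=11))
        norm = study.normalize_treated_to_control(table, "wave_speed_mps")
        day0 = norm[norm.day == 0]["ratio"]
        assert not np.allclose(day0, 1.0)  # noisy ratios reported as computed


class TestSummarizeStudy:
    def test_effect_structure_flagged_correctly(self):
        table = synth.make_study_dataset(synth.default_study_spec(seed=1))
        report = study.summarize_study(table)
        mwu = {(r["group"], r["day"]): r for r in report["mann_whitney"]}
        assert mwu[("LN229", 7)]["significant"]
        assert not mwu[("HA", 7)]["significant"]

    def test_constant_table_all_nonsignificant(self):
        spec = synth.default_study_spec(cv=0.0)
        flat = {d: 1.0 for d in (0, 4, 7)}
        table = synth.make_study_dataset(
            synth.StudyEffectSpec(
                baselines={k: 1.0 for k in spec.baselines},
                day_factors={k: dict(flat) for k in spec.day_factors},
                cv=0.0, n_replicates=3,
            )
        )
        report = study.summarize_study(table)
        assert all(r["statistic"] == 0.0 and not r["significant"] for r in report["kruskal_wallis"])
        assert all(not r["significant"] for r in report["mann_whitney"])

    def test_row_permutation_invariance(self, rng):
        table = synth.make_study_dataset(synth.default_study_spec(seed=5))
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert study.summarize_study(table) == study.summarize_study(shuffled)

    def test_duplicate_keys_rejected(self):
        table = synth.make_study_dataset(synth.default_study_spec(n_replicates=3))
        bad = np.vstack([table.values, table.values[:1]])
        import pandas as pd

        with pytest.raises(ConfigurationError):
            study.summarize_study(pd.DataFrame(bad, columns=table.columns))
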