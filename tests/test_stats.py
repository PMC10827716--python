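import itertools

import numpy as np
import pandas as pd
import pytest

from strokequant.stats import (compare_groups, dunn_posthoc, normality_gate,
                               outcome_report, repeated_measures)


class TestGate:
    def test_normal_groups_usually_pass(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(size=20) for g in "abcd"}
            gate, _ = normality_gate(groups)
            hits += gate == "parametric"
        assert hits >= 45  # expected pass rate (1 - alpha)^4 ~ 0.81; 45/50 allows margin below

    def test_bimodal_group_forces_nonparametric(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            bimodal = np.concatenate([rng.normal(-8, 0.5, 25),
                                      rng.normal(8, 0.5, 25)])
            groups = {"a": rng.normal(size=50), "b": bimodal}
            gate, _ = normality_gate(groups)
            hits += gate == "nonparametric"
        assert hits >= 38

    def test_tiny_group_warns_and_degrades(self):
        with pytest.warns(UserWarning, match="n=2"):
            gate, notes = normality_gate({"a": [1.0, 2.0],
                                          "b": [1.0, 2.0, 3.0]})
        assert gate == "nonparametric"
        assert notes


def _exact_mwu(a, b):
    """Brute-force two-sided Mann-Whitney p by exhaustive enumeration of
    group labelings of the pooled sample."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(idx):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for xi in x for yi in y if xi > yi) \
            + 0.5 * sum(1 for xi in x for yi in y if xi == yi)

    observed = u_stat(tuple(range(n_a)))
    n = len(pooled)
    us = [u_stat(c) for c in itertools.combinations(range(n), n_a)]
    mean_u = n_a * (n - n_a) / 2
    extreme = sum(1 for u in us if abs(u - mean_u) >= abs(observed - mean_u))
    return observed, extreme / len(us)


class TestCompareGroups:
    def test_two_separated_groups_match_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups({"lo": a, "hi": b}, gate="nonparametric")
        u, p = _exact_mwu(a, b)
        assert res.test_name == "Wilcoxon rank-sum"
        assert res.statistic in (u, len(a) * len(b) - u)
        assert res.p == pytest.approx(p)

    def test_kruskal_matches_hand_computation(self):
        # three groups without ties: H = 12/(N(N+1)) * sum n_i R_i^2 - 3(N+1)
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = compare_groups(groups, gate="nonparametric")
        ranks = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        h = 12 / (9 * 10) * sum(
            len(r) * (np.mean(r)) ** 2 for r in ranks.values()) - 3 * 10
        assert res.statistic == pytest.approx(h)
        assert res.post_hoc  # Dunn pairs present

    def test_constant_groups_take_degenerate_path(self):
        res = compare_groups({g: [5.0] * 4 for g in "abcd"})
        assert res.p == 1.0
        assert "all values identical" in ";".join(res.notes)

    def test_rank_tests_invariant_under_monotone_transform(self, rng):
        groups = {g: rng.normal(size=9) for g in "abc"}
        res = compare_groups(groups, gate="nonparametric", post_hoc=False)
        warped = {g: np.exp(3 * v) for g, v in groups.items()}
        res2 = compare_groups(warped, gate="nonparametric", post_hoc=False)
        assert res2.statistic == pytest.approx(res.statistic)
        assert res2.p == pytest.approx(res.p)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2, 3]})

    def test_null_rejection_rate_near_alpha(self):
        """Gate-then-compare on 4 x n=7 normal null data rejects near the
        nominal 5% level (400 quick replicates; the acceptance suite runs
        the full-size simulation)."""
        rng = np.random.default_rng(7)
        rej = sum(compare_groups({g: rng.normal(size=7) for g in "abcd"},
                                 post_hoc=False).p < 0.05
                  for _ in range(400))
        assert 0.02 <= rej / 400 <= 0.08


class TestDunn:
    def test_adjusted_p_at_least_unadjusted_and_bounded(self, rng):
        groups = {g: rng.normal(loc, size=8)
                  for g, loc in zip("abcd", (0, 0, 1, 3))}
        pairs = dunn_posthoc({k: np.asarray(v, float)
                              for k, v in groups.items()})
        assert len(pairs) == 6
        for _, p in pairs:
            assert 0 <= p <= 1

    def test_separated_group_flagged(self, rng):
        groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
                  "c": rng.normal(12, 1, 10)}
        pairs = dict(dunn_posthoc({k: np.asarray(v, float)
                                   for k, v in groups.items()}))
        assert pairs["a vs c"] < 0.05


def _rm_table(rng, n_per_arm=6, arms=("a", "b"), shift=0.0,
              timepoints=("t0", "t1", "t2")):
    rows = []
    for arm in arms:
        for i in range(n_per_arm):
            base = rng.normal()
            for j, tp in enumerate(timepoints):
                rows.append({"animal_id": f"{arm}{i}", "arm": arm,
                             "timepoint": tp,
                             "value": base + shift * j + rng.normal()})
    return pd.DataFrame(rows)


class TestRepeatedMeasures:
    def test_time_shift_detected(self):
        hits = 0
        for seed in range(20):
            df = _rm_table(np.random.default_rng(seed), shift=2.5)
            res = repeated_measures(df, gate="parametric")
            hits += res.effects["time"].p < 0.001
        assert hits >= 19

    def test_null_time_effect_rate_near_alpha(self):
        rej = 0
        n = 200
        for seed in range(n):
            df = _rm_table(np.random.default_rng(1000 + seed), shift=0.0)
            res = repeated_measures(df, gate="parametric")
            rej += res.effects["time"].p < 0.05
        assert 0.02 <= rej / n <= 0.09

    def test_friedman_matches_brute_force_on_small_n(self):
        """Friedman statistic equals the exact rank computation for a tiny
        block design (no ties)."""
        rng = np.random.default_rng(2)
        df = _rm_table(rng, n_per_arm=4, arms=("a",))
        res = repeated_measures(df, gate="nonparametric")
        wide = df.pivot_table(index="animal_id", columns="timepoint",
                              values="value")
        ranks = np.argsort(np.argsort(wide.to_numpy(), axis=1), axis=1) + 1
        n, k = ranks.shape
        q = 12 * n / (k * (k + 1)) * np.sum(
            (ranks.mean(axis=0) - (k + 1) / 2) ** 2)
        assert res.test_name == "Friedman"
        assert res.statistic == pytest.approx(q)

    def test_two_timepoints_use_signed_rank(self):
        df = _rm_table(np.random.default_rng(3), timepoints=("t0", "t1"))
        res = repeated_measures(df, gate="nonparametric")
        assert res.test_name == "Wilcoxon signed-rank"

    def test_incomplete_subject_removed_listwise(self):
        df = _rm_table(np.random.default_rng(4))
        df = df[~((df.animal_id == "a0") & (df.timepoint == "t2"))]
        res = repeated_measures(df, gate="parametric")
        assert any("a0" in n for n in res.notes)


class TestOutcomeReport:
    def test_injected_group_effect_flagged_and_null_not(self, rng):
        null = pd.DataFrame({
            "animal_id": [f"x{i}" for i in range(28)],
            "arm": list("abcd") * 7,
            "value": rng.normal(size=28)})
        effect = null.copy()
        effect["value"] = effect["value"] + np.where(
            effect["arm"] == "d", 8.0, 0.0)
        rep = outcome_report({"quiet": null, "loud": effect})
        rep = rep.set_index("outcome")
        assert not rep.loc["quiet", "significant"]
        assert rep.loc["loud", "significant"]
        assert "d" in rep.loc["loud", "posthoc_significant"]

    def test_empty_outcome_omitted_with_warning(self):
        tab = pd.DataFrame({"animal_id": ["a", "b", "c", "d"],
                            "arm": ["x", "x", "y", "y"],
                            "value": [1.0, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="no data"):
            rep = outcome_report({"ok": tab, "empty": tab.iloc[:0]})
        assert rep["outcome"].tolist() == ["ok"]

    def test_empty_input_gives_empty_report(self):
        rep = outcome_report({})
        assert len(rep) == 0
        assert "outcome" in rep.columns
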