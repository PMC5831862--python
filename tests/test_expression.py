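"""ddCt closed forms, t-test oracle, type-I error, clustering behavior."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmeta.expression import (
    ExpressionParams,
    bh_adjust,
    cluster_heatmap_matrix,
    ddct,
    stage_profile_vector,
    stage_test,
    summarize,
)
from mirmeta.simulate import SimulationConfig, gen_expression


def _ct_table(mirna_cts, u6_ct=18.0, stages=(18, 21, 42), reps=3):
    """mirna_cts: {mirna: {stage: ct}} constant across replicates."""
    rows = []
    for stage in stages:
        for rep in range(1, reps + 1):
            rows.append({"mirna": "U6", "stage": stage, "replicate": rep, "ct": u6_ct})
            for mirna, per_stage in mirna_cts.items():
                rows.append(
                    {
                        "mirna": mirna,
                        "stage": stage,
                        "replicate": rep,
                        "ct": per_stage[stage],
                    }
                )
    return pd.DataFrame(rows)


class TestDdct:
    def test_reference_stage_is_one(self):
        ct = _ct_table({"m": {18: 25.0, 21: 25.0, 42: 25.0}})
        res = ddct(ct, 18)
        assert np.allclose(res["rel_expr"], 1.0, atol=1e-12)

    def test_minus_one_ddct_doubles(self):
        ct = _ct_table({"m": {18: 25.0, 21: 25.0, 42: 24.0}})
        res = ddct(ct, 18)
        at42 = res[res["stage"] == 42]["rel_expr"]
        assert np.allclose(at42, 2.0, atol=1e-12)

    def test_synthetic_effect_exact_without_noise(self):
        cfg = SimulationConfig(
            seed=2, ct_noise_sd=0.0, stage_effects={"m": {42: 2.0}}
        )
        ct, _, _ = gen_expression(cfg, mirna_ids=["m"])
        res = ddct(ct, 18)
        summary = summarize(res).set_index(["mirna", "stage"])
        assert summary.loc[("m", 42), "mean"] == pytest.approx(2.0, abs=1e-9)
        assert summary.loc[("m", 18), "mean"] == pytest.approx(1.0, abs=1e-9)

    def test_unit_effect_everywhere(self):
        cfg = SimulationConfig(seed=2, ct_noise_sd=0.0, stage_effects={"m": {}})
        ct, _, _ = gen_expression(cfg, mirna_ids=["m"])
        res = ddct(ct, 18)
        assert np.allclose(res["rel_expr"], 1.0, atol=1e-9)

    def test_missing_reference_gene(self):
        ct = _ct_table({"m": {18: 25.0, 21: 25.0, 42: 25.0}})
        ct = ct[ct["mirna"] != "U6"]
        with pytest.raises(ValueError, match="reference gene"):
            ddct(ct, 18)

    def test_missing_reference_stage(self):
        ct = _ct_table({"m": {18: 25.0, 21: 25.0, 42: 25.0}})
        with pytest.raises(ValueError):
            ddct(ct, 99)

    def test_shift_invariance(self):
        """Adding a constant to both target and U6 Ct of one stage leaves
        relative expression unchanged."""
        ct1 = _ct_table({"m": {18: 25.0, 21: 26.0, 42: 24.0}})
        ct2 = ct1.copy()
        shift = ct2["stage"] == 21
        ct2.loc[shift, "ct"] += 3.5
        r1 = ddct(ct1, 18).sort_values(["stage", "replicate"])["rel_expr"]
        r2 = ddct(ct2, 18).sort_values(["stage", "replicate"])["rel_expr"]
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)


class TestStageTest:
    def test_identical_groups_unchanged(self):
        ct = _ct_table({"m": {18: 25.0, 21: 25.0, 42: 25.0}})
        res = ddct(ct, 18)
        out = stage_test(res, 42, [18, 21])
        assert out.loc[0, "p_value"] == 1.0
        assert out.loc[0, "direction"] == "unchanged"

    def test_planted_strong_up_effect(self):
        cfg = SimulationConfig(
            seed=3, ct_noise_sd=0.1, stage_effects={"m": {42: 8.0}}
        )
        ct, _, _ = gen_expression(cfg, mirna_ids=["m"])
        res = ddct(ct, 18)
        out = stage_test(res, 42, [18, 21]).set_index("mirna")
        assert bool(out.loc["m", "significant"])
        assert out.loc["m", "direction"] == "up"

    def test_t_statistic_matches_closed_form(self):
        a = np.array([24.1, 24.5, 23.9])
        b = np.array([26.0, 25.8, 26.3])
        rows = []
        for rep, (x, y) in enumerate(zip(a, b), 1):
            rows.append({"mirna": "m", "stage": 42, "replicate": rep, "dct": x})
            rows.append({"mirna": "m", "stage": 18, "replicate": rep, "dct": y})
        res = pd.DataFrame(rows)
        res["rel_expr"] = 2.0 ** (-res["dct"])  # not used by the test path
        out = stage_test(res, 42, [18])
        # hand-computed pooled-variance two-sample t
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert out.loc[0, "p_value"] == pytest.approx(p, abs=1e-12)

    @staticmethod
    def null_flag_rate(n_sim=1000, sd=0.3, n_reps=3, alpha=0.01, seed=42,
                       baselines=(18,)):
        """Flag rate of stage_test on independent null miRNAs (no effect)."""
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_sim):
            for stage in (18, 21, 42):
                for rep in range(1, n_reps + 1):
                    rows.append(
                        {
                            "mirna": f"null{i:04d}",
                            "stage": stage,
                            "replicate": rep,
                            "dct": rng.normal(0, sd),
                        }
                    )
        res = pd.DataFrame(rows)
        res["rel_expr"] = 2.0 ** (-res["dct"])
        out = stage_test(
            res, 42, list(baselines), ExpressionParams(alpha=alpha)
        )
        return out["significant"].mean()

    def test_type_one_error_rate(self):
        """Null simulation: per-comparison flag rate at alpha=0.01 lies in
        [0.003, 0.03].  (Requiring significance against both earlier stages
        is strictly more conservative, so it is also checked to stay below
        the upper bound.)"""
        rate_single = self.null_flag_rate(baselines=(18,))
        assert 0.003 <= rate_single <= 0.03
        rate_both = self.null_flag_rate(baselines=(18, 21))
        assert rate_both <= 0.03

    def test_too_few_replicates(self):
        rows = [
            {"mirna": "m", "stage": s, "replicate": 1, "dct": 1.0, "rel_expr": 1.0}
            for s in (18, 42)
        ]
        with pytest.raises(ValueError, match="replicates"):
            stage_test(pd.DataFrame(rows), 42, [18])


class TestBH:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        assert q[0] == pytest.approx(0.004)


class TestHeatmap:
    def _results(self, profiles):
        rows = []
        for mirna, vec in profiles.items():
            for stage, value in zip((18, 21, 42), vec):
                for rep in (1, 2):
                    rows.append(
                        {
                            "mirna": mirna,
                            "stage": stage,
                            "replicate": rep,
                            "dct": -np.log2(value),
                            "rel_expr": value,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_rows_merge_first(self):
        res = self._results(
            {"a": [1, 2, 4], "b": [1, 2, 4], "c": [4, 2, 1]}
        )
        _, linkage = cluster_heatmap_matrix(res, (18, 21, 42))
        first = linkage[0]
        assert first[2] == pytest.approx(0.0, abs=1e-12)  # a and b at distance 0
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_outlier_joins_last(self):
        res = self._results(
            {"a": [1, 2, 4], "b": [1.1, 2.1, 4.2], "c": [8, 2, 0.5]}
        )
        _, linkage = cluster_heatmap_matrix(res, (18, 21, 42))
        # last merge joins the anticorrelated outlier (index 2)
        assert int(linkage[-1][0]) == 2 or int(linkage[-1][1]) == 2

    def test_permutation_invariant_topology(self):
        profiles = {"a": [1, 2, 4], "b": [1.1, 2.2, 4.1], "c": [5, 1, 0.3]}
        res1 = self._results(profiles)
        res2 = self._results(dict(reversed(list(profiles.items()))))
        m1, l1 = cluster_heatmap_matrix(res1, (18, 21, 42))
        m2, l2 = cluster_heatmap_matrix(res2, (18, 21, 42))
        assert set(map(tuple, m1.round(9).values)) == set(
            map(tuple, m2.round(9).values)
        )

    def test_single_row_rejected(self):
        res = self._results({"a": [1, 2, 4]})
        with pytest.raises(ValueError):
            cluster_heatmap_matrix(res, (18, 21, 42))


class TestProfiles:
    def test_fixed_stage_order(self):
        res = TestHeatmap()._results({"a": [1.0, 2.0, 4.0]})
        vec = stage_profile_vector(res, "a", (18, 21, 42))
        assert np.allclose(vec, [1.0, 2.0, 4.0])

    def test_planted_decreasing_profile(self):
        cfg = SimulationConfig(
            seed=4, ct_noise_sd=0.0, stage_effects={"m": {21: 0.5, 42: 0.25}}
        )
        ct, _, _ = gen_expression(cfg, mirna_ids=["m"])
        res = ddct(ct, 18)
        vec = stage_profile_vector(res, "m", (18, 21, 42))
        assert vec[0] > vec[1] > vec[2]

    def test_single_stage_errors(self):
        res = TestHeatmap()._results({"a": [1.0, 2.0, 4.0]})
        with pytest.raises(ValueError):
            stage_profile_vector(res, "a", (18,))

    def test_unknown_mirna(self):
        res = TestHeatmap()._results({"a": [1.0, 2.0, 4.0]})
        with pytest.raises(ValueError):
            stage_profile_vector(res, "zz", (18, 21, 42))
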