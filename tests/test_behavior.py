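"""Bootstrap/KS/effect-size behavioral statistics."""

import numpy as np
import pandas as pd
import pytest

from coactnet.behavior import (
    bootstrap_ci_mean,
    bootstrap_p,
    cohens_d,
    f_statistic,
    ks_two_sample,
    oneway_F,
    pairwise_t_bootstrap,
    regionwise_expression_test,
    welch_t,
)
from coactnet.datatypes import BehaviorTable


def table_from(groups: dict[str, list[float]]) -> BehaviorTable:
    rows = [
        {"subject": f"{g}{i}", "group": g, "freezing_s": v}
        for g, values in groups.items()
        for i, v in enumerate(values)
    ]
    return BehaviorTable(pd.DataFrame(rows))


class TestOnewayF:
    def test_hand_computed_on_3x3_fixture(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [4.0, 5.0, 6.0]}
        # grand mean 10/3; SSbetween = 3*[(2-10/3)^2+(3-10/3)^2+(5-10/3)^2]
        # = 14; MSb = 7; SSwithin = 6; MSw = 1 -> F = 7
        assert oneway_F(table_from(groups)) == pytest.approx(7.0)

    def test_two_groups_equals_pooled_t_squared(self, rng):
        a = rng.normal(10, 2, 12)
        b = rng.normal(12, 2, 9)
        f_val = f_statistic([a, b])
        # pooled-variance two-sample t
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_val = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert f_val == pytest.approx(t_val**2, rel=1e-10)

    def test_constant_groups_rejected(self):
        groups = {"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}
        with pytest.raises(ValueError, match="zero within-group variance"):
            oneway_F(table_from(groups))

    def test_location_invariance_and_scale(self, rng):
        samples = [rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
        f_base = f_statistic(samples)
        assert f_statistic([s + 7.5 for s in samples]) == pytest.approx(f_base)
        assert f_statistic([s * 3.0 for s in samples]) == pytest.approx(f_base)


class TestBootstrapP:
    def test_same_seed_identical(self, rng):
        samples = [rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)]
        r1 = bootstrap_p(f_statistic, samples, 500, rng_seed=9)
        r2 = bootstrap_p(f_statistic, samples, 500, rng_seed=9)
        assert r1 == r2

    def test_planted_shift_detected(self, rng):
        rejections = 0
        for k in range(100):
            local = np.random.default_rng(k)
            a = local.normal(0.0, 1.0, 10)
            b = local.normal(2.0, 1.0, 10)  # 2 pooled SDs apart
            _, p = bootstrap_p(f_statistic, [a, b], 500, rng_seed=k)
            rejections += p < 0.05
        assert rejections >= 95

    def test_few_resamples_warns(self, rng):
        with pytest.warns(UserWarning, match="unstable"):
            bootstrap_p(f_statistic, [rng.normal(size=8), rng.normal(size=8)], 50, 0)


class TestPairwiseT:
    def test_single_comparison_uncorrected(self, rng):
        table = table_from(
            {"a": list(rng.normal(10, 2, 8)), "b": list(rng.normal(14, 2, 8))}
        )
        res = pairwise_t_bootstrap(table, [("a", "b")], n_resamples=500)
        assert res[0].p_corrected == res[0].p

    def test_correction_capped_at_one(self, rng):
        table = table_from(
            {
                "a": list(rng.normal(10, 2, 8)),
                "b": list(rng.normal(10, 2, 8)),
                "c": list(rng.normal(10, 2, 8)),
            }
        )
        comparisons = [("a", "b"), ("a", "c"), ("b", "c")]
        for res in pairwise_t_bootstrap(table, comparisons, n_resamples=300):
            assert res.p_corrected <= 1.0
            assert res.p_corrected == pytest.approx(min(1.0, res.p * 3))

    def test_planted_pair_detected(self):
        hits = 0
        misses = 0
        for k in range(60):
            local = np.random.default_rng(500 + k)
            table = table_from(
                {
                    "a": list(local.normal(100, 15, 10)),
                    "b": list(local.normal(100, 15, 10)),
                    "c": list(local.normal(160, 15, 10)),  # 4 SD shift
                }
            )
            comparisons = [("a", "b"), ("a", "c"), ("b", "c")]
            res = pairwise_t_bootstrap(table, comparisons, 400, rng_seed=k)
            by_pair = {r.groups: r.p_corrected for r in res}
            if by_pair[("a", "c")] < 0.05 and by_pair[("b", "c")] < 0.05:
                hits += 1
            if by_pair[("a", "b")] < 0.05:
                misses += 1
        assert hits >= 54  # >= 90%
        assert misses <= 12


class TestRegionwise:
    def test_fdr_column_matches_hand_bh_of_raw_p(self, study_expressions):
        exprA = study_expressions["SHAM"].restrict(["RSC", "IL", "vSub", "Por"])
        exprB = study_expressions["dHPC"].restrict(["RSC", "IL", "vSub", "Por"])
        out = regionwise_expression_test(exprA, exprB, n_resamples=300)

        def hand_bh(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            return adj

        np.testing.assert_allclose(
            out["p_fdr"], hand_bh(out["p"].to_numpy()), atol=1e-12
        )

    def test_single_region_uncorrected(self, study_expressions):
        exprA = study_expressions["SHAM"].restrict(["RSC"])
        exprB = study_expressions["dHPC"].restrict(["RSC"])
        out = regionwise_expression_test(exprA, exprB, n_resamples=200)
        assert out.loc[0, "p_fdr"] == out.loc[0, "p"]

    def test_null_rejection_rate_bounded(self):
        sig_frac = []
        for k in range(20):
            local = np.random.default_rng(900 + k)
            from coactnet.datatypes import ExpressionMatrix

            def draw(label):
                data = pd.DataFrame(
                    local.normal(100, 10, size=(10, 8)),
                    index=[f"{label}{i}" for i in range(10)],
                    columns=[f"r{j}" for j in range(8)],
                )
                return ExpressionMatrix(data, pd.Series(label, index=data.index))

            out = regionwise_expression_test(draw("a"), draw("b"), n_resamples=200)
            sig_frac.append((out["p"] < 0.05).mean())
        assert np.mean(sig_frac) == pytest.approx(0.05, abs=0.04)


class TestKSAndCohensD:
    def test_identical_samples_zero_D(self):
        x = np.array([1.0, 2.0, 3.0])
        D, _ = ks_two_sample(x, x)
        assert D == 0.0

    def test_disjoint_samples_full_D(self):
        D, _ = ks_two_sample(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert D == 1.0

    def test_cohens_d_hand_value(self):
        assert cohens_d(np.array([1.0, 2, 3]), np.array([3.0, 4, 5])) == pytest.approx(
            2.0
        )

    def test_cohens_d_antisymmetric_signed(self):
        a, b = np.array([1.0, 2, 3]), np.array([2.0, 4, 6])
        assert cohens_d(a, b, signed=True) == -cohens_d(b, a, signed=True)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d(np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_equal_means_zero(self):
        assert cohens_d(np.array([1.0, 3.0]), np.array([0.0, 4.0])) == 0.0


class TestBootstrapCI:
    def test_constant_sample_degenerate(self):
        lo, hi = bootstrap_ci_mean(np.full(10, 4.2), n_resamples=200)
        assert lo == pytest.approx(4.2, abs=1e-12)
        assert hi == pytest.approx(lo, abs=1e-12)

    def test_same_seed_identical(self, rng):
        x = rng.normal(size=30)
        assert bootstrap_ci_mean(x, 500, rng_seed=3) == bootstrap_ci_mean(
            x, 500, rng_seed=3
        )

    def test_coverage_near_nominal(self):
        covered = 0
        n_sim = 300
        for k in range(n_sim):
            local = np.random.default_rng(1_000 + k)
            x = local.normal(5.0, 2.0, 30)
            lo, hi = bootstrap_ci_mean(x, 400, rng_seed=k)
            covered += lo <= 5.0 <= hi
        assert covered / n_sim == pytest.approx(0.95, abs=0.03)
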