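"""T-score standardization, effect flags, correlation matrices with Fisher-z
CIs, cross-matrix comparison, and benchmark deviation tables."""

import numpy as np
import pandas as pd
import pytest

from panelqc import compare
from panelqc.synthetic_cohort import PersonaConfig, generate_cohort


class TestTScores:
    def test_self_standardization(self, rng):
        x = rng.standard_normal(2000) * 3 + 7
        t = compare.tscore_standardize(x, x)
        assert t.mean() == pytest.approx(50.0, abs=1e-9)
        assert t.std(ddof=1) == pytest.approx(10.0, abs=1e-9)

    def test_one_sd_above_is_sixty(self):
        ref = [1.0, 2.0, 3.0, 4.0, 5.0]
        sd = np.std(ref, ddof=1)
        t = compare.tscore_standardize([3.0 + sd], ref)
        assert t.iloc[0] == pytest.approx(60.0)

    def test_affine_invariance(self, rng):
        ref = rng.standard_normal(500)
        x = rng.standard_normal(100)
        t1 = compare.tscore_standardize(x, ref)
        t2 = compare.tscore_standardize(4 * x - 2, 4 * ref - 2)
        assert np.allclose(t1, t2)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            compare.tscore_standardize([1.0], [2.0, 2.0, 2.0])


class TestEffectFlag:
    @pytest.mark.parametrize(
        "t1, t2, flagged",
        [(52.0, 50.0, False), (52.1, 50.0, True), (50.0, 52.1, True), (50.0, 50.0, False)],
    )
    def test_strict_threshold_and_symmetry(self, t1, t2, flagged):
        assert compare.effect_flag(t1, t2) is flagged


class TestCorrelationMatrix:
    def test_diagonal_and_antithetic(self, rng):
        x = rng.standard_normal(300)
        df = pd.DataFrame({"x": x, "y": -x, "z": rng.standard_normal(300)})
        res = compare.correlation_matrix(df)
        assert res.r.loc["x", "x"] == 1.0
        assert res.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_constant_column_undefined(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(50), "c": np.ones(50)})
        res = compare.correlation_matrix(df)
        assert np.isnan(res.r.loc["x", "c"])

    def test_pairwise_complete_counts(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(100), "y": rng.standard_normal(100)})
        df.loc[:19, "y"] = np.nan
        res = compare.correlation_matrix(df)
        assert res.n.loc["x", "y"] == 80

    def test_bivariate_normal_ci_covers_truth(self, rng):
        rho, n = 0.5, 10000
        cov = [[1, rho], [rho, 1]]
        df = pd.DataFrame(rng.multivariate_normal([0, 0], cov, n), columns=["a", "b"])
        res = compare.correlation_matrix(df)
        assert res.ci_low.loc["a", "b"] < rho < res.ci_high.loc["a", "b"]
        assert res.r.loc["a", "b"] == pytest.approx(rho, abs=0.03)

    def test_fisher_ci_coverage_quick(self, rng):
        rho, n, reps = 0.5, 200, 300
        cov = np.array([[1, rho], [rho, 1]])
        chol = np.linalg.cholesky(cov)
        hits = 0
        for _ in range(reps):
            xy = rng.standard_normal((n, 2)) @ chol.T
            r = np.corrcoef(xy.T)[0, 1]
            lo, hi = compare.fisher_ci(r, n)
            hits += lo < rho < hi
        assert 0.91 <= hits / reps <= 0.99

    def test_spearman_option(self, rng):
        x = rng.standard_normal(200)
        df = pd.DataFrame({"x": x, "y": np.exp(x)})  # monotone, nonlinear
        res = compare.correlation_matrix(df, method="spearman")
        assert res.r.loc["x", "y"] == pytest.approx(1.0)


def sym(mat, cols):
    return pd.DataFrame(mat, index=cols, columns=cols)


class TestCompareCorrelationMatrices:
    M1 = sym([[1.0, 0.5, 0.2], [0.5, 1.0, -0.1], [0.2, -0.1, 1.0]], ["a", "b", "c"])

    def test_identical_matrices(self):
        out = compare.compare_correlation_matrices(self.M1, self.M1.copy())
        assert out.mean_abs_diff == 0.0 and out.n_sign_flips == 0

    def test_negated_matrix_flips_everything(self):
        out = compare.compare_correlation_matrices(self.M1, -self.M1)
        assert out.n_sign_flips == out.n_pairs == 3

    def test_hand_enumeration(self):
        m2 = sym([[1.0, 0.46, 0.32], [0.46, 1.0, 0.1], [0.32, 0.1, 1.0]], ["a", "b", "c"])
        out = compare.compare_correlation_matrices(self.M1, m2)
        diffs = [abs(0.5 - 0.46), abs(0.2 - 0.32), abs(-0.1 - 0.1)]
        assert out.n_pairs == 3
        assert out.mean_abs_diff == pytest.approx(np.mean(diffs))
        assert out.max_abs_diff == pytest.approx(0.2)
        assert out.prop_exceeding[0.05] == pytest.approx(2 / 3)
        assert out.prop_exceeding[0.15] == pytest.approx(1 / 3)
        assert out.n_sign_flips == 1 and out.sign_flips == [("b", "c")]
        assert out.share_second_larger == pytest.approx(1 / 3)

    def test_commutes_with_relabeling(self):
        order = ["c", "a", "b"]
        m2 = self.M1 * 0.9
        a = compare.compare_correlation_matrices(self.M1, m2)
        b = compare.compare_correlation_matrices(
            self.M1.loc[order, order], m2.loc[order, order]
        )
        assert a.mean_abs_diff == pytest.approx(b.mean_abs_diff)
        assert a.n_sign_flips == b.n_sign_flips

    def test_mismatched_variables_rejected(self):
        other = sym(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError):
            compare.compare_correlation_matrices(self.M1, other)

    def test_planted_education_reversal_is_detected(self, codebook):
        """Two cohorts whose education effect on the latent health factor has
        opposite signs: every education x scale-score correlation pair should
        flip sign between the samples."""
        effects = {"education": {"no_hs": -0.4, "hs_grad": -0.2, "some_college": 0.0,
                                 "bachelors": 0.2, "masters_plus": 0.4}}
        flipped = {"education": {k: -v for k, v in effects["education"].items()}}
        frames = {}
        for name, eff in (("pos", effects), ("neg", flipped)):
            cfg = PersonaConfig(
                n_respondents=4000, persona_mix={"attentive": 1.0},
                demo_trait_effects=eff, health_loading=0.8,
                missing_rate=0.0, seed=55,
            )
            c = generate_cohort(cfg, codebook)
            scores = compare.score_scales(c.responses, codebook)
            scores["education"] = c.demographics["education"].map(
                {c_: i + 1 for i, c_ in enumerate(codebook.demographic_variables["education"])}
            )
            frames[name] = compare.correlation_matrix(scores)
        out = compare.compare_correlation_matrices(frames["pos"], frames["neg"])
        edu_flips = {frozenset(p) for p in out.sign_flips if "education" in p}
        expected = {frozenset({"education", s}) for s in codebook.scales}
        assert expected <= edu_flips


class TestBenchmarkTable:
    BENCH = {"v1": 10.0, "v2": 20.0}

    def test_zero_deviation_when_equal(self):
        est = {"all": {"v1": 10.0, "v2": 20.0}}
        tbl = compare.benchmark_table(est, self.BENCH)
        assert (tbl["dev_all"] == 0).all()

    def test_stage_order_preserved(self):
        est = {
            "all": {"v1": 12.0, "v2": 19.0},
            "no_fake": {"v1": 11.0, "v2": 19.5},
            "weighted": {"v1": 10.2, "v2": 20.1},
        }
        tbl = compare.benchmark_table(est, self.BENCH)
        assert list(tbl.columns[:3]) == ["all", "no_fake", "weighted"]
        assert tbl.loc["v1", "dev_weighted"] == pytest.approx(0.2)

    def test_missing_variable_rejected(self):
        with pytest.raises(KeyError):
            compare.benchmark_table({"all": {"v1": 1.0}}, self.BENCH)

    def test_weighting_reduces_demographic_deviation(self, codebook):
        from panelqc import weighting
        from panelqc.codebook import packaged_path

        cfg = PersonaConfig.from_yaml(
            packaged_path("personas_convenience.yaml"),
            n_respondents=4000, persona_mix={"attentive": 1.0},
            incomplete_frac=0.0, seed=77,
        )
        c = generate_cohort(cfg, codebook)
        targets = weighting.load_targets(packaged_path("targets_national.yaml"))
        wv = weighting.rake(c.demographics, targets, max_weight=30, tol=1e-8)
        for var, cats in targets.items():
            unw = weighting.weighted_proportions(c.demographics[var], np.ones(len(c.demographics)))
            wgt = weighting.weighted_proportions(c.demographics[var], wv.weights)
            dev_unw = sum(abs(unw.get(k, 0) - v) for k, v in cats.items())
            dev_w = sum(abs(wgt.get(k, 0) - v) for k, v in cats.items())
            assert dev_w <= dev_unw + 1e-9
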