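"""ANOVA, Pillai MANOVA, Tukey letters, and the contribution estimator."""

import itertools

import numpy as np
import pandas as pd
import pytest

from isofinger.isotope_io import ValidationError
from isofinger.simulate import SimulationConfig, simulate_study
from isofinger import isotope_io as iio
from isofinger.stats import (
    estimate_contribution,
    format_p,
    one_way_anova,
    pillai_manova,
    tukey_letter_display,
    turnover_corrected_offsets,
    two_way_anova,
)


def _balanced_2x2():
    """Cell means 0, 1 / 2, 3 with +-0.5 replicate deviations.

    Hand decomposition (computed before implementation): SS_A = 8, SS_B = 2,
    SS_AB = 0, SS_res = 2 on df (1, 1, 1, 4) -> F_A = 16, F_B = 4, F_AB = 0.
    """
    rows = []
    means = {("a1", "b1"): 0.0, ("a1", "b2"): 1.0, ("a2", "b1"): 2.0, ("a2", "b2"): 3.0}
    for (a, b), mu in means.items():
        rows += [(mu - 0.5, a, b), (mu + 0.5, a, b)]
    return pd.DataFrame(rows, columns=["y", "A", "B"])


class TestTwoWayAnova:
    def test_hand_computed_sums_of_squares(self):
        res = two_way_anova(_balanced_2x2(), "y", "A", "B")
        a, b, ab = res.term("A"), res.term("B"), res.term("A:B")
        assert (a.ss, b.ss, ab.ss, res.residual.ss) == pytest.approx((8, 2, 0, 2), abs=1e-10)
        assert (a.df, b.df, ab.df, res.residual.df) == (1, 1, 1, 4)
        assert a.f == pytest.approx(16.0, abs=1e-9)
        assert b.f == pytest.approx(4.0, abs=1e-9)
        assert ab.f == pytest.approx(0.0, abs=1e-9)

    def test_constant_response_flagged_degenerate(self):
        df = _balanced_2x2()
        df["y"] = 1.0
        res = two_way_anova(df, "y", "A", "B")
        assert res.term("A").degenerate and np.isnan(res.term("A").f)

    def test_balanced_decomposition_additivity_and_relabel_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "y": rng.normal(size=24),
            "A": np.repeat(["a1", "a2", "a3"], 8),
            "B": np.tile(np.repeat(["b1", "b2"], 4), 3),
        })
        res = two_way_anova(df, "y", "A", "B")
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        parts = sum(t.ss for t in res.terms) + res.residual.ss
        assert parts == pytest.approx(total, abs=1e-8)
        relabel = df.assign(A=df["A"].map({"a1": "zz", "a2": "mm", "a3": "aa"}))
        res2 = two_way_anova(relabel, "y", "A", "B")
        assert res2.term("A").f == pytest.approx(res.term("A").f, abs=1e-10)

    def test_empty_cell_rejected(self):
        df = _balanced_2x2()
        df = df[~((df["A"] == "a1") & (df["B"] == "b2"))]
        with pytest.raises(ValidationError, match="empty factor cell"):
            two_way_anova(df, "y", "A", "B")

    def test_unbalanced_type_ii_matches_statsmodels(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        sm_anova = pytest.importorskip("statsmodels.stats.anova")
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "A": rng.choice(["a1", "a2"], size=40, p=[0.3, 0.7]),
            "B": rng.choice(["b1", "b2", "b3"], size=40),
        })
        df["y"] = rng.normal(size=40) + (df["A"] == "a2") * 1.5
        res = two_way_anova(df, "y", "A", "B")
        assert res.ss_type == "II"
        lm = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        tab = sm_anova.anova_lm(lm, typ=2)
        assert res.term("A").ss == pytest.approx(tab.loc["C(A)", "sum_sq"], rel=1e-8)
        assert res.term("B").ss == pytest.approx(tab.loc["C(B)", "sum_sq"], rel=1e-8)
        assert res.term("A:B").ss == pytest.approx(tab.loc["C(A):C(B)", "sum_sq"], rel=1e-8)
        assert res.term("A").f == pytest.approx(tab.loc["C(A)", "F"], rel=1e-8)


class TestPillai:
    def test_identical_groups_null_identity(self):
        X = np.tile(np.arange(10.0)[:, None], (2, 2))
        labels = ["g1"] * 10 + ["g2"] * 10
        X = X + 0.0
        res = pillai_manova(X[:, :1], labels)
        assert res.pillai == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_single_response_equals_one_way_anova(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30)
        labels = np.repeat(["g1", "g2", "g3"], 10)
        y[labels == "g2"] += 1.0
        man = pillai_manova(y[:, None], labels)
        aov = one_way_anova(y, labels)
        ss_b, ss_w = aov.terms[0].ss, aov.residual.ss
        assert man.pillai == pytest.approx(ss_b / (ss_b + ss_w), abs=1e-10)
        assert man.f == pytest.approx(aov.terms[0].f, rel=1e-10)
        assert man.p == pytest.approx(aov.terms[0].p, rel=1e-8)

    def test_two_group_hotelling_t2_relation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(24, 2))
        labels = np.array(["g1"] * 12 + ["g2"] * 12)
        X[labels == "g2"] += [0.8, -0.4]
        n = len(labels)
        # independent T^2 oracle
        x1, x2 = X[labels == "g1"], X[labels == "g2"]
        d = x1.mean(axis=0) - x2.mean(axis=0)
        S = ((x1 - x1.mean(0)).T @ (x1 - x1.mean(0))
             + (x2 - x2.mean(0)).T @ (x2 - x2.mean(0))) / (n - 2)
        t2 = (12 * 12 / n) * d @ np.linalg.solve(S, d)
        res = pillai_manova(X, labels)
        assert res.pillai == pytest.approx(t2 / (t2 + n - 2), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariance_under_shared_linear_transform(self, seed):
        rng = np.random.default_rng(10 + seed)
        X = rng.normal(size=(30, 3))
        labels = np.repeat(["a", "b", "c"], 10)
        M = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3)
        r1 = pillai_manova(X, labels)
        r2 = pillai_manova(X @ M.T + b, labels)
        assert r2.pillai == pytest.approx(r1.pillai, abs=1e-9)
        assert r2.p == pytest.approx(r1.p, rel=1e-6)

    def test_matches_statsmodels_pillai(self):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        labels = np.repeat(["a", "b", "c"], 10)
        X[labels == "b"] += 0.7
        df = pd.DataFrame(X, columns=["y1", "y2", "y3"])
        df["g"] = labels
        mv = sm_manova.MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
        tab = mv.mv_test().results["g"]["stat"]
        res = pillai_manova(X, labels)
        assert res.pillai == pytest.approx(float(tab.loc["Pillai's trace", "Value"]), rel=1e-8)
        assert res.f == pytest.approx(float(tab.loc["Pillai's trace", "F Value"]), rel=1e-6)
        assert res.p == pytest.approx(float(tab.loc["Pillai's trace", "Pr > F"]), rel=1e-6, abs=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            pillai_manova(np.zeros((6, 6)), ["a", "a", "a", "b", "b", "b"])


class TestLetters:
    def test_full_separation_distinct_letters(self):
        disp = tukey_letter_display({"g1": 0.0, "g2": 10.0, "g3": 20.0},
                                    ms_resid=0.01, df_resid=12, n_per_group=5)
        assert list(disp.table["letters"]) == ["a", "b", "c"]
        assert list(disp.table["level"]) == ["g3", "g2", "g1"]  # descending means

    def test_no_separation_single_letter(self):
        disp = tukey_letter_display({"g1": 1.0, "g2": 1.0, "g3": 1.0},
                                    ms_resid=1.0, df_resid=12, n_per_group=5)
        assert set(disp.table["letters"]) == {"a"}

    def test_only_extremes_differ_gives_bridge_pattern(self):
        # crit = q(0.05, 3, 12) * sqrt(0.8/5) ~= 1.51: gaps of 1 non-sig, 2 sig
        disp = tukey_letter_display({"lo": 0.0, "mid": 1.0, "hi": 2.0},
                                    ms_resid=0.8, df_resid=12, n_per_group=5)
        letters = disp.letters()
        assert letters["hi"] == "a" and letters["mid"] == "ab" and letters["lo"] == "b"

    @pytest.mark.parametrize("seed", range(10))
    def test_sharing_iff_nonsignificant_biconditional(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(3, 7)
        means = {f"g{i}": float(rng.normal(0, 2)) for i in range(k)}
        ns = {f"g{i}": int(rng.integers(3, 8)) for i in range(k)}
        ms, df = float(rng.uniform(0.2, 2.0)), int(rng.integers(8, 30))
        disp = tukey_letter_display(means, ms, df, ns, alpha=0.05)
        letters = disp.letters()
        from scipy.stats import studentized_range

        q = studentized_range.ppf(0.95, k, df)
        for a, b in itertools.combinations(means, 2):
            se = np.sqrt(ms / 2 * (1 / ns[a] + 1 / ns[b]))
            significant = abs(means[a] - means[b]) > q * se
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares != significant, (a, b, letters)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            tukey_letter_display({"a": 0.0, "b": 1.0}, ms_resid=0.0, df_resid=5,
                                 n_per_group=3)


class TestContribution:
    def test_zero_offsets_give_zero_fraction(self):
        est = estimate_contribution([0.0] * 6, [5.0, 6, 7, 5, 8, 7], seed=0)
        assert est.f == 0.0

    def test_pure_source_gives_unit_fraction(self):
        m = [5.0, 6, 7, 5, 8, 7]
        est = estimate_contribution(m, m, seed=0)
        assert est.f == 1.0
        np.testing.assert_allclose(est.residuals, 0.0, atol=1e-12)

    def test_all_zero_microbe_offsets_unidentifiable(self):
        with pytest.raises(ValidationError):
            estimate_contribution([1.0, 2.0], [0.0, 0.0])

    def test_noiseless_study_recovers_f_exactly(self):
        cfg = SimulationConfig(noise_sd=0.0, f_microbial={"GF": 0.0, "CVZ": 0.35})
        study = simulate_study(cfg)
        m = study.measurements
        cons = iio.aggregate_replicates(m[m["group"].isin(["GF", "CVZ"])])
        diet = iio.aggregate_replicates(m[m["group"] == "DIET"])
        offsets = iio.diet_normalize(cons, diet)
        shift = {a: cfg.diet_old[a] - cfg.diet_new[a] for a in cfg.eaa_list}
        corrected = turnover_corrected_offsets(offsets, cfg.turnover, shift)
        means = corrected.groupby(["group", "analyte"])["offset"].mean()
        d = [means[("CVZ", a)] - means[("GF", a)] for a in cfg.eaa_list]
        mvec = [cfg.microbe_source[a] - cfg.diet_new[a] for a in cfg.eaa_list]
        est = estimate_contribution(d, mvec, seed=0)
        assert est.f == pytest.approx(0.35, abs=1e-9)

    def test_error_decreases_with_noise(self):
        errs = []
        for noise in (0.05, 0.4, 1.6):
            per_seed = []
            for seed in range(8):
                cfg = SimulationConfig(noise_sd=noise, seed=seed,
                                       f_microbial={"GF": 0.0, "CVZ": 0.4})
                study = simulate_study(cfg)
                m = study.measurements
                cons = iio.aggregate_replicates(m[m["group"].isin(["GF", "CVZ"])])
                diet = iio.aggregate_replicates(m[m["group"] == "DIET"])
                offsets = iio.diet_normalize(cons, diet)
                shift = {a: cfg.diet_old[a] - cfg.diet_new[a] for a in cfg.eaa_list}
                corrected = turnover_corrected_offsets(offsets, cfg.turnover, shift)
                means = corrected.groupby(["group", "analyte"])["offset"].mean()
                d = [means[("CVZ", a)] - means[("GF", a)] for a in cfg.eaa_list]
                mvec = [cfg.microbe_source[a] - cfg.diet_new[a] for a in cfg.eaa_list]
                per_seed.append(abs(estimate_contribution(d, mvec, n_bootstrap=0,
                                                          seed=0).f - 0.4))
            errs.append(np.mean(per_seed))
        assert errs[0] < errs[1] < errs[2]

    def test_bootstrap_interval_is_ordered_and_bounded(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(4, 9, size=6)
        d = 0.3 * m + rng.normal(0, 0.2, size=6)
        est = estimate_contribution(d, m, n_bootstrap=500, seed=1)
        assert 0.0 <= est.ci_low <= est.f <= est.ci_high <= 1.0


class TestHelpers:
    def test_turnover_correction_inverts_mixing(self):
        offsets = pd.DataFrame({
            "sample_id": ["m1", "m2"], "group": "GF",
            "organ": ["liver", "brain"], "analyte": "Val",
            "offset": [0.75 * 2.0 + 0.25 * 7.0, 0.30 * 2.0 + 0.70 * 7.0],
            "diet_reference_id": "d",
        })
        out = turnover_corrected_offsets(offsets, {"liver": 0.75, "brain": 0.30},
                                         {"Val": 7.0})
        np.testing.assert_allclose(out["offset"], 2.0, atol=1e-12)

    def test_format_p_style(self):
        assert format_p(5e-5) == "< 0.0001"
        assert format_p(0.0321) == "0.0321"
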