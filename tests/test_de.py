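import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from devmir.de import (
    adjust_bh,
    call_de,
    compare_de_sets,
    de_vs_reference,
    fit_moderated_t,
    paired_sex_contrast,
    sex_fold_change_counts,
    shrink_variances,
)
from devmir.simulate import SyntheticConfig, generate_dataset


# --- independent oracle for the variance-prior moment equations -----------

def oracle_prior(sample_var, residual_df):
    """Re-derivation of the log-variance moment matching, solving the
    trigamma equation by bracketed root finding instead of Newton."""
    z = np.log(sample_var)
    e = z - special.digamma(residual_df / 2) + np.log(residual_df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, residual_df / 2)
    if e_var > 0:
        x = optimize.brentq(lambda v: special.polygamma(1, v) - e_var, 1e-8, 1e12)
        d0 = 2.0 * x
        s0_sq = np.exp(e_mean + special.digamma(x) - np.log(x))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return d0, s0_sq


def oracle_moderated_t(a, b):
    n_a, n_b = a.shape[1], b.shape[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    d_g = n_a + n_b - 2
    s2 = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / d_g
    d0, s0_sq = oracle_prior(s2, d_g)
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq)
        df = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df = d0 + d_g
    t = lfc / np.sqrt(s_tilde_sq * (1 / n_a + 1 / n_b))
    return d0, s0_sq, t, df


class TestModeratedT:
    @pytest.fixture(scope="class")
    def class_matrix(self):
        import pandas as pd

        from devmir.io import ExpressionMatrix
        from devmir.simulate import _sample_sheet
        from devmir.stages import DEFAULT_STAGES

        rng = np.random.default_rng(123)
        sheet = _sample_sheet(DEFAULT_STAGES, 3, "s")
        scales = rng.uniform(0.2, 0.8, size=50)
        values = rng.normal(8.0, 1.0, size=(50, 36)) * 1.0
        values += rng.normal(0.0, scales[:, None], size=(50, 36))
        frame = pd.DataFrame(
            values, index=pd.Index([f"f{i}" for i in range(50)], name="feature_id"),
            columns=list(sheet["sample_id"]),
        )
        return ExpressionMatrix(frame, sheet, "gene")

    def test_d0_zero_recovers_classical_pooled_t(self, class_matrix):
        a = class_matrix.samples_for(stage="E10.5")
        b = class_matrix.samples_for(stage="young")
        res, _ = fit_moderated_t(class_matrix, a, b, prior_df=0)
        classical = stats.ttest_ind(
            class_matrix.values[a], class_matrix.values[b], axis=1
        ).statistic
        np.testing.assert_allclose(res["t_mod"], classical, atol=1e-10)

    def test_d0_infinite_uses_prior_variance(self, class_matrix):
        a = class_matrix.samples_for(stage="E10.5")
        b = class_matrix.samples_for(stage="young")
        res, mod = fit_moderated_t(class_matrix, a, b, prior_df=np.inf)
        lfc = res["log2FC"].to_numpy()
        expected = lfc / np.sqrt(mod.prior_var * (1 / 3 + 1 / 3))
        np.testing.assert_allclose(res["t_mod"], expected, rtol=1e-12)

    def test_matches_independent_oracle(self, class_matrix):
        a_ids = class_matrix.samples_for(stage="E10.5")
        b_ids = class_matrix.samples_for(stage="young")
        res, mod = fit_moderated_t(class_matrix, a_ids, b_ids)
        a = class_matrix.values[a_ids].to_numpy()
        b = class_matrix.values[b_ids].to_numpy()
        d0, s0_sq, t, _ = oracle_moderated_t(a, b)
        assert mod.prior_df == pytest.approx(d0, rel=1e-6)
        assert mod.prior_var == pytest.approx(s0_sq, rel=1e-9)
        np.testing.assert_allclose(res["t_mod"], t, rtol=1e-6)

    def test_shrunken_variance_between_extremes(self, class_matrix):
        a = class_matrix.samples_for(stage="E12.5")
        b = class_matrix.samples_for(stage="old")
        _, mod = fit_moderated_t(class_matrix, a, b)
        lo = np.minimum(mod.prior_var, mod.sample_var)
        hi = np.maximum(mod.prior_var, mod.sample_var)
        assert np.all(mod.shrunken_var >= lo - 1e-12)
        assert np.all(mod.shrunken_var <= hi + 1e-12)

    def test_group_overlap_rejected(self, class_matrix):
        a = class_matrix.samples_for(stage="E10.5")
        with pytest.raises(ValueError, match="overlap"):
            fit_moderated_t(class_matrix, a, a)

    def test_small_group_rejected(self, class_matrix):
        a = class_matrix.samples_for(stage="E10.5")
        b = class_matrix.samples_for(stage="young")
        with pytest.raises(ValueError, match="at least 2"):
            fit_moderated_t(class_matrix, a[:1], b)

    def test_swapping_groups_negates_statistics(self, class_matrix):
        a = class_matrix.samples_for(stage="E13.5")
        b = class_matrix.samples_for(stage="young")
        res_ab, _ = fit_moderated_t(class_matrix, a, b)
        res_ba, _ = fit_moderated_t(class_matrix, b, a)
        np.testing.assert_allclose(res_ab["log2FC"], -res_ba["log2FC"], atol=1e-12)
        np.testing.assert_allclose(res_ab["t_mod"], -res_ba["t_mod"], atol=1e-12)
        np.testing.assert_allclose(res_ab["p_raw"], res_ba["p_raw"], atol=1e-12)


def bh_oracle(p):
    """Literal step-up: adj_i = min over j with p_(j) >= p_(i) of m*p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [min(1.0, m * p[order[j]] / (j + 1)) for j in range(pos, m)]
        out[idx] = min(candidates)
    return out


class TestAdjustBH:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_value(self):
        np.testing.assert_allclose(adjust_bh([0.05]), [0.05])

    def test_tied_values(self):
        np.testing.assert_allclose(adjust_bh([0.2, 0.2]), [0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert np.all(adjust_bh(p) >= p)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20)
    )
    def test_agrees_with_oracle(self, p):
        np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)


class TestCallDE:
    @pytest.mark.parametrize(
        "p_adj, lfc, expected",
        [(1e-6, 2.5, True), (1e-6, -1.9, False), (2e-5, 3.0, False), (1e-5, 2.0, True)],
        ids=["de-up", "small-fold", "weak-p", "boundary-inclusive"],
    )
    def test_threshold_conjunction(self, p_adj, lfc, expected):
        frame = pd.DataFrame(
            {"feature_id": ["x"], "contrast": ["c"], "log2FC": [lfc],
             "t_mod": [0.0], "p_raw": [p_adj], "p_adj": [p_adj]}
        )
        assert bool(call_de(frame)["is_DE"].iloc[0]) is expected


class TestDeVsReference:
    def test_contrast_count(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(0).normal(8, 0.5, size=(30, 36)))
        res = de_vs_reference(matrix, "young")
        assert res["contrast"].nunique() == 11
        assert not res["contrast"].str.startswith("young_vs").any()

    def test_reference_excluded(self, make_matrix):
        matrix = make_matrix(np.random.default_rng(0).normal(8, 0.5, size=(30, 36)))
        res = de_vs_reference(matrix, "E19.5")
        assert "E19.5_vs_E19.5" not in set(res["contrast"])

    def test_unknown_reference(self, make_matrix):
        matrix = make_matrix(np.zeros((2, 36)) + 8)
        with pytest.raises(ValueError, match="reference"):
            de_vs_reference(matrix, "E99.5")

    def test_single_planted_change_is_only_call(self, make_matrix):
        rng = np.random.default_rng(5)
        values = np.full((40, 36), 8.0) + rng.normal(0, 0.05, size=(40, 36))
        # 16-fold (log2 = 4) change at E10.5 for feature f0
        values[0, :3] += 4.0
        matrix = make_matrix(values)
        res = de_vs_reference(matrix, "young")
        e105 = res[res["contrast"] == "E10.5_vs_young"]
        assert set(e105.loc[e105["is_DE"], "feature_id"]) == {"f0"}

    def test_null_type_one_error_calibrated(self, make_matrix):
        rng = np.random.default_rng(42)
        matrix = make_matrix(rng.normal(8.0, 0.5, size=(2000, 36)))
        res = de_vs_reference(matrix, "young")
        assert len(res) >= 20000
        frac = float((res["p_raw"] < 0.05).mean())
        assert 0.045 <= frac <= 0.055

    def test_planted_power(self):
        # every planted effect with true |lfc| >= 3 at noise 0.3 is called DE
        cfg = SyntheticConfig(
            n_genes=200, n_mirnas=20, n_planted_repressors=2, targets_per_repressor=2,
            decoy_interactions=10, noise_sd=0.3, amplitude=6.0, seed=8,
        )
        genes, _, _, _, truth = generate_dataset(cfg)
        res = de_vs_reference(genes, "young")
        lfc_range = res.groupby("feature_id")["log2FC"].apply(lambda s: s.abs().max())
        de_ids = set(res.loc[res["is_DE"], "feature_id"])
        strong = lfc_range[lfc_range >= 3.0].index
        assert len(strong) > 0
        missing = set(strong) - de_ids
        assert not missing


class TestPairedSexContrast:
    def test_identical_sexes_zero_effect(self, make_matrix):
        matrix = make_matrix(np.full((5, 36), 8.0))
        res = paired_sex_contrast(matrix)
        np.testing.assert_allclose(res["log2FC"], 0.0)

    def test_constant_shift_recovered(self, make_matrix):
        values = np.full((3, 36), 8.0)
        matrix = make_matrix(values)
        male_cols = [i for i, s in enumerate(matrix.samples["sex"]) if s == "M"]
        values[1, male_cols] += 1.5
        matrix = make_matrix(values)
        res = paired_sex_contrast(matrix)
        assert res.loc[res["feature_id"] == "f1", "log2FC"].iloc[0] == pytest.approx(1.5)

    def test_matches_classical_paired_t_with_d0_zero(self, make_matrix):
        rng = np.random.default_rng(31)
        matrix = make_matrix(rng.normal(8, 0.5, size=(25, 36)))
        res = paired_sex_contrast(matrix, prior_df=0)
        # classical paired t on stage-wise M-F differences
        kept = [s for s in matrix.stages_present() if s not in {"E10.5", "E11.5", "E12.5"}]
        diffs = np.column_stack(
            [
                matrix.values[matrix.samples_for(stage=s, sex="M")].mean(axis=1)
                - matrix.values[matrix.samples_for(stage=s, sex="F")].mean(axis=1)
                for s in kept
            ]
        )
        classical = stats.ttest_1samp(diffs, 0.0, axis=1)
        np.testing.assert_allclose(res["t_mod"], classical.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_raw"], classical.pvalue, atol=1e-10)

    def test_missing_sex_errors(self, make_matrix):
        matrix = make_matrix(np.full((2, 12), 8.0), n_reps=1)  # all replicate-1 => F only
        with pytest.raises(ValueError, match="E12.5|E13.5"):
            paired_sex_contrast(matrix)


class TestSexFoldChangeCounts:
    def test_all_zero(self, make_matrix):
        counts = sex_fold_change_counts(make_matrix(np.full((4, 36), 8.0)))
        assert counts["n_up_in_male"].sum() == 0
        assert counts["n_down_in_male"].sum() == 0

    def test_single_up_feature(self, make_matrix):
        values = np.full((3, 36), 8.0)
        matrix = make_matrix(values)
        male_e155 = [
            i for i, (s, x) in enumerate(zip(matrix.samples["stage"], matrix.samples["sex"]))
            if s == "E15.5" and x == "M"
        ]
        values[2, male_e155] += 1.5
        counts = sex_fold_change_counts(make_matrix(values))
        row = counts.set_index("stage").loc["E15.5"]
        assert (row["n_up_in_male"], row["n_down_in_male"]) == (1, 0)

    def test_strict_threshold(self, make_matrix):
        values = np.full((1, 36), 8.0)
        matrix = make_matrix(values)
        male = [
            i for i, (s, x) in enumerate(zip(matrix.samples["stage"], matrix.samples["sex"]))
            if s == "E15.5" and x == "M"
        ]
        values[0, male] += 1.0  # exactly the threshold: not counted
        counts = sex_fold_change_counts(make_matrix(values))
        assert counts.set_index("stage").loc["E15.5", "n_up_in_male"] == 0


class TestCompareDESets:
    def test_basic_set_algebra(self):
        out = compare_de_sets({"x", "y"}, {"y", "z"})
        assert out == {"common": {"y"}, "unique_to_a": {"x"}, "unique_to_b": {"z"}}

    def test_identity(self):
        out = compare_de_sets({"a", "b"}, {"a", "b"})
        assert out["unique_to_a"] == set() and out["unique_to_b"] == set()

    def test_disjoint(self):
        out = compare_de_sets({"a"}, {"b"})
        assert out["common"] == set()

    def test_per_contrast_maps_pooled(self):
        out = compare_de_sets({"c1": {"a", "b"}}, {"c1": {"b"}, "c2": {"c"}})
        assert out["common"] == {"b"}
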