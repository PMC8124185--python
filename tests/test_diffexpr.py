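"""Single-layer differential expression: filtering, normalisation,
moderated t, BH adjustment and threshold classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from duomics.diffexpr import (
    AnalysisThresholds,
    EmptyMatrixError,
    adjust_bh,
    classify_de,
    drop_incomplete_features,
    fit_variance_prior,
    log2_transform,
    median_normalize,
    moderated_ttest,
    signed_fold_change,
)

from conftest import make_matrix


class TestDropIncompleteFeatures:
    def test_complete_matrix_unchanged(self):
        m = make_matrix(np.arange(12.0).reshape(3, 4) + 1)
        out = drop_incomplete_features(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_single_missing_cell_drops_feature(self):
        vals = np.ones((3, 4))
        vals[1, 2] = np.nan
        out = drop_incomplete_features(make_matrix(vals))
        assert list(out.feature_ids) == ["f0000", "f0002"]

    def test_matches_row_scan_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.lognormal(3, 1, (1000, 8))
        mask = rng.random(vals.shape) < 0.10
        vals[mask] = np.nan
        out = drop_incomplete_features(make_matrix(vals))
        expected = sum(1 for row in vals if not any(np.isnan(v) for v in row))
        assert len(out.feature_ids) == expected

    def test_all_dropped_raises(self):
        vals = np.full((2, 4), np.nan)
        with pytest.raises(EmptyMatrixError):
            drop_incomplete_features(make_matrix(vals))


class TestLog2Transform:
    def test_known_values_and_roundtrip(self):
        m = make_matrix(np.array([[8.0, 1.0, 2.0, 0.5]]))
        out = log2_transform(m)
        assert out.values.iloc[0].tolist() == [3.0, 0.0, 1.0, -1.0]
        back = 2.0 ** out.values.to_numpy()
        np.testing.assert_allclose(back, m.values.to_numpy(), rtol=1e-12)

    def test_nonpositive_value_names_offender(self):
        vals = np.ones((2, 4))
        vals[1, 3] = -2.0
        with pytest.raises(ValueError, match="f0001"):
            log2_transform(make_matrix(vals))


class TestMedianNormalize:
    def test_hand_computed_shift(self):
        # columns [1,2,3] and [3,4,5]: grand median 3, column medians 2 and 4
        vals = np.array([[1.0, 3.0], [2.0, 4.0], [3.0, 5.0]])
        out = median_normalize(make_matrix(vals))
        np.testing.assert_allclose(out.values.iloc[:, 0], [2.0, 3.0, 4.0])
        np.testing.assert_allclose(out.values.iloc[:, 1], [2.0, 3.0, 4.0])

    def test_column_medians_equal_grand_median_and_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(5, 2, (41, 6)))
        grand = float(np.median(m.values.to_numpy()))
        out = median_normalize(m)
        np.testing.assert_allclose(out.values.median(axis=0), grand)
        again = median_normalize(out)
        pd.testing.assert_frame_equal(again.values, out.values)


class TestModeratedT:
    def _pooled_t_oracle(self, ctrl, trt):
        """Brute-force two-sample pooled-variance t per feature."""
        n1, n2 = ctrl.shape[1], trt.shape[1]
        out = []
        for a, b in zip(ctrl, trt):
            sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            sp2 /= n1 + n2 - 2
            out.append((b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))
        return np.array(out)

    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(8, 1, (50, 10))
        res = moderated_ttest(make_matrix(vals), d0=0)
        oracle = self._pooled_t_oracle(vals[:, :5], vals[:, 5:])
        np.testing.assert_allclose(res["t_mod"].to_numpy(), oracle, atol=1e-10)
        assert (res["df_total"] == 8).all()

    def test_d0_inf_equalizes_standard_errors(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(8, 1, (40, 8))
        # force two features to the same log2fc
        vals[1] = vals[0] + np.array([0, 0, 0, 0, 1, 1, 1, 1]) * 0.0
        vals[1, :4] = vals[0, :4] + 0.3
        vals[1, 4:] = vals[0, 4:] + 0.3
        res = moderated_ttest(make_matrix(vals), d0=np.inf)
        lfc = res["log2fc"].to_numpy()
        t = res["t_mod"].to_numpy()
        assert np.isclose(lfc[0], lfc[1])
        assert np.isclose(t[0], t[1])
        # all se equal => t proportional to log2fc
        np.testing.assert_allclose(t / lfc, t[0] / lfc[0], rtol=1e-9)

    def test_prior_recovery_and_null_uniformity(self):
        """Known scaled inv-chi-square prior (d0=4, s0^2=0.05): the
        moment-matching fit lands near truth and null p-values are uniform."""
        rng = np.random.default_rng(3)
        nfeat, n1 = 500, 5
        sigma2 = 4 * 0.05 / rng.chisquare(4, nfeat)
        vals = rng.normal(0, np.sqrt(sigma2)[:, None], (nfeat, 2 * n1))
        ctrl, trt = vals[:, :n1], vals[:, n1:]
        ss = ((ctrl - ctrl.mean(1, keepdims=True)) ** 2).sum(1) + (
            (trt - trt.mean(1, keepdims=True)) ** 2
        ).sum(1)
        d0_hat, s02_hat = fit_variance_prior(ss / (2 * n1 - 2), 2 * n1 - 2)
        assert 2 <= d0_hat <= 8
        assert 0.025 <= s02_hat <= 0.1
        res = moderated_ttest(make_matrix(vals))
        assert stats.kstest(res["p_value"], "uniform").pvalue > 0.01

    def test_few_features_warns_and_falls_back(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, (5, 8))
        with pytest.warns(UserWarning, match="fewer than 10"):
            res = moderated_ttest(make_matrix(vals))
        oracle = self._pooled_t_oracle(vals[:, :4], vals[:, 4:])
        np.testing.assert_allclose(res["t_mod"].to_numpy(), oracle, atol=1e-10)


class TestAdjustBH:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2]) == pytest.approx([0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bounds_and_sorted_monotonicity(self, p):
        q = adjust_bh(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_stepup_definition_oracle(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = adjust_bh(p)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            expected[i] = running
        np.testing.assert_allclose(q, expected, atol=1e-12)


class TestClassifyDE:
    @pytest.mark.parametrize(
        "signed_fc,fdr,expected",
        [
            (1.61, 0.04, "up"),     # just above the symmetric cut
            (1.59, 0.001, "ns"),    # below fc cut despite tiny fdr
            (-2.0, 0.2, "ns"),      # fails fdr cut
            (-1.6, 0.05, "down"),   # boundary inclusive on both cuts
        ],
    )
    def test_threshold_rule(self, signed_fc, fdr, expected):
        log2fc = np.log2(signed_fc) if signed_fc > 0 else -np.log2(-signed_fc)
        df = pd.DataFrame({"log2fc": [log2fc], "p_value": [fdr], "fdr": [fdr]}, index=["g"])
        out = classify_de(df, AnalysisThresholds())
        assert out["status"].iloc[0] == expected
        assert out["signed_fc"].iloc[0] == pytest.approx(signed_fc)

    def test_statuses_partition_features(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 300), "p_value": rng.random(300)},
            index=[f"g{i}" for i in range(300)],
        )
        out = classify_de(df)
        counts = out["status"].value_counts()
        assert counts.sum() == 300

    @settings(deadline=None, max_examples=100)
    @given(st.floats(-10, 10))
    def test_signed_fc_invariant(self, log2fc):
        sfc = float(signed_fold_change([log2fc])[0])
        assert abs(sfc) >= 1
        if log2fc >= 0:
            assert sfc == pytest.approx(2.0 ** log2fc)
        else:
            assert sfc == pytest.approx(-(2.0 ** -log2fc))


class TestLimmaCrossCheck:
    def test_moderated_t_matches_limma(self, tmp_path):
        """Independent oracle: the empirical-Bayes moderated t and its
        p-values agree with R limma's eBayes on the same matrix."""
        import subprocess

        rng = np.random.default_rng(33)
        sigma2 = 4 * 0.05 / rng.chisquare(4, 200)
        vals = rng.normal(0, np.sqrt(sigma2)[:, None], (200, 10))
        vals[:20] += np.array([0] * 5 + [1] * 5) * 0.5  # some real effects
        np.savetxt(tmp_path / "mat.tsv", vals, delimiter="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.table("{tmp_path}/mat.tsv", sep="\\t"))\n'
            "fit <- eBayes(lmFit(x, cbind(1, rep(0:1, each=5))))\n"
            f'write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2]), "{tmp_path}/out.tsv",'
            " sep=\"\\t\", row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = moderated_ttest(make_matrix(vals))
        np.testing.assert_allclose(res["t_mod"].to_numpy(), ref["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(res["p_value"].to_numpy(), ref["p"].to_numpy(), atol=1e-10)


class TestFDRControl:
    def test_null_simulation_controls_fdr(self):
        """With no planted effects the fraction of features at fdr<=0.05
        stays within Monte-Carlo error of the nominal level."""
        hits, total = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            vals = 2.0 ** rng.normal(8, 1, (1000, 10))
            res = moderated_ttest(log2_transform(make_matrix(vals)))
            fdr = adjust_bh(res["p_value"].to_numpy())
            hits += int((fdr <= 0.05).sum())
            total += 1000
        se = np.sqrt(0.05 * 0.95 / total)
        assert hits / total <= 0.05 + 3 * se
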