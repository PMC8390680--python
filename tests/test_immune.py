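"""ssGSEA, CYT, deconvolution, cell-score dynamics."""

import numpy as np
import pandas as pd
import pytest

from icbstrat.immune import (SSGSEA_ALPHA, cell_score_log2fc, cytolytic_score,
                             deconvolve, ssgsea_sample, ssgsea_score,
                             tertile_high_split)


def ssgsea_oracle(values, member_mask, alpha=SSGSEA_ALPHA):
    """Hand-stepped per-position ECDF summation, independent of the
    vectorised implementation."""
    n = len(values)
    order = sorted(range(n), key=lambda i: -values[i])
    k = sum(member_mask)
    total_w = sum(
        (n - pos) ** alpha for pos, i in enumerate(order) if member_mask[i]
    )
    score, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        if member_mask[i]:
            cum_in += (n - pos) ** alpha / total_w
        else:
            cum_out += 1.0 / (n - k)
        score += cum_in - cum_out
    return score


class TestSsgsea:
    def toy_matrix(self):
        genes = ["g1", "g2", "g3", "g4", "g5", "g6"]
        return pd.DataFrame(
            {"s1": [10.0, 9.0, 1.0, 2.0, 3.0, 4.0],
             "s2": [1.0, 2.0, 10.0, 9.0, 8.0, 7.0]},
            index=genes,
        )

    def test_ordering(self):
        expr = self.toy_matrix()
        scores = ssgsea_score(expr, ["g1", "g2"], normalize=False)
        assert scores["s1"] > scores["s2"]

    def test_hand_stepped_oracle(self):
        expr = self.toy_matrix()
        mask = expr.index.isin(["g1", "g2"])
        for col in expr.columns:
            vals = expr[col].to_numpy()
            assert ssgsea_sample(vals, mask) == pytest.approx(
                ssgsea_oracle(list(vals), list(mask))
            )

    def test_rank_invariance_under_monotone_transform(self):
        expr = self.toy_matrix()
        mask = expr.index.isin(["g1", "g5"])
        raw = ssgsea_sample(expr["s1"].to_numpy(), mask)
        squashed = ssgsea_sample(np.log1p(expr["s1"].to_numpy()) ** 3, mask)
        assert raw == pytest.approx(squashed)

    def test_normalization_divides_by_range(self):
        expr = self.toy_matrix()
        raw = ssgsea_score(expr, ["g1", "g2"], normalize=False)
        norm = ssgsea_score(expr, ["g1", "g2"], normalize=True)
        rng = raw.max() - raw.min()
        np.testing.assert_allclose(norm, raw / rng)

    def test_empty_intersection_warns_nan(self):
        with pytest.warns(UserWarning):
            scores = ssgsea_score(self.toy_matrix(), ["nope"])
        assert scores.isna().all()

    def test_full_universe_rejected(self):
        expr = self.toy_matrix()
        with pytest.raises(ValueError):
            ssgsea_score(expr, list(expr.index))


class TestCyt:
    def matrix(self, gzma, prf1):
        return pd.DataFrame({"s": [gzma, prf1, 5.0]},
                            index=["GZMA", "PRF1", "other"])

    def test_geometric_mean(self):
        assert cytolytic_score(self.matrix(4, 16), offset=0)["s"] == \
            pytest.approx(8.0)

    def test_zero_expression_gives_offset(self):
        assert cytolytic_score(self.matrix(0, 0), offset=0.01)["s"] == \
            pytest.approx(0.01)

    def test_default_offset_formula(self):
        assert cytolytic_score(self.matrix(4, 16))["s"] == pytest.approx(
            np.sqrt(4.01 * 16.01)
        )

    def test_missing_gene_is_nan(self):
        m = pd.DataFrame({"s": [1.0]}, index=["GZMA"])
        with pytest.warns(UserWarning):
            assert cytolytic_score(m).isna().all()


class TestDeconvolve:
    def reference(self):
        rng = np.random.default_rng(0)
        R = rng.uniform(0.1, 1, size=(60, 3))
        R[:20, 0] += 10
        R[20:40, 1] += 10
        R[40:, 2] += 10
        return pd.DataFrame(R, index=[f"g{i}" for i in range(60)],
                            columns=["A", "B", "C"])

    def test_pure_column_recovered(self):
        ref = self.reference()
        expr = pd.DataFrame({"s": ref["B"]})
        fracs, absolute = deconvolve(expr, ref)
        np.testing.assert_allclose(fracs["s"], [0, 1, 0], atol=1e-8)
        assert (absolute.to_numpy() >= 0).all()

    def test_fifty_fifty_mixture(self):
        ref = self.reference()
        expr = pd.DataFrame({"s": 0.5 * ref["A"] + 0.5 * ref["C"]})
        fracs, _ = deconvolve(expr, ref)
        np.testing.assert_allclose(fracs["s"], [0.5, 0, 0.5], atol=1e-6)

    def test_fractions_on_simplex(self):
        ref = self.reference()
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.uniform(0, 5, size=(60, 4)), index=ref.index,
            columns=list("wxyz"))
        fracs, _ = deconvolve(expr, ref)
        np.testing.assert_allclose(fracs.sum(axis=0), 1.0, atol=1e-9)

    def test_insufficient_overlap_rejected(self):
        ref = self.reference()
        expr = pd.DataFrame({"s": [1.0] * 10}, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="reference genes"):
            deconvolve(expr, ref)

    def test_noisy_recovery_vs_ground_truth(self):
        """Pearson r(true, estimated) > 0.95 per cell type at noise_sd 0.1."""
        ref = self.reference()
        rng = np.random.default_rng(5)
        true = rng.dirichlet(np.ones(3), size=40).T  # 3 x 40
        mix = ref.to_numpy() @ true
        mix = mix * np.exp(rng.normal(0, 0.1, size=mix.shape))
        expr = pd.DataFrame(mix, index=ref.index,
                            columns=[f"s{i}" for i in range(40)])
        fracs, _ = deconvolve(expr, ref)
        for t in range(3):
            r = np.corrcoef(true[t], fracs.to_numpy()[t])[0, 1]
            assert r > 0.95


class TestCellScoreFc:
    def setup_frames(self):
        scores = pd.DataFrame(
            {"p1_B": [2.0, 4.0], "p1_C3": [8.0, 4.0],
             "p2_B": [6.0, 4.0], "p3_C3": [8.0, 1.0]},
            index=["tcell", "bcell"],
        )
        meta = pd.DataFrame(
            [("p1_B", "p1", "baseline"), ("p1_C3", "p1", "on_treatment"),
             ("p2_B", "p2", "baseline"), ("p3_C3", "p3", "on_treatment")],
            columns=["sample_id", "patient_id", "timepoint"],
        )
        return scores, meta

    def test_paired_change(self):
        scores, meta = self.setup_frames()
        fc = cell_score_log2fc(scores, meta, eps=0)
        assert fc.loc["p1", "tcell"] == pytest.approx(2.0)
        assert fc.loc["p1", "bcell"] == pytest.approx(0.0)

    def test_median_baseline_fallback(self):
        scores, meta = self.setup_frames()
        fc = cell_score_log2fc(scores, meta, eps=0)
        # baseline tcell median over p1_B, p2_B = 4; on = 8 -> +1
        assert fc.loc["p3", "tcell"] == pytest.approx(1.0)

    def test_eps_insensitivity_for_large_scores(self):
        scores, meta = self.setup_frames()
        a = cell_score_log2fc(scores, meta, eps=1e-3)
        b = cell_score_log2fc(scores, meta, eps=5e-4)
        assert (a - b).abs().to_numpy().max() < 1e-3

    def test_no_baseline_anywhere_errors(self):
        scores, meta = self.setup_frames()
        meta_on = meta[meta["timepoint"] == "on_treatment"]
        with pytest.raises(ValueError):
            cell_score_log2fc(scores[["p1_C3", "p3_C3"]], meta_on)


class TestTertileSplit:
    def test_small_example(self):
        labels = tertile_high_split(pd.Series([1.0, 2.0, 3.0]))
        assert list(labels) == [False, False, True]

    def test_all_equal_none_high(self):
        assert not tertile_high_split(pd.Series([2.0] * 5)).any()

    def test_matches_percentile_oracle(self):
        v = pd.Series(np.arange(1.0, 10.0))
        cut = np.percentile(v, 200 / 3)
        assert list(v[tertile_high_split(v)]) == list(v[v > cut])


def test_immune_shift_recovered_on_synthetic(default_cohort):
    """HS baselines score higher on IM/IFNG than LS baselines, and the two
    scores correlate positively (Spearman), mirroring the planted shift."""
    from scipy.stats import spearmanr

    from icbstrat.synthetic import immune_gene_sets

    c = default_cohort
    log_tpm = np.log2(c.expression_tpm + 1)
    sets = immune_gene_sets(c.reference, c.config.n_celltypes)
    meta = c.sample_meta.set_index("sample_id")
    base = meta.index[meta["timepoint"] == "baseline"]
    im = ssgsea_score(log_tpm[base], sets["IM"])
    ifng = ssgsea_score(log_tpm[base], sets["IFNG"])
    groups = meta.loc[base, "patient_id"].map(c.truth.groups)
    assert im[groups == "HS"].mean() > im[groups == "LS"].mean()
    assert ifng[groups == "HS"].mean() > ifng[groups == "LS"].mean()
    rho = spearmanr(im, ifng).statistic
    assert rho > 0
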