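"""TMB, PGA, copy-number status calls, catalogs, signature fitting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_mutations
from icbstrat.genomics import (CopyNumberSegment, SignatureExposure,
                               call_segment_status,
                               catalog_alteration_frequencies, classify_pga,
                               classify_tmb, compute_pga, compute_tmb,
                               filter_by_cellularity, fit_signatures,
                               gene_copy_status, tertile_threshold)


def muts_frame(n_nonsyn=0, n_silent=0, n_germline=0):
    rows = (
        [("s", "G", "missense", "somatic")] * n_nonsyn
        + [("s", "G", "silent", "somatic")] * n_silent
        + [("s", "G", "missense", "germline_pathogenic")] * n_germline
    )
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "variant_classification", "origin"]
    )


class TestTmb:
    @pytest.mark.parametrize(
        "n_nonsyn, n_silent, mb, expected",
        [(100, 0, 50.0, 2.0), (0, 0, 30.0, 0.0), (30, 10, 30.0, 1.0)],
    )
    def test_values(self, n_nonsyn, n_silent, mb, expected):
        assert compute_tmb(muts_frame(n_nonsyn, n_silent), mb) == expected

    def test_germline_excluded(self):
        assert compute_tmb(muts_frame(10, 0, n_germline=5), 10.0) == 1.0

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            compute_tmb(muts_frame(1), 0.0)

    def test_additive_and_inverse_scaling(self, rng):
        a, b = muts_frame(int(rng.integers(1, 50))), muts_frame(int(rng.integers(1, 50)))
        both = pd.concat([a, b], ignore_index=True)
        mb = 25.0
        assert compute_tmb(both, mb) == pytest.approx(
            compute_tmb(a, mb) + compute_tmb(b, mb)
        )
        assert compute_tmb(a, 2 * mb) == pytest.approx(compute_tmb(a, mb) / 2)

    @pytest.mark.parametrize(
        "tmb, expected", [(10.0, "TMB-high"), (9.99, "TMB-low"), (0, "TMB-low")]
    )
    def test_classify(self, tmb, expected):
        assert classify_tmb(tmb) == expected


def seg(chrom, start, end, cn_total, cn_minor=None, sid="s"):
    if cn_minor is None:
        cn_minor = min(1, cn_total)
    return CopyNumberSegment(sid, chrom, start, end, cn_total, cn_minor)


class TestPga:
    def test_simple_fractions(self):
        segs = [seg("chr1", 1, 300_000_000, 3),
                seg("chr2", 1, 2_700_000_000, 2)]
        assert compute_pga(segs) == pytest.approx(10.0)
        assert compute_pga([seg("chr1", 1, 100, 2)]) == 0.0

    def test_no_segments_is_nan(self):
        assert np.isnan(compute_pga([]))

    def test_matches_bruteforce_base_count(self, rng):
        """Interval-arithmetic oracle: count altered bases directly."""
        segs = []
        pos = 1
        for _ in range(20):
            length = int(rng.integers(10, 5000))
            cn = int(rng.integers(0, 5))
            segs.append(seg("chr1", pos, pos + length - 1, cn, min(1, cn)))
            pos += length
        total = sum(s.end - s.start + 1 for s in segs)
        altered = sum(s.end - s.start + 1 for s in segs if s.cn_total != 2)
        assert compute_pga(segs) == pytest.approx(100 * altered / total)

    def test_invariant_to_segment_splitting(self):
        whole = [seg("chr1", 1, 1000, 3), seg("chr1", 1001, 4000, 2)]
        split = [seg("chr1", 1, 500, 3), seg("chr1", 501, 1000, 3),
                 seg("chr1", 1001, 4000, 2)]
        assert compute_pga(whole) == pytest.approx(compute_pga(split))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            compute_pga([seg("chr1", 1, 100, 2), seg("chr1", 50, 200, 3)])

    def test_bounds(self, rng):
        segs = [seg("chr1", i * 100 + 1, (i + 1) * 100, int(rng.integers(0, 6)))
                for i in range(30)]
        assert 0.0 <= compute_pga(segs) <= 100.0


class TestSegmentStatus:
    @pytest.mark.parametrize(
        "cn, ploidy, expected",
        [
            (1, 2, ["LOH", "single_copy_loss"]),
            (5, 2, ["gain"]),
            (4, 2, ["neutral"]),  # 4 is not > ploidy+2
            (0, 2, ["homozygous_loss"]),
            (6, 4, ["neutral"]),
            (7, 4, ["gain"]),
        ],
    )
    def test_rules(self, cn, ploidy, expected):
        assert call_segment_status(seg("chr1", 1, 10, cn, 0), ploidy) == expected


class TestGeneStatus:
    B2M = ("chr15", 45_000_001, 45_010_000)

    def test_inside_loh_segment(self):
        segs = [seg("chr15", 44_000_000, 46_000_000, 1, 0)]
        assert "LOH" in gene_copy_status(*self.B2M, segs, 2.0)

    def test_any_overlap_rule(self):
        segs = [seg("chr15", 44_000_000, 45_005_000, 1, 0),
                seg("chr15", 45_005_001, 46_000_000, 2)]
        assert "LOH" in gene_copy_status(*self.B2M, segs, 2.0)

    def test_majority_base_rule(self):
        # LOH segment covers <50% of the gene; majority rule says neutral
        segs = [seg("chr15", 44_000_000, 45_003_000, 1, 0),
                seg("chr15", 45_003_001, 46_000_000, 2)]
        assert gene_copy_status(*self.B2M, segs, 2.0, rule="majority_base") == [
            "neutral"
        ]

    def test_uncovered_gene_is_missing(self):
        assert gene_copy_status(*self.B2M, [seg("chr1", 1, 100, 1, 0)], 2.0) is None


class TestCatalog:
    def test_printed_count_fixtures(self):
        samples = [f"s{i}" for i in range(72)]
        muts = make_mutations({"TP53": samples[:35], "BRCA2": samples[30:39]})
        per_gene, any_frac = catalog_alteration_frequencies(
            muts, ["TP53", "BRCA2"], samples
        )
        freq = dict(zip(per_gene["gene"], per_gene["frequency"]))
        assert round(100 * freq["TP53"], 1) == 48.6
        assert round(100 * freq["BRCA2"], 1) == 12.5

    def test_any_gene_union(self):
        samples = [f"s{i}" for i in range(72)]
        muts = make_mutations({"A": samples[:30], "B": samples[25:49]})
        _, any_frac = catalog_alteration_frequencies(muts, ["A", "B"], samples)
        assert any_frac == pytest.approx(49 / 72)

    def test_empty_catalog(self):
        per_gene, any_frac = catalog_alteration_frequencies(
            make_mutations({"A": ["s1"]}), [], ["s1"]
        )
        assert len(per_gene) == 0 and any_frac == 0.0

    def test_silent_records_do_not_count(self):
        muts = pd.DataFrame(
            [("s1", "A", "silent", "somatic")],
            columns=["sample_id", "gene", "variant_classification", "origin"],
        )
        per_gene, _ = catalog_alteration_frequencies(muts, ["A"], ["s1", "s2"])
        assert per_gene.loc[0, "n_altered"] == 0


class TestSignatures:
    def _signatures(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(0, 1, size=(96, 3))
        return M / M.sum(axis=0)

    def test_exact_two_signature_mixture(self):
        M = self._signatures()
        counts = 1000 * (0.7 * M[:, 0] + 0.3 * M[:, 1])
        exp = fit_signatures(counts, M)
        np.testing.assert_allclose(exp.normalized, [0.7, 0.3, 0.0], atol=1e-8)
        assert exp.residual < 1e-8

    def test_single_signature(self):
        M = self._signatures()
        exp = fit_signatures(5.0 * M[:, 2], M)
        np.testing.assert_allclose(exp.weights, [0.0, 0.0, 5.0], atol=1e-8)

    def test_nnls_beats_grid(self):
        """Oracle: no grid-enumerated non-negative weight pair fits better."""
        M = self._signatures()[:, :2]
        rng = np.random.default_rng(1)
        counts = 100 * (0.4 * M[:, 0] + 0.6 * M[:, 1]) + rng.uniform(0, 0.5, 96)
        exp = fit_signatures(counts, M)
        grid = np.arange(0, 150.01, 1.5)
        best = min(
            np.linalg.norm(counts - M @ np.array([a, b]))
            for a, b in itertools.product(grid, grid)
        )
        assert exp.residual <= best + 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fit_signatures(-np.ones(96), self._signatures())

    def test_zero_counts_warn(self):
        with pytest.warns(UserWarning):
            exp = fit_signatures(np.zeros(96), self._signatures())
        assert isinstance(exp, SignatureExposure)
        assert not exp.weights.any()


def test_cellularity_filter():
    purity = pd.DataFrame(
        {"sample_id": ["a", "b", "c"], "cellularity": [0.19, 0.20, 0.9],
         "ploidy": [2.0, 2.0, 3.1]}
    )
    kept = filter_by_cellularity(purity)
    assert list(kept["sample_id"]) == ["b", "c"]


def test_tertile_and_pga_class():
    v = np.arange(1.0, 10.0)  # 1..9
    cut = tertile_threshold(v)
    assert set(v[v > cut]) == {7.0, 8.0, 9.0}
    labels = classify_pga(pd.Series(v))
    assert (labels == "PGA-high").sum() == 3
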