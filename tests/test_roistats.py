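"""ROI statistics: erosion, thresholding, Welch tests, RFT correction."""

import numpy as np
import pytest
from scipy import stats

from braintensor import (
    ROIAtlas,
    erode_mask,
    rft_correct,
    roi_values,
    roi_vs_region_ttest,
    summarize_rois,
    threshold_probability_map,
)
from braintensor.roistats import _welch_df


@pytest.fixture()
def nested_atlas():
    """A big region containing a small nucleus, plus an outside ROI."""
    labels = np.zeros((8, 8, 8), dtype=int)
    labels[1:7, 1:7, 1:7] = 1  # region
    labels[3:5, 3:5, 3:5] = 2  # nucleus inside it
    labels[0, 0, 0] = 3
    return ROIAtlas(labels=labels, names={1: "region", 2: "nucleus", 3: "spot"})


class TestErodeMask:
    def test_cube_erosion_matches_set_logic(self):
        """Eroding a solid 5^3 cube with a radius-1 ball leaves the 3^3 core."""
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True
        eroded = erode_mask(mask, 1.0, voxel_size=(1, 1, 1))
        # brute force: voxel survives iff all ball offsets stay inside
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1),
                   (0, 0, -1), (0, 0, 0)]
        expected = np.zeros_like(mask)
        for i in range(7):
            for j in range(7):
                for k in range(7):
                    expected[i, j, k] = all(
                        0 <= i + a < 7 and 0 <= j + b < 7 and 0 <= k + c < 7
                        and mask[i + a, j + b, k + c]
                        for a, b, c in offsets
                    )
        np.testing.assert_array_equal(eroded, expected)
        assert eroded.sum() == 27

    def test_radius_zero_identity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 2, 3] = True
        np.testing.assert_array_equal(erode_mask(mask, 0.0), mask)

    def test_single_voxel_erodes_to_empty_with_warning(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.warns(UserWarning, match="empty"):
            out = erode_mask(mask, 1.0, voxel_size=(1, 1, 1))
        assert not out.any()

    def test_touching_masks_separate_after_erosion(self):
        """Two touching slabs eroded by one voxel end >= 2 voxels apart."""
        a = np.zeros((10, 4, 4), dtype=bool)
        b = np.zeros((10, 4, 4), dtype=bool)
        a[:5] = True
        b[5:] = True
        ea = erode_mask(a, 1.0, voxel_size=(1, 1, 1))
        eb = erode_mask(b, 1.0, voxel_size=(1, 1, 1))
        assert not (ea & eb).any()
        gap = np.flatnonzero(eb.any(axis=(1, 2)))[0] - np.flatnonzero(
            ea.any(axis=(1, 2))
        )[-1]
        assert gap >= 2


class TestThresholdProbabilityMap:
    def test_uniform_map_fully_retained(self):
        mask, _ = threshold_probability_map(np.full((3, 3, 3), 0.5), 0.03)
        assert mask.all()

    def test_counts_and_percentile_by_hand(self):
        vals = np.round(np.arange(0.01, 0.11, 0.01), 2)
        prob = np.zeros((10, 1, 1))
        prob[:, 0, 0] = vals
        mask, pct = threshold_probability_map(prob, 0.03)
        assert mask.sum() == 7
        assert pct == pytest.approx(30.0)

    def test_threshold_one_empty(self):
        mask, _ = threshold_probability_map(np.full((2, 2, 2), 0.4), 1.0)
        assert not mask.any()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            threshold_probability_map(np.zeros((2, 2, 2)), 0.1)


class TestRoiValues:
    def test_returns_labeled_values(self, nested_atlas):
        vol = np.zeros((8, 8, 8))
        vol[nested_atlas.mask("nucleus")] = 7.0
        vals = roi_values(vol, nested_atlas, "nucleus")
        assert vals.size == 8 and (vals == 7.0).all()

    def test_outside_support_rejected(self, nested_atlas):
        vol = np.full((8, 8, 8), np.nan)
        with pytest.raises(ValueError, match="support"):
            roi_values(vol, nested_atlas, "spot")

    def test_partition_accounting(self, nested_atlas, rng):
        vol = rng.standard_normal((8, 8, 8))
        total = sum(
            roi_values(vol, nested_atlas, name).size
            for name in ("region", "nucleus", "spot")
        )
        assert total + (nested_atlas.labels == 0).sum() == 8**3


class TestWelchTTest:
    def test_degenerate_roi_matches_textbook_formula(self, nested_atlas):
        """ROI (2,2,2) vs region (2,2,2,0,0,0): compare against the Welch
        statistic coded directly from the formula."""
        a = np.array([2.0, 2.0, 2.0])
        b = np.array([2.0, 2.0, 2.0, 0.0, 0.0, 0.0])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (
            va**2 / (a.size - 1) + vb**2 / (b.size - 1)
        )
        p_hand = stats.t.sf(t_hand, df_hand)
        res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.pvalue == pytest.approx(p_hand, abs=1e-10)
        assert _welch_df(a, b) == pytest.approx(df_hand, abs=1e-10)

    def test_identical_distributions_symmetric_null(self, nested_atlas):
        # alternate 0/1 in both samples: equal means -> t = 0, p = 0.5
        vol = np.zeros((8, 8, 8))
        for name in ("nucleus", "region"):
            m = nested_atlas.mask(name)
            vals = np.zeros(m.sum())
            vals[::2] = 1.0
            vol[m] = vals
        t, p = roi_vs_region_ttest(vol, nested_atlas, "nucleus", "region")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    def test_roi_excluded_variant_changes_region_sample(self, nested_atlas, rng):
        vol = rng.standard_normal((8, 8, 8))
        t_inc, _ = roi_vs_region_ttest(vol, nested_atlas, "nucleus", "region")
        t_exc, _ = roi_vs_region_ttest(
            vol, nested_atlas, "nucleus", "region", include_roi=False
        )
        assert t_inc != t_exc

    def test_null_calibration_monte_carlo(self):
        """One-sided Welch rejection rate at alpha=0.05 under the null is
        0.05 +/- 0.01 over 10^4 replicates."""
        rng = np.random.default_rng(1234)
        n_rep = 10_000
        a = rng.standard_normal((n_rep, 10))
        b = rng.standard_normal((n_rep, 40))
        res = stats.ttest_ind(a, b, axis=1, equal_var=False, alternative="greater")
        rate = np.mean(res.pvalue < 0.05)
        assert abs(rate - 0.05) < 0.01


class TestRFTCorrection:
    def test_zero_resel_limit_recovers_raw_p(self):
        t, df = 3.0, 20.0
        p_raw = float(stats.t.sf(t, df))
        p_small = rft_correct(p_raw, t, df, roi_volume_mm3=1e-9, fwhm_mm=2.0)
        assert p_small == pytest.approx(p_raw, rel=1e-6)

    def test_monotone_in_resels(self):
        t, df = 3.5, 30.0
        p_raw = float(stats.t.sf(t, df))
        vols = [10.0, 20.0, 40.0, 80.0]
        ps = [rft_correct(p_raw, t, df, v, 2.0) for v in vols]
        assert all(p2 >= p1 for p1, p2 in zip(ps, ps[1:]))

    def test_never_below_raw_even_for_small_t(self):
        # the 3-D EC density is negative for small t; the clamp keeps
        # p_corrected >= p_raw
        t, df = 0.5, 10.0
        p_raw = float(stats.t.sf(t, df))
        assert rft_correct(p_raw, t, df, 1000.0, 2.0) >= p_raw

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rft_correct(0.01, 3.0, 0.0, 10.0, 2.0)
        with pytest.raises(ValueError):
            rft_correct(0.01, 3.0, 10.0, 10.0, 0.0)


class TestSummarizeRois:
    def test_elevated_nucleus_flagged_significant(self, nested_atlas, rng):
        vol = rng.standard_normal((8, 8, 8)) * 0.1
        vol[nested_atlas.mask("nucleus")] += 2.0
        table = summarize_rois(
            vol, nested_atlas, [("nucleus", "region")], fwhm_mm=2.0
        )
        row = table.row("nucleus")
        assert row["significant_at_0.05"]
        assert row["p_corrected"] >= row["p_raw"]

    def test_all_zero_map_nothing_significant(self, nested_atlas, rng):
        vol = rng.standard_normal((8, 8, 8)) * 1e-3
        table = summarize_rois(vol, nested_atlas, [("nucleus", "region")])
        assert not table.row("nucleus")["significant_at_0.05"]

    def test_row_count_matches_pairs_and_na_rows_kept(self, nested_atlas):
        vol = np.full((8, 8, 8), np.nan)
        vol[nested_atlas.mask("nucleus")] = 1.0
        vol[nested_atlas.mask("region")] = 0.5
        # "spot" lies outside the support -> NA row, table still emitted
        table = summarize_rois(
            vol, nested_atlas, [("nucleus", "region"), ("spot", "region")]
        )
        assert len(table.table) == 2
        assert np.isnan(table.row("spot")["t_statistic"])

    def test_unknown_roi_aborts(self, nested_atlas):
        with pytest.raises(KeyError, match="bogus"):
            summarize_rois(np.zeros((8, 8, 8)), nested_atlas, [("bogus", "region")])
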