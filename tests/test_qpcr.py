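"""CT preprocessing: standard curves, linearization, normalization, concordance."""

import numpy as np
import pandas as pd
import pytest

from breastmarker import qpcr
from breastmarker import synthetic as syn


class TestStandardCurve:
    DILUTIONS = [1, 1 / 3, 1 / 9, 1 / 27, 1 / 81]

    def test_perfect_doubling_series_gives_efficiency_two(self):
        # a 3-fold dilution step at efficiency 2 raises CT by log2(3) = 1.585
        cts = [20, 21.585, 23.170, 24.755, 26.340]
        curve = qpcr.fit_standard_curve(zip(self.DILUTIONS, cts))
        assert curve.efficiency == pytest.approx(2.0, abs=1e-3)
        assert curve.slope < 0

    def test_flat_series_rejected(self):
        with pytest.raises(ValueError):
            qpcr.fit_standard_curve([(d, 25.0) for d in self.DILUTIONS])

    def test_too_few_dilutions_rejected(self):
        with pytest.raises(ValueError):
            qpcr.fit_standard_curve([(1, 20), (1 / 3, 21.6)])

    def test_non_monotone_series_warns_but_fits(self):
        cts = [20, 23.2, 21.6, 24.8, 26.3]
        with pytest.warns(UserWarning, match="monotone"):
            curve = qpcr.fit_standard_curve(zip(self.DILUTIONS, cts))
        assert 1 < curve.efficiency < 4

    def test_noisy_series_recovers_known_efficiency(self, rng):
        eff = 1.8
        base = 22.0
        cts = [base - np.log(d) / np.log(eff) + rng.normal(0, 0.05)
               for d in self.DILUTIONS]
        curve = qpcr.fit_standard_curve(zip(self.DILUTIONS, cts))
        assert 1.75 <= curve.efficiency <= 1.85


class TestLinearization:
    def test_anchor_maps_to_one(self):
        curve = qpcr.StandardCurve(slope=-1.4427, intercept=22.0, efficiency=2.0)
        assert qpcr.ct_to_linear(22.0, curve) == pytest.approx(1.0)
        assert qpcr.ct_to_linear(21.0, curve) == pytest.approx(2.0)
        # the most dilute standard (1:81) amplifies log2(81) cycles later
        assert qpcr.ct_to_linear(22.0 + np.log2(81), curve) == pytest.approx(1 / 81)

    @pytest.mark.parametrize(
        "ct,expected", [(32, 1.0), (31, 1.735), (30, 3.010225)]
    )
    def test_openarray_fixed_transform(self, ct, expected):
        assert qpcr.openarray_linear(ct) == pytest.approx(expected)

    def test_openarray_strictly_decreasing_in_ct(self):
        cts = np.linspace(10, 40, 301)
        vals = qpcr.openarray_linear(cts)
        assert np.all(np.diff(vals) < 0)


class TestReplicatesAndNormalization:
    def _raw(self, pairs):
        wells = pd.DataFrame(
            [("G1", "T1", i + 1, ct) for i, ct in enumerate(pairs)],
            columns=["gene", "tissue", "replicate", "ct"],
        )
        standard = pd.DataFrame(
            {"dilution": [1, 1 / 3, 1 / 9, 1 / 27, 1 / 81],
             "ct": [22, 23.585, 25.170, 26.755, 28.340]},
        )
        return qpcr.RawPlateData(wells=wells, standard=standard)

    def test_duplicate_wells_average_linear_values(self):
        # CTs 21 and 22 at efficiency 2 linearize to 2.0 and 1.0
        summ = qpcr.average_replicates(self._raw([21.0, 22.0]))
        assert summ.matrix.loc["G1", "T1"] == pytest.approx(1.5, rel=1e-3)
        sd = np.std([2.0, 1.0], ddof=1)
        assert summ.cv_percent.loc["G1", "T1"] == pytest.approx(100 * sd / 1.5, rel=1e-2)

    def test_identical_replicates_have_zero_cv(self):
        summ = qpcr.average_replicates(self._raw([21.0, 21.0]))
        assert summ.cv_percent.loc["G1", "T1"] == pytest.approx(0.0)
        assert summ.discordant == []

    def test_single_replicate_keeps_value_with_undefined_cv(self):
        summ = qpcr.average_replicates(self._raw([22.0]))
        assert summ.matrix.loc["G1", "T1"] == pytest.approx(1.0)
        assert np.isnan(summ.cv_percent.loc["G1", "T1"])

    def test_discordant_replicates_flagged(self):
        summ = qpcr.average_replicates(self._raw([20.0, 24.0]))
        assert ("G1", "T1") in summ.discordant

    def test_housekeeping_division_hand_case(self):
        m = pd.DataFrame(
            {"T1": [8.0, 1.0, 3.0], "T2": [8.0, 3.0, 5.0]},
            index=["TARGET", "HK1", "HK2"],
        )
        out = qpcr.normalize_housekeeping(m, ["HK1", "HK2"])
        assert out.loc["TARGET", "T1"] == pytest.approx(4.0)  # hk mean 2
        assert out.loc["TARGET", "T2"] == pytest.approx(2.0)  # hk mean 4

    def test_housekeeping_scale_invariance(self):
        m = pd.DataFrame(
            {"T1": [5.0, 2.0], "T2": [7.0, 4.0]}, index=["TARGET", "HK"]
        )
        doubled = m.copy()
        doubled["T1"] *= 2  # whole tissue column rescaled, hk included
        a = qpcr.normalize_housekeeping(m, ["HK"])
        b = qpcr.normalize_housekeeping(doubled, ["HK"])
        pd.testing.assert_frame_equal(a, b)

    def test_missing_housekeeping_value_names_tissue(self):
        m = pd.DataFrame({"T1": [5.0, 2.0], "T2": [7.0, 0.0]},
                         index=["TARGET", "HK"])
        with pytest.raises(ValueError, match="T2"):
            qpcr.normalize_housekeeping(m, ["HK"])


class TestCentering:
    def test_median_centering_hand_case(self):
        m = pd.DataFrame({"T1": [1.0], "T2": [2.0], "T3": [4.0]}, index=["G"])
        out = qpcr.median_center(m)
        assert out.loc["G"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_gene_centers_to_zero(self):
        m = pd.DataFrame({"T1": [3.0], "T2": [3.0]}, index=["G"])
        assert (qpcr.median_center(m) == 0).all().all()

    def test_per_gene_median_is_zero_after_centering(self, rng):
        m = pd.DataFrame(rng.lognormal(0, 1, size=(20, 11)))
        out = qpcr.median_center(m)
        assert np.allclose(out.median(axis=1), 0.0, atol=1e-12)


class TestCrossPlatformCV:
    def test_identical_matrices_give_zero_cv(self, rng):
        a = pd.DataFrame(rng.lognormal(0, 1, size=(5, 4)))
        per_gene, summary = qpcr.cross_platform_cv(a, a.copy())
        assert np.allclose(per_gene, 0.0)
        assert summary["mean"] == pytest.approx(0.0)

    def test_global_scale_removed_by_mean_normalization(self, rng):
        a = pd.DataFrame(rng.lognormal(0, 1, size=(5, 4)))
        per_gene, _ = qpcr.cross_platform_cv(a, 2.0 * a)
        assert np.allclose(per_gene, 0.0, atol=1e-12)

    def test_hand_computed_pair(self):
        # pair (1, 3): sd/mean with ddof=1 -> sqrt(2)/2 = 70.7%
        a = pd.DataFrame({"T1": [1.0]}, index=["G"])
        b = pd.DataFrame({"T1": [3.0]}, index=["G"])
        per_gene, _ = qpcr.cross_platform_cv(a, b, mean_normalize=False)
        assert per_gene["G"] == pytest.approx(70.71, abs=0.01)

    def test_disjoint_matrices_rejected(self):
        a = pd.DataFrame({"T1": [1.0]}, index=["G1"])
        b = pd.DataFrame({"T2": [1.0]}, index=["G2"])
        with pytest.raises(ValueError):
            qpcr.cross_platform_cv(a, b)


class TestPlateRoundTrip:
    def test_noiseless_plates_recover_truth_up_to_scale(self, rng):
        truth = pd.DataFrame(
            rng.lognormal(0, 1, size=(6, 5)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"T{j}" for j in range(5)],
        )
        cfg = syn.PlateConfig(ct_noise_sd=0.0, seed=1)
        raw = syn.gen_ct_plates(cfg, truth)
        summ = qpcr.average_replicates(raw)
        recovered = summ.matrix.loc[truth.index, truth.columns]
        ratio = (recovered / truth).to_numpy()
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_replicate_count_respected(self):
        truth = pd.DataFrame({"T1": [1.0]}, index=["G1"])
        raw = syn.gen_ct_plates(syn.PlateConfig(replicate_count=2), truth)
        per_well = raw.wells.groupby(["gene", "tissue"]).size()
        assert (per_well == 2).all()

    def test_nonpositive_truth_rejected(self):
        truth = pd.DataFrame({"T1": [0.0]}, index=["G1"])
        with pytest.raises(ValueError):
            syn.gen_ct_plates(syn.PlateConfig(), truth)
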