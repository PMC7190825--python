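"""Pipeline arithmetic, cohort statistics against permutation oracles, and
end-to-end parameter recovery on noiseless phantoms."""

import numpy as np
import pytest

from bcsfbasl import (
    AslSeries,
    PhantomSpec,
    RoiSpec,
    apply_intervention,
    cohort_compare,
    correlate,
    cp_blood_flow,
    flow_to_reporting_units,
    m0_correction,
    make_phantom,
    pairwise_subtract,
    percent_change,
    quantify_subject,
    roi_sum,
    scan_rescan_error,
    simulate_subject,
    total_delivery_rate,
)


def _series(controls, labels, ti=(1.0, 2.0), te=0.02):
    return AslSeries(ti_list=np.asarray(ti), controls=controls,
                     labels=labels, te=te)


class TestPairwiseSubtract:
    def test_identical_pairs_give_zero(self):
        c = np.ones((2, 3, 4, 4))
        assert not pairwise_subtract(_series(c, c.copy())).any()

    def test_constant_offset(self):
        c = np.full((2, 1, 4, 4), 5.0)
        lab = np.full((2, 1, 4, 4), 3.0)
        np.testing.assert_array_equal(pairwise_subtract(_series(c, lab)), 2.0)

    def test_flipped_order_convention(self):
        c = np.full((2, 1, 4, 4), 5.0)
        lab = np.full((2, 1, 4, 4), 3.0)
        dm = pairwise_subtract(_series(c, lab), order="label-control")
        np.testing.assert_array_equal(dm, -2.0)

    def test_averaging_suppresses_noise(self):
        rng = np.random.default_rng(0)
        n_rep = 20
        c = 10.0 + rng.normal(0, 1.0, (1, n_rep, 8, 8))
        lab = 9.0 + rng.normal(0, 1.0, (1, n_rep, 8, 8))
        dm = pairwise_subtract(_series(c, lab, ti=(1.0,)))
        # residual noise ~ sqrt(2/20); mean over 64 voxels well within 3 SE
        assert np.mean(dm) == pytest.approx(
            1.0, abs=3 * np.sqrt(2 / n_rep / 64))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            _series(np.ones((2, 2, 4, 4)), np.ones((2, 3, 4, 4)))


class TestRoiOps:
    def _roi(self, mask, vol=0.9375, vent=None):
        return RoiSpec(mask=mask, voxel_volume=vol, ventricle_volume=vent)

    def test_sum_under_mask(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[:3, :2] = True  # 6 voxels
        mask[3, 3] = True
        assert roi_sum(np.ones((4, 4)), self._roi(mask)) == 7.0
        assert roi_sum(np.zeros((4, 4)), self._roi(mask)) == 0.0

    def test_single_voxel(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(4, 4))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        assert roi_sum(img, self._roi(mask)) == pytest.approx(img[2, 1])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            self._roi(np.zeros((4, 4), dtype=bool))

    def test_m0_correction_arithmetic(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[:3, :4] = True  # 12 voxels * 0.9375 = 11.25 mm^3
        roi = self._roi(mask, vent=3.75)
        assert m0_correction(100.0, roi) == pytest.approx(300.0)
        roi_id = self._roi(mask, vent=roi.roi_volume)
        assert m0_correction(100.0, roi_id) == pytest.approx(100.0)

    def test_m0_correction_requires_ventricle_volume(self):
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            m0_correction(1.0, self._roi(mask, vent=None))


class TestUnitChain:
    def test_flow_reporting_units(self):
        assert flow_to_reporting_units(0.004) == pytest.approx(24.0)
        assert flow_to_reporting_units(0.0) == 0.0
        assert flow_to_reporting_units(0.00216667) == pytest.approx(
            13.0, rel=1e-5)

    def test_total_delivery_reproduces_2p7_ul_min(self):
        assert total_delivery_rate(24.0, 11.25) == pytest.approx(2.7)
        assert total_delivery_rate(0.0, 11.25) == 0.0
        assert total_delivery_rate(13.0, 11.25) == pytest.approx(1.4625)

    def test_conservation_native_units(self):
        f = 0.0037
        vol = 11.25
        assert total_delivery_rate(flow_to_reporting_units(f), vol) == \
            pytest.approx(f * vol * 60.0)

    def test_cp_blood_flow(self):
        assert cp_blood_flow(2.7, 0.22) == pytest.approx(1227.27, rel=1e-4)
        assert cp_blood_flow(0.0, 0.22) == 0.0
        assert cp_blood_flow(2.7, 0.44) == pytest.approx(
            cp_blood_flow(2.7, 0.22) / 2)

    def test_cp_blood_flow_extraction_and_errors(self):
        assert cp_blood_flow(2.7, 0.22, extraction=0.9) == pytest.approx(
            cp_blood_flow(2.7, 0.22) / 0.9)
        with pytest.raises(ValueError):
            cp_blood_flow(2.7, 0.0)

    def test_percent_change(self):
        assert percent_change(251.0, 218.0) == pytest.approx(-13.147, rel=1e-3)
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(100.0, 37.0) == pytest.approx(-63.0)
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestCohortStats:
    def test_identical_groups(self):
        t, p = cohort_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_clear_separation(self):
        t, p = cohort_compare([11.0, 12.0, 13.0], [1.0, 2.0, 3.0])
        assert p < 0.001

    def test_one_tailed_against_permutation_oracle(self):
        rng = np.random.default_rng(123)
        a = rng.normal(10.0, 2.0, 6)
        b = rng.normal(8.0, 2.0, 6)
        _, p = cohort_compare(a, b, tail="one")
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = 0
        n_perm = 20000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += (pooled[:6].mean() - pooled[6:].mean()) >= obs
        p_perm = (count + 1) / (n_perm + 1)
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(
            p_perm * (1 - p_perm) / n_perm) + 0.01)

    def test_insufficient_n_raises(self):
        with pytest.raises(ValueError):
            cohort_compare([1.0], [1.0, 2.0])

    def test_correlate_exact_lines(self):
        x = np.arange(5.0)
        r, _ = correlate(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_correlate_against_permutation_oracle(self):
        rng = np.random.default_rng(7)
        n = 12
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        r, p = correlate(x, y)
        count = 0
        n_perm = 20000
        yy = y.copy()
        for _ in range(n_perm):
            rng.shuffle(yy)
            count += abs(np.corrcoef(x, yy)[0, 1]) >= abs(r)
        p_perm = (count + 1) / (n_perm + 1)
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(
            max(p_perm * (1 - p_perm) / n_perm, 1e-9)) + 0.005)

    def test_correlate_rejects_constant(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestScanRescan:
    def test_identical_pairs(self):
        assert scan_rescan_error([(20.0, 20.0), (13.0, 13.0)]) == 0.0

    def test_arithmetic(self):
        assert scan_rescan_error([(20.0, 21.0), (10.0, 9.0)]) == 1.0

    def test_half_normal_mean(self):
        """|repeat - baseline| with within-subject SD s is half-normal with
        mean s*sqrt(2)*sqrt(2/pi)."""
        rng = np.random.default_rng(99)
        s = 1.15
        base = rng.normal(20.0, s, 20000)
        rept = rng.normal(20.0, s, 20000)
        mad = scan_rescan_error(np.column_stack([base, rept]))
        expected = s * np.sqrt(2) * np.sqrt(2 / np.pi)
        assert mad == pytest.approx(expected, rel=0.03)


class TestQuantifySubject:
    def _quant(self, phantom, seed=1, noise=0.0, **kw):
        s_std, s_csf = simulate_subject(phantom, seed=seed, noise_sd=noise)
        return quantify_subject(s_std, s_csf, phantom.roi_spec_cortex(),
                                phantom.roi_spec_ventricles(),
                                rel=phantom.spec.relaxation, **kw)

    def test_noiseless_round_trip_within_1pct(self, noiseless_subject):
        phantom, s_std, s_csf = noiseless_subject
        q = quantify_subject(s_std, s_csf, phantom.roi_spec_cortex(),
                             phantom.roi_spec_ventricles(),
                             rel=phantom.spec.relaxation, cp_mass_mg=0.22)
        spec = phantom.spec
        assert q.f_bcsfb == pytest.approx(spec.f_bcsfb_true, rel=0.01)
        assert q.cbf_cortex == pytest.approx(spec.cbf_true, rel=0.01)
        assert q.t1_csf == pytest.approx(spec.relaxation.t1_csf, rel=0.01)
        assert q.t1_tissue == pytest.approx(spec.relaxation.t1_tissue,
                                            rel=0.01)
        assert q.total_delivery == pytest.approx(2.7, rel=0.01)
        assert q.cp_blood_flow == pytest.approx(2.7 / 0.22 * 100, rel=0.01)

    def test_zero_delivery_specificity(self):
        phantom = make_phantom(PhantomSpec(f_bcsfb_true=0.0))
        q = self._quant(phantom)
        assert q.f_bcsfb == pytest.approx(0.0, abs=1e-6)
        assert q.cbf_cortex == pytest.approx(251.0, rel=0.01)

    def test_vasopressin_contrast(self, default_phantom):
        base = self._quant(default_phantom)
        post = self._quant(apply_intervention(default_phantom, 0.37, 1.0))
        assert percent_change(base.f_bcsfb, post.f_bcsfb) == \
            pytest.approx(-63.0, abs=1.0)
        assert percent_change(base.cbf_cortex, post.cbf_cortex) == \
            pytest.approx(0.0, abs=1.0)

    def test_f_invariant_to_ventricle_volume(self):
        """The M0 correction removes the ventricle-size dependence."""
        values = []
        for vol in (2.0, 3.0, 4.0, 5.0):
            phantom = make_phantom(PhantomSpec(ventricle_volume=vol))
            values.append(self._quant(phantom).f_bcsfb)
        assert np.ptp(values) / np.mean(values) <= 0.01

    def test_alpha_linearity_of_both_pipelines(self, default_phantom):
        """Halving labelling efficiency halves the normalised difference
        signal of both branches by the same factor (the basis of the
        labelling-efficiency control experiment), and halves the recovered
        delivery rate when quantified assuming full efficiency."""
        def measure(alpha):
            s_std, s_csf = simulate_subject(default_phantom, seed=1,
                                            noise_sd=0.0, alpha=alpha)
            q = quantify_subject(s_std, s_csf,
                                 default_phantom.roi_spec_cortex(),
                                 default_phantom.roi_spec_ventricles(),
                                 rel=default_phantom.spec.relaxation,
                                 alpha=1.0)
            roi_c = default_phantom.roi_spec_cortex()
            roi_v = default_phantom.roi_spec_ventricles()
            amp_ctx = max(roi_sum(img, roi_c)
                          for img in pairwise_subtract(s_std))
            amp_csf = max(roi_sum(img, roi_v)
                          for img in pairwise_subtract(s_csf))
            return q.f_bcsfb, amp_ctx, amp_csf
        full = measure(1.0)
        half = measure(0.5)
        assert half[0] == pytest.approx(full[0] / 2, rel=0.01)
        assert half[1] == pytest.approx(full[1] / 2, rel=0.01)
        assert half[2] == pytest.approx(full[2] / 2, rel=0.01)

    def test_stage_labelled_errors(self, noiseless_subject):
        phantom, s_std, s_csf = noiseless_subject
        bad_roi = RoiSpec(mask=phantom.roi_ventricles,
                          voxel_volume=phantom.voxel_volume,
                          ventricle_volume=None)
        with pytest.raises(ValueError, match="BCSFB-ASL stage"):
            quantify_subject(s_std, s_csf, phantom.roi_spec_cortex(),
                             bad_roi, rel=phantom.spec.relaxation)
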