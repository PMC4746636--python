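"""AFM/DREEM statistics: fits, tests, calibrations, renderer."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telocompact.afm import (
    AFMTable,
    DreemTrace,
    IdentityCalibration,
    PolynomialCalibration,
    compare_contour_lengths,
    dreem_contrast,
    fit_gaussian_mixture,
    fit_volume_compaction,
    measure_volume,
    mw_to_volume,
    render_pseudo_afm,
)


class TestMixtureFit:
    def test_delta_sample_k1(self):
        rng = np.random.default_rng(0)
        values = 5.0 + rng.normal(0, 1e-3, 60)
        fit = fit_gaussian_mixture(values, K=1, bin_width=0.5)
        assert fit.means[0] == pytest.approx(values.mean(), abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=0.01)

    def test_k2_on_unimodal_flags_overlap(self):
        rng = np.random.default_rng(1)
        fit = fit_gaussian_mixture(rng.normal(100, 10, 300), K=2, bin_width=5.0)
        assert fit.overlapping

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(50, 5, 200), rng.normal(120, 8, 200)])
        fit = fit_gaussian_mixture(values, K=2, bin_width=5.0)
        assert fit.means[0] == pytest.approx(50, rel=0.05)
        assert fit.means[1] == pytest.approx(120, rel=0.05)
        assert not fit.overlapping

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(50, 5, 100), rng.normal(120, 8, 100)])
        a = fit_gaussian_mixture(values, K=2, bin_width=5.0)
        b = fit_gaussian_mixture(values[::-1], K=2, bin_width=5.0)
        assert np.allclose(a.means, b.means)


class TestContourComparison:
    def test_identical_groups_p_near_one(self):
        g = np.array([1700.0, 1710.0, 1720.0, 1730.0])
        _, _, p = compare_contour_lengths(g, g)
        assert p > 0.99

    def test_published_groups_significant(self):
        """Groups at the published free-DNA and large-complex statistics
        separate decisively: at these group sizes the Welch test has
        ~90% power at p < 1e-4 and ~98% at p < 1e-3 (computed by direct
        simulation of the generating statistics)."""
        hits4 = hits3 = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            a = rng.normal(1721.0, 61.9, 69)
            b = rng.normal(1532.0, 241.0, 51)
            _, _, p = compare_contour_lengths(a, b)
            hits4 += p < 1e-4
            hits3 += p < 1e-3
        assert hits4 >= 170
        assert hits3 >= 190

    def test_null_pvalues_uniform(self):
        pvals = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            a = rng.normal(1700.0, 60.0, 400)
            b = rng.normal(1700.0, 60.0, 400)
            _, _, p = compare_contour_lengths(a, b)
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_contour_lengths([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestVolumeCompaction:
    def _table(self, contours, volumes):
        return AFMTable(
            pd.DataFrame(
                {
                    "volume_nm3": volumes,
                    "height_nm": np.full(len(volumes), 1.5),
                    "dna_contour_length_nm": contours,
                }
            )
        )

    def test_noiseless_exact_recovery(self):
        lc_bp = np.linspace(200, 3000, 40)
        volumes = 1284.0 + 3.2 * lc_bp
        contours = 1721.0 - lc_bp * 0.32
        fit = fit_volume_compaction(self._table(contours, volumes), 1721.0)
        assert fit.slope == pytest.approx(3.2, abs=1e-9)
        assert fit.intercept == pytest.approx(1284.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_units_per_100bp(self):
        # 3.2 nm^3/bp means 320 nm^3 of complex volume per 100 bp compacted
        assert 3.2 * 100 == pytest.approx(320.0)

    def test_binned_fit_smooths_noise(self):
        from telocompact.synth import gen_afm_table

        table = gen_afm_table(seed=5)
        fit = fit_volume_compaction(table, 1721.0)
        assert fit.binned_r_squared > fit.r_squared

    def test_row_order_invariance(self):
        from telocompact.synth import gen_afm_table

        table = gen_afm_table(seed=7)
        a = fit_volume_compaction(table, 1721.0)
        b = fit_volume_compaction(table.iloc[::-1].reset_index(drop=True), 1721.0)
        assert a.slope == pytest.approx(b.slope)


class TestCalibration:
    def test_identity(self):
        assert mw_to_volume(55.0, IdentityCalibration()) == 55.0

    def test_round_trip(self):
        cal = PolynomialCalibration.from_anchors([(55, 58), (110, 138), (220, 217)])
        for mw in (60.0, 100.0, 200.0):
            assert cal.mw(cal.volume(mw)) == pytest.approx(mw, abs=1e-9)

    def test_anchors_reproduced(self):
        anchors = [(55, 58), (110, 138), (220, 217)]
        cal = PolynomialCalibration.from_anchors(anchors)
        for mw, vol in anchors:
            assert cal.volume(mw) == pytest.approx(vol, abs=1e-9)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            IdentityCalibration().volume(-1.0)


def _trace(free, bound, cid=0):
    samples = np.concatenate([free, bound])
    labels = np.array(["DNA_FREE"] * len(free) + ["DNA_BOUND"] * len(bound))
    return DreemTrace(samples, labels, cid)


class TestDreemContrast:
    def test_identical_segments_null(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.1, 30)
        res = dreem_contrast([_trace(x, x.copy())])
        assert res.classes == ["NULL"]

    def test_all_lower_cohort_zero_enhanced(self):
        rng = np.random.default_rng(1)
        traces = [
            _trace(rng.normal(0, 0.05, 30), rng.normal(-0.5, 0.05, 30), k) for k in range(20)
        ]
        res = dreem_contrast(traces)
        assert res.enhanced_fraction == 0.0
        assert all(c == "REDUCED" for c in res.classes)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(2)
        traces = [
            _trace(rng.normal(0, 0.1, 25), rng.normal(rng.choice([-0.5, 0.5]), 0.1, 25), k)
            for k in range(30)
        ]
        res = dreem_contrast(traces)
        flipped = [DreemTrace(-t.samples, t.labels, t.complex_id) for t in traces]
        res_f = dreem_contrast(flipped)
        swap = {"ENHANCED": "REDUCED", "REDUCED": "ENHANCED", "NULL": "NULL"}
        assert res_f.classes == [swap[c] for c in res.classes]

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            dreem_contrast([_trace(np.zeros(30), np.zeros(5))])


class TestPseudoAFM:
    def test_single_bead_cap_volume(self):
        # sphere of radius 0.5 resting on the plane (center z = 0.5):
        # rendered volume = integral of (z_c + sqrt(r^2 - d^2)) over the disc
        grid, _ = render_pseudo_afm(np.array([[0.0, 0.0, 0.5]]), pixel_nm=0.05)
        vol = measure_volume(grid, 0.05, height_floor=0.0)
        r = 0.5
        expected = np.pi * r**2 * 0.5 + 2.0 / 3.0 * np.pi * r**3
        assert vol == pytest.approx(expected, rel=0.10)

    def test_tip_dilation_monotone(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 10, 30), rng.uniform(0, 10, 30), rng.uniform(0.5, 2, 30)])
        g0, _ = render_pseudo_afm(pts, pixel_nm=0.25, tip_radius_nm=0.0)
        g2, _ = render_pseudo_afm(pts, pixel_nm=0.25, tip_radius_nm=2.0)
        assert measure_volume(g2, 0.25) >= measure_volume(g0, 0.25)

    def test_far_particles_additive(self):
        one, _ = render_pseudo_afm(np.array([[0.0, 0.0, 0.5]]), pixel_nm=0.1)
        two, _ = render_pseudo_afm(np.array([[0.0, 0.0, 0.5], [40.0, 0.0, 0.5]]), pixel_nm=0.1)
        v1 = measure_volume(one, 0.1, 0.0)
        v2 = measure_volume(two, 0.1, 0.0)
        assert v2 == pytest.approx(2 * v1, rel=0.01)

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            render_pseudo_afm(np.zeros((0, 3)))


class TestAFMTableValidation:
    def test_size_class_consistency_enforced(self):
        with pytest.raises(ValueError):
            AFMTable(
                pd.DataFrame(
                    {
                        "volume_nm3": [100.0, 900.0],
                        "height_nm": [0.5, 1.5],
                        "dna_contour_length_nm": [1700.0, 1500.0],
                        "size_class": ["LARGE", "LARGE"],
                    }
                )
            )
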