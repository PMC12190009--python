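"""Generators: determinism, ground-truth fidelity, domain errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ermech_quant import synthetic
from ermech_quant.errors import ConfigurationError, DomainError, GenerationError

from helpers import numeric_profile_extent


class TestStrainToDisplacement:
    @pytest.mark.parametrize(
        "length,strain,expected",
        [(60.0, 9.0, 5.4), (60.0, 6.0, 3.6), (60.0, 0.0, 0.0)],
    )
    def test_worked_examples(self, length, strain, expected):
        assert synthetic.strain_to_displacement(length, strain) == pytest.approx(
            expected, abs=1e-12
        )

    @given(
        length=st.floats(0.1, 1e4),
        strain=st.floats(0.0, 100.0),
        k=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_both_arguments(self, length, strain, k):
        d = synthetic.strain_to_displacement(length, strain)
        assert synthetic.strain_to_displacement(k * length, strain) == pytest.approx(
            k * d, rel=1e-12
        )
        assert synthetic.strain_to_displacement(length, k * strain) == pytest.approx(
            k * d, rel=1e-12
        )

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DomainError):
            synthetic.strain_to_displacement(0.0, 9.0)
        with pytest.raises(DomainError):
            synthetic.strain_to_displacement(60.0, -1.0)


class TestDecayHistogram:
    def test_mixture_mean_arrival_time(self):
        """Sample mean arrival of a 60/40 mix of 6 ns and 2 ns components
        matches the closed-form mixture mean 4.4 ns within 3 SE."""
        tau1, tau2, f1, n = 6.0, 2.0, 0.6, 100_000
        # wide window so truncation is negligible
        hist, truth = synthetic.gen_decay_histogram(
            tau1, tau2, f1, n, bin_width_ns=0.05, n_bins=2000, seed=1
        )
        mean_true = f1 * tau1 + (1 - f1) * tau2
        assert truth.parameters["mean_arrival_ns_pretruncation"] == pytest.approx(4.4)
        t = hist.bin_centers_ns
        sample_mean = float(np.sum(t * hist.counts) / hist.counts.sum())
        # variance of the mixture arrival time
        second = f1 * 2 * tau1**2 + (1 - f1) * 2 * tau2**2
        se = np.sqrt((second - mean_true**2) / hist.counts.sum())
        assert abs(sample_mean - mean_true) < 3 * se

    def test_single_exponential_degenerate_mixture(self):
        hist, _ = synthetic.gen_decay_histogram(
            6.0, 2.0, 1.0, 200_000, n_bins=2000, seed=2
        )
        t = hist.bin_centers_ns
        sample_mean = float(np.sum(t * hist.counts) / hist.counts.sum())
        assert sample_mean == pytest.approx(6.0, rel=0.02)

    def test_component_ordering_enforced(self):
        with pytest.raises(DomainError):
            synthetic.gen_decay_histogram(2.0, 6.0, 0.6, 1000)

    def test_empty_histogram_rejected(self):
        with pytest.raises(DomainError):
            synthetic.gen_decay_histogram(6.0, 2.0, 0.6, 0)

    def test_deterministic_given_seed(self):
        h1, t1 = synthetic.gen_decay_histogram(6.0, 2.0, 0.6, 10_000, seed=7)
        h2, t2 = synthetic.gen_decay_histogram(6.0, 2.0, 0.6, 10_000, seed=7)
        np.testing.assert_array_equal(h1.counts, h2.counts)
        assert t1.to_json() == t2.to_json()

    def test_truncation_fraction_recorded(self):
        _, truth = synthetic.gen_decay_histogram(
            6.0, 2.0, 0.6, 50_000, bin_width_ns=0.05, n_bins=100, seed=3
        )
        # window 5 ns; survival of the mixture past 5 ns is substantial
        expected = 0.6 * np.exp(-5 / 6.0) + 0.4 * np.exp(-5 / 2.0)
        assert truth.parameters["truncation_fraction"] == pytest.approx(
            expected, abs=0.01
        )


class TestERCellImage:
    def test_zero_sheet_target_gives_empty_sheet_mask(self):
        _, seg, truth = synthetic.gen_er_cell_image(
            sheet_fraction_target=0.0, seed=0
        )
        assert not seg.sheet_mask.any()
        assert truth.parameters["realized_sheet_fraction"] == 0.0

    def test_noiseless_image_is_three_level(self):
        img, seg, _ = synthetic.gen_er_cell_image(noise_sd=0.0, seed=1)
        values = np.unique(img.channel("ER"))
        assert set(values) <= {20.0, 100.0, 220.0}
        # labels and intensities correspond
        er = img.channel("ER")
        assert np.all(er[seg.sheet_mask] == 220.0)
        assert np.all(er[seg.tubule_mask] == 100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_realized_sheet_fraction_near_target(self, seed):
        _, _, truth = synthetic.gen_er_cell_image(
            sheet_fraction_target=0.3, seed=seed
        )
        assert truth.parameters["realized_sheet_fraction"] == pytest.approx(
            0.3, abs=0.05
        )

    def test_nucleus_too_large_rejected(self):
        with pytest.raises(DomainError):
            synthetic.gen_er_cell_image(image_shape=(64, 64), nucleus_radius_px=60)

    def test_masks_are_consistent(self):
        img, _, _ = synthetic.gen_er_cell_image(seed=2)
        assert not np.any(img.masks["cytoplasm"] & img.masks["nucleus"])
        assert np.all(img.masks["cytoplasm"] <= img.masks["cell"])


class TestMembranePair:
    def test_constant_gap_below_cutoff(self):
        a, b, extent, _ = synthetic.gen_membrane_pair(
            500.0, 1.0, {"name": "constant", "gap_nm": 20.0}, cutoff_nm=30.0
        )
        assert extent == 500.0
        np.testing.assert_allclose(b.points[:, 1], 20.0)

    def test_constant_gap_above_cutoff(self):
        _, _, extent, _ = synthetic.gen_membrane_pair(
            500.0, 1.0, {"name": "constant", "gap_nm": 35.0}, cutoff_nm=30.0
        )
        assert extent == 0.0

    def test_linear_ramp_extent(self):
        # gap 10 -> 50 over 400 nm crosses 30 at midpoint
        _, _, extent, _ = synthetic.gen_membrane_pair(
            400.0, 1.0,
            {"name": "linear", "start_nm": 10.0, "end_nm": 50.0},
            cutoff_nm=30.0,
        )
        assert extent == pytest.approx(200.0)

    @pytest.mark.parametrize("phase", [0.0, 0.7, 2.0, 4.5])
    def test_sinusoid_extent_matches_fine_grid_oracle(self, phase):
        profile = {
            "name": "sinusoid", "mean_nm": 25.0, "amplitude_nm": 10.0,
            "period_nm": 200.0, "phase_rad": phase,
        }
        span, cutoff = 730.0, 30.0
        _, _, extent, _ = synthetic.gen_membrane_pair(span, 1.0, profile, cutoff)

        def gap(x):
            return 25.0 + 10.0 * np.sin(2 * np.pi * x / 200.0 + phase)

        oracle = numeric_profile_extent(gap, span, cutoff, step=0.01)
        assert extent == pytest.approx(oracle, abs=0.05)

    def test_full_period_sinusoid_closed_form(self):
        # sin(u) <= 0.5 holds on 2/3 of each period
        _, _, extent, _ = synthetic.gen_membrane_pair(
            600.0, 1.0,
            {"name": "sinusoid", "mean_nm": 25.0, "amplitude_nm": 10.0,
             "period_nm": 200.0},
            cutoff_nm=30.0,
        )
        assert extent == pytest.approx(400.0, abs=1e-9)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            synthetic.gen_membrane_pair(100.0, 1.0, {"name": "sawtooth"})


class TestFiberImage:
    def test_infinite_concentration_all_angles_equal(self):
        _, angles, _ = synthetic.gen_fiber_image(
            n_fibers=10, mean_angle_deg=37.0, concentration=np.inf, seed=0
        )
        np.testing.assert_allclose(angles, 37.0)

    def test_zero_concentration_is_uniform_axial(self):
        """kappa=0: circular variance of doubled angles ~ 1 (Monte Carlo)."""
        _, angles, _ = synthetic.gen_fiber_image(
            n_fibers=500, concentration=0.0, seed=1
        )
        doubled = np.deg2rad(2 * angles)
        R = np.hypot(np.mean(np.cos(doubled)), np.mean(np.sin(doubled)))
        assert 1.0 - R == pytest.approx(1.0, abs=0.12)  # E[R] ~ n^-1/2

    def test_fiber_at_90_is_horizontal(self):
        img, _, _ = synthetic.gen_fiber_image(
            n_fibers=1, mean_angle_deg=90.0, concentration=np.inf,
            noise_sd=0.0, seed=0,
        )
        rr, cc = np.nonzero(img.channel("F-actin") > 150)
        assert np.ptp(rr) <= 4 and np.ptp(cc) == img.data.shape[-1] - 1

    def test_fiber_at_0_is_vertical(self):
        img, _, _ = synthetic.gen_fiber_image(
            n_fibers=1, mean_angle_deg=0.0, concentration=np.inf,
            noise_sd=0.0, seed=0,
        )
        rr, cc = np.nonzero(img.channel("F-actin") > 150)
        assert np.ptp(cc) <= 4 and np.ptp(rr) == img.data.shape[-2] - 1

    def test_no_fibers_rejected(self):
        with pytest.raises(DomainError):
            synthetic.gen_fiber_image(n_fibers=0)


class TestPunctaVolume:
    def test_zero_puncta_blank_volume(self):
        img, truth = synthetic.gen_puncta_volume(n_puncta=0, noise_sd=0.0)
        assert img.channel("SPLICS").max() == 0.0
        assert truth.parameters["centers_px"] == []

    def test_disjoint_spheres_form_n_components(self):
        from scipy import ndimage

        img, _ = synthetic.gen_puncta_volume(
            n_puncta=5, radius_px=3.0, min_separation_px=12.0,
            noise_sd=0.0, seed=4,
        )
        _, n = ndimage.label(img.channel("SPLICS") > 100)
        assert n == 5

    def test_infeasible_packing_names_constraint(self):
        with pytest.raises(GenerationError, match="min_separation"):
            synthetic.gen_puncta_volume(
                stack_shape=(16, 24, 24), n_puncta=200, radius_px=2.0,
                min_separation_px=10.0, seed=0,
            )

    def test_deterministic_given_seed(self):
        v1, t1 = synthetic.gen_puncta_volume(seed=9)
        v2, t2 = synthetic.gen_puncta_volume(seed=9)
        np.testing.assert_array_equal(v1.data, v2.data)
        assert t1.to_json() == t2.to_json()


class TestSoceTrace:
    def test_flat_trace_when_peak_equals_baseline(self):
        trace, _ = synthetic.gen_soce_trace(1.0, 1.0, noise_sd=0.0)
        np.testing.assert_allclose(trace.F, 1.0)

    def test_noiseless_peak_equals_peak_F(self):
        trace, _ = synthetic.gen_soce_trace(1.0, 3.0, noise_sd=0.0)
        post = trace.time_s >= trace.phase_marks["readdition_s"]
        assert trace.F[post].max() == pytest.approx(3.0, abs=1e-12)

    def test_five_second_sampling_and_phase_order(self):
        trace, _ = synthetic.gen_soce_trace()
        np.testing.assert_allclose(np.diff(trace.time_s), 5.0)
        m = trace.phase_marks
        assert m["ca_free_start_s"] < m["depletion_start_s"] < m["readdition_s"]

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            synthetic.gen_soce_trace(baseline_F=0.0)
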