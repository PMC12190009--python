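"""Colocalization, ER-on-mitochondria mapping, contact extent, puncta."""

import numpy as np
import pytest

from ermech_quant import interactions as ia
from ermech_quant import synthetic
from ermech_quant.errors import DomainError, SegmentationError
from ermech_quant.interactions import MembraneTrace

from helpers import flood_fill_component_count


class TestManders:
    def test_identical_masks_give_unity(self):
        m = (np.random.default_rng(0).uniform(0, 1, (32, 32)) > 0.5).astype(float)
        res = ia.manders(m, m, threshold_method="zero")
        assert res.M1 == 1.0 and res.M2 == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a[:8], b[8:] = 1.0, 1.0
        res = ia.manders(a, b, threshold_method="zero")
        assert res.M1 == 0.0 and res.M2 == 0.0

    def test_half_overlap_is_half(self):
        """ch1 uniform over a region half-covered by ch2 -> M1 = 0.5."""
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[5:15, :10] = 7.0          # 100 px of ch1
        b[5:15, 5:15] = 3.0         # covers exactly half of them
        res = ia.manders(a, b, threshold_method="zero")
        assert res.M1 == pytest.approx(0.5)

    def test_channel_swap_symmetry_exact(self, rng):
        a = rng.uniform(0, 10, (24, 24))
        b = rng.uniform(0, 10, (24, 24))
        r1 = ia.manders(a, b, thresholds=(2.0, 3.0), threshold_method="fixed")
        r2 = ia.manders(b, a, thresholds=(3.0, 2.0), threshold_method="fixed")
        assert (r1.M1, r1.M2) == (r2.M2, r2.M1)

    def test_all_zero_channel_rejected(self):
        with pytest.raises(DomainError):
            ia.manders(np.zeros((8, 8)), np.ones((8, 8)))


class TestErOnMitoMap:
    def test_er_at_max_everywhere_on_mito(self):
        mito = np.zeros((16, 16))
        mito[4:12, 4:12] = 100.0
        er = np.where(mito > 0, 50.0, 0.0)
        _, summary = ia.er_on_mito_map(er, mito)
        assert summary == pytest.approx(1.0)

    def test_er_absent_from_mito(self):
        mito = np.zeros((16, 16))
        mito[4:12, 4:12] = 100.0
        er = np.where(mito > 0, 0.0, 80.0)
        _, summary = ia.er_on_mito_map(er, mito)
        assert summary == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_known_coverage_fraction_recovered(self, seed):
        """ER at max intensity on fraction f of mito pixels -> summary f."""
        rng = np.random.default_rng(seed)
        mito = np.zeros((32, 32))
        mito[8:24, 8:24] = 150.0
        f = rng.uniform(0.2, 0.8)
        er = np.zeros((32, 32))
        mito_idx = np.argwhere(mito > 0)
        chosen = mito_idx[rng.random(len(mito_idx)) < f]
        er[tuple(chosen.T)] = 200.0
        _, summary = ia.er_on_mito_map(er, mito)
        realized = len(chosen) / len(mito_idx)
        assert summary == pytest.approx(realized, abs=1e-9)

    def test_empty_mito_mask_rejected(self):
        with pytest.raises(SegmentationError):
            ia.er_on_mito_map(
                np.ones((8, 8)), np.zeros((8, 8)), mito_threshold_method="fixed",
                mito_threshold=10.0,
            )


class TestContactExtent:
    def test_parallel_gap_20_single_full_site(self):
        a, b, _, _ = synthetic.gen_membrane_pair(
            500.0, 1.0, {"name": "constant", "gap_nm": 20.0}
        )
        sites = ia.contact_extent(a, b, max_gap_nm=30.0)
        assert len(sites) == 1
        assert sites[0].extent_nm == pytest.approx(500.0, abs=1e-9)
        assert sites[0].mean_gap_nm == pytest.approx(20.0, abs=1e-9)

    def test_parallel_gap_35_no_sites(self):
        a, b, _, _ = synthetic.gen_membrane_pair(
            500.0, 1.0, {"name": "constant", "gap_nm": 35.0}
        )
        assert ia.contact_extent(a, b, max_gap_nm=30.0) == []

    def test_sinusoidal_gap_matches_analytic_extent(self):
        """Gentle sinusoidal profile: measured total extent within 2 nm of
        the closed-form crossing-interval length."""
        a, b, analytic, _ = synthetic.gen_membrane_pair(
            4000.0, 1.0,
            {"name": "sinusoid", "mean_nm": 25.0, "amplitude_nm": 10.0,
             "period_nm": 2000.0},
            cutoff_nm=30.0,
        )
        total = ia.total_contact_extent(ia.contact_extent(a, b, 30.0))
        assert total == pytest.approx(analytic, abs=2.0)

    def test_symmetry_between_traces(self):
        a, b, _, _ = synthetic.gen_membrane_pair(
            1500.0, 1.0,
            {"name": "sinusoid", "mean_nm": 27.0, "amplitude_nm": 8.0,
             "period_nm": 700.0},
        )
        t_ab = ia.total_contact_extent(ia.contact_extent(a, b, 30.0))
        t_ba = ia.total_contact_extent(ia.contact_extent(b, a, 30.0))
        assert abs(t_ab - t_ba) <= 2.0

    def test_monotone_in_max_gap(self, rng):
        """Total extent is non-decreasing in max_gap on random profiles."""
        for _ in range(20):
            profile = {
                "name": "sinusoid",
                "mean_nm": float(rng.uniform(15, 40)),
                "amplitude_nm": float(rng.uniform(2, 12)),
                "period_nm": float(rng.uniform(800, 3000)),
                "phase_rad": float(rng.uniform(0, 2 * np.pi)),
            }
            a, b, _, _ = synthetic.gen_membrane_pair(2000.0, 2.0, profile)
            totals = [
                ia.total_contact_extent(ia.contact_extent(a, b, g, min_run_nm=0.0))
                for g in (20.0, 30.0, 40.0, 50.0)
            ]
            assert all(t2 >= t1 - 1e-9 for t1, t2 in zip(totals, totals[1:]))

    def test_min_run_suppresses_grazing_contacts(self):
        a, b, _, _ = synthetic.gen_membrane_pair(
            2000.0, 1.0,
            {"name": "sinusoid", "mean_nm": 32.0, "amplitude_nm": 2.5,
             "period_nm": 400.0},
        )
        sites_all = ia.contact_extent(a, b, 30.0, min_run_nm=0.0)
        sites_gated = ia.contact_extent(a, b, 30.0, min_run_nm=100.0)
        assert len(sites_gated) <= len(sites_all)
        assert all(s.extent_nm >= 100.0 for s in sites_gated)

    def test_runs_separated_by_gaps_stay_distinct(self):
        a, b, _, _ = synthetic.gen_membrane_pair(
            4000.0, 1.0,
            {"name": "sinusoid", "mean_nm": 25.0, "amplitude_nm": 10.0,
             "period_nm": 2000.0},
        )
        sites = ia.contact_extent(a, b, 30.0)
        # below-cutoff arcs: [0, pi/6], [5pi/6, 13pi/6], [17pi/6, 4pi]
        assert len(sites) == 3

    def test_degenerate_trace_rejected(self):
        with pytest.raises(DomainError):
            MembraneTrace(np.array([[0.0, 0.0]]), "ER")

    def test_json_round_trip(self, tmp_path):
        t = MembraneTrace(np.array([[0.0, 0.0], [10.0, 5.0], [20.0, 0.0]]), "PM")
        p = tmp_path / "trace.json"
        t.to_json(p)
        t2 = MembraneTrace.from_json(p)
        np.testing.assert_allclose(t.points, t2.points)
        assert t2.organelle == "PM"


class TestCorticalER:
    def test_labels_and_boundary_convention(self):
        labels, props = ia.classify_cortical_er([10.0, 50.0], thin_cutoff_nm=30.0)
        assert labels == ["thin", "wide"]
        labels_b, _ = ia.classify_cortical_er([30.0], thin_cutoff_nm=30.0)
        assert labels_b == ["wide"]  # cutoff itself is wide
        assert props == {"thin": 0.5, "wide": 0.5}

    def test_bimodal_widths_recover_mixture_weights(self, rng):
        w_thin = rng.normal(12.0, 2.0, 140).clip(1.0)
        w_wide = rng.normal(60.0, 8.0, 60).clip(1.0)
        widths = np.concatenate([w_thin, w_wide])
        _, props = ia.classify_cortical_er(widths, thin_cutoff_nm=30.0)
        assert props["thin"] == pytest.approx(0.7, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            ia.classify_cortical_er([])


class TestPunctaCounting:
    def test_five_disjoint_spheres(self):
        vol, _ = synthetic.gen_puncta_volume(
            n_puncta=5, radius_px=3.0, min_separation_px=12.0,
            noise_sd=0.0, seed=3,
        )
        res = ia.count_splics_puncta(vol.channel("SPLICS"))
        assert res.count == 5

    def test_empty_volume_counts_zero(self):
        res = ia.count_splics_puncta(np.zeros((8, 16, 16)))
        assert res.count == 0

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        vol, _ = synthetic.gen_puncta_volume(
            stack_shape=(20, 48, 48), n_puncta=10, radius_px=2.0,
            min_separation_px=5.0, noise_sd=0.0, seed=seed,
        )
        stack = vol.channel("SPLICS")
        res = ia.count_splics_puncta(
            stack, threshold_method="fixed", threshold=100.0,
            min_voxels=1, connectivity=connectivity,
        )
        oracle = flood_fill_component_count(stack > 100.0, connectivity)
        assert res.count == oracle

    def test_intensity_rescaling_invariance(self):
        vol, _ = synthetic.gen_puncta_volume(n_puncta=6, noise_sd=0.0, seed=1)
        s = vol.channel("SPLICS")
        c1 = ia.count_splics_puncta(s, threshold_method="fixed", threshold=100.0)
        c2 = ia.count_splics_puncta(
            3 * s, threshold_method="fixed", threshold=300.0
        )
        assert c1.count == c2.count

    def test_axis_permutation_invariance_26(self):
        vol, _ = synthetic.gen_puncta_volume(
            stack_shape=(24, 40, 40), n_puncta=7, noise_sd=0.0, seed=2,
            radius_px=2.5, min_separation_px=8.0,
        )
        s = vol.channel("SPLICS")
        c1 = ia.count_splics_puncta(s, threshold_method="fixed", threshold=100.0)
        c2 = ia.count_splics_puncta(
            np.transpose(s, (1, 2, 0)), threshold_method="fixed", threshold=100.0
        )
        assert c1.count == c2.count

    def test_min_voxel_filter_drops_specks(self):
        vol = np.zeros((8, 16, 16))
        vol[2, 2, 2] = 200.0          # single-voxel speck
        vol[5, 8:11, 8:11] = 200.0    # 9-voxel punctum
        res = ia.count_splics_puncta(
            vol, threshold_method="fixed", threshold=100.0, min_voxels=4
        )
        assert res.count == 1
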