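"""Tests for voxelization, slab projection and the domain pipeline."""

import numpy as np
import pytest

from srev.excluded_volume import BeadChain
from srev.tomogram import (DensityVolume, DomainRecord, domain_radius,
                           domain_statistics, enhance, find_domain_centers,
                           slab_projection, voxelize)


def _chain(pos):
    pos = np.asarray(pos, dtype=float)
    return BeadChain(positions=pos,
                     bond_rest_lengths=np.full(max(len(pos) - 1, 0), 10.0))


class TestVoxelize:
    def test_mass_conserved_for_single_bead(self):
        vol = voxelize(_chain([[0.0, 0.0, 0.0]]), voxel_size=2.0, sigma=5.0)
        assert vol.total_mass == pytest.approx(1.0, abs=1e-3)

    def test_mass_within_three_sigma_per_axis(self):
        """>= 99.7% of a bead's mass lies within +-3 sigma along each axis."""
        vol = voxelize(_chain([[0.0, 0.0, 0.0]]), voxel_size=1.0, sigma=4.0)
        for d in range(3):
            c = vol.origin[d] + (np.arange(vol.shape[d]) + 0.5) * vol.voxel_size
            axes = tuple(a for a in range(3) if a != d)
            marginal = vol.data.sum(axis=axes)
            assert marginal[np.abs(c) <= 3 * 4.0].sum() >= 0.997

    def test_mass_conserved_for_chain(self, tiny_chain):
        vol = voxelize(tiny_chain, voxel_size=4.0, sigma=5.0)
        assert vol.total_mass == pytest.approx(tiny_chain.n_beads, rel=1e-3)

    def test_parameter_errors(self, tiny_chain):
        with pytest.raises(ValueError):
            voxelize(tiny_chain, voxel_size=0.0)
        with pytest.raises(ValueError):
            voxelize(tiny_chain, sigma=-1.0)


class TestSlabProjection:
    def _uniform_volume(self):
        return DensityVolume(data=np.ones((8, 8, 10)), voxel_size=10.0,
                             origin=np.zeros(3), deposition_sigma=5.0)

    def test_uniform_volume_projects_uniformly(self):
        img = slab_projection(self._uniform_volume(), z_center=50.0,
                              thickness=40.0)
        assert np.allclose(img, img.flat[0])

    def test_projection_is_linear_in_slabs(self):
        vol = DensityVolume(data=np.arange(8 * 8 * 10, dtype=float)
                            .reshape(8, 8, 10),
                            voxel_size=10.0, origin=np.zeros(3),
                            deposition_sigma=5.0)
        full = slab_projection(vol, z_center=50.0, thickness=100.0)
        lower = slab_projection(vol, z_center=25.0, thickness=50.0)
        upper = slab_projection(vol, z_center=75.0, thickness=50.0)
        np.testing.assert_allclose(full, lower + upper)

    def test_single_bead_blob_mass(self):
        vol = voxelize(_chain([[0.0, 0.0, 0.0]]), voxel_size=2.0, sigma=4.0)
        img = slab_projection(vol, z_center=0.0,
                              thickness=vol.shape[2] * vol.voxel_size)
        assert img.sum() == pytest.approx(1.0, abs=1e-3)
        assert img.max() > 0.01  # concentrated blob, not spread flat

    def test_slab_outside_volume(self):
        with pytest.raises(ValueError):
            slab_projection(self._uniform_volume(), z_center=500.0,
                            thickness=40.0)


class TestEnhance:
    def test_constant_image_stays_constant(self):
        img = enhance(np.full((64, 64), 3.0), clahe_block_px=16)
        assert np.allclose(img, img.flat[0])
        assert 0.0 <= img.min() and img.max() <= 1.0

    def test_output_range(self, rng):
        img = enhance(rng.random((128, 128)), clahe_block_px=32)
        assert img.min() >= 0.0
        assert img.max() <= 1.0

    def test_delta_spike_spreads_with_kernel(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        smoothed = enhance(img, gaussian_radius_px=3.0, clahe_block_px=16)
        peak = np.unravel_index(np.argmax(smoothed), smoothed.shape)
        assert abs(peak[0] - 32) <= 1 and abs(peak[1] - 32) <= 1
        # mass is no longer a delta: neighbourhood carries signal
        assert smoothed[32, 35] > 0.1 * smoothed[32, 32]

    def test_block_larger_than_image(self):
        with pytest.raises(ValueError):
            enhance(np.zeros((32, 32)), clahe_block_px=64)


def _gaussian_blob(shape, center, sigma, amplitude=1.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-(((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                                / (2 * sigma ** 2)))


class TestFindDomainCenters:
    def test_two_blobs_found_at_peaks(self):
        img = (_gaussian_blob((128, 128), (40, 40), 6)
               + _gaussian_blob((128, 128), (90, 85), 6))
        centers = find_domain_centers(img, min_distance=5)
        assert len(centers) == 2
        found = {tuple(c) for c in centers}
        assert any(abs(r - 40) <= 2 and abs(c - 40) <= 2 for r, c in found)
        assert any(abs(r - 90) <= 2 and abs(c - 85) <= 2 for r, c in found)

    def test_uniform_image_has_no_centers(self):
        assert len(find_domain_centers(np.full((64, 64), 2.0))) == 0

    def test_single_blob(self):
        img = _gaussian_blob((96, 96), (48, 48), 8)
        centers = find_domain_centers(img)
        assert len(centers) == 1


def _power_law_blob(shape, center, r0, background):
    """Decreasing radial density rho ~ r**-0.5 out to r0, then background.

    In 2D, M(r) = int 2 pi u rho(u) du ~ r**1.5 inside the blob, so the
    mass scaling is an exact power law that breaks at r0.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.maximum(np.hypot(yy - center[0], xx - center[1]), 0.5)
    return np.where(r <= r0, r ** -0.5, background)


class TestDomainRadius:
    @pytest.mark.parametrize("r0", [25, 30, 40])
    def test_powerlaw_deviation_detects_blob_edge(self, r0):
        img = _power_law_blob((200, 200), (100, 100), r0, background=0.005)
        rec = domain_radius(img, (100, 100), voxel_size=2.0, r_max_px=70)
        assert rec.stop_criterion == "powerlaw_deviation"
        assert rec.radius_px == pytest.approx(r0, rel=0.10)
        assert rec.radius_nm == pytest.approx(rec.radius_px * 2.0)
        assert rec.local_D == pytest.approx(1.5, abs=0.15)

    def test_space_filling_limit_triggers(self):
        """A planar uniform disk scales with the space-filling exponent of
        the plane; with the planar limit the fit stops immediately."""
        img = np.ones((160, 160))
        rec = domain_radius(img, (80, 80), voxel_size=2.0, r_max_px=40,
                            d_limit=2.0, deviation=0.5)
        assert rec.stop_criterion == "local_D_limit"

    def test_cvc_minimum_detected(self):
        """Shell density dipping at r1 then rising triggers criterion 3."""
        r1 = 25
        yy, xx = np.mgrid[0:160, 0:160]
        r = np.maximum(np.hypot(yy - 80, xx - 80), 0.5)
        img = 0.5 + ((r - r1) / r1) ** 2
        rec = domain_radius(img, (80, 80), voxel_size=2.0, r_max_px=50,
                            d_limit=10.0, deviation=10.0)
        assert rec.stop_criterion == "cvc_minimum"
        assert rec.radius_px == pytest.approx(r1, abs=3)

    def test_edge_center_rejected(self):
        img = np.ones((64, 64))
        with pytest.raises(ValueError):
            domain_radius(img, (2, 2), voxel_size=2.0, r_max_px=30)


class TestDomainStatistics:
    def _rec(self, radius):
        return DomainRecord(center_px=(0, 0), radius_px=radius / 2.0,
                            radius_nm=radius, stop_criterion="cvc_minimum",
                            local_D=2.5, radial_cvc=np.zeros(3))

    def test_single_record(self):
        st = domain_statistics([self._rec(80.0)])
        assert st.mean_radius_nm == 80.0
        assert st.n_domains == 1

    def test_grouped_counts(self):
        st = domain_statistics([[self._rec(60), self._rec(100)],
                                [self._rec(80)]])
        np.testing.assert_array_equal(st.counts_per_config, [2, 1])
        assert st.n_domains == 3
        assert st.mean_radius_nm == pytest.approx(80.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            domain_statistics([])
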