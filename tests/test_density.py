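"""Tests for CVC, coordination numbers, g(r)/G(r) and local packing stats."""

import numpy as np
import pytest

from srev.density import (LocalStats, RadialProfile, coordination_numbers,
                          cvc_distribution, di_phi_correlation,
                          ensemble_pair_correlation, local_stats,
                          local_volume_fraction, packing_exponent,
                          pair_correlation, pair_correlation_bruteforce)
from srev.excluded_volume import BeadChain


def _chain(pos, radius=4.9):
    pos = np.asarray(pos, dtype=float)
    return BeadChain(positions=pos, bead_radius=radius,
                     bond_rest_lengths=np.full(max(len(pos) - 1, 0), 10.0))


def _uniform_sphere(n, radius, rng):
    pts = rng.normal(size=(int(n * 2.5), 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= radius * rng.random(len(pts))[:, None] ** (1 / 3)
    return pts[:n]


def _fcc_lattice(nn_dist, n_cells):
    """FCC points with nearest-neighbour distance ``nn_dist``."""
    a = nn_dist * np.sqrt(2.0)
    base = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    cells = np.mgrid[0:n_cells, 0:n_cells, 0:n_cells].reshape(3, -1).T
    pts = (cells[:, None, :] + base[None, :, :]).reshape(-1, 3) * a
    return pts - pts.mean(axis=0)


class TestCVC:
    def test_empty_cells_report_zero(self):
        chain = _chain([[0, 0, 0], [10, 0, 0]])
        vals = cvc_distribution(chain, grid_shape=(4, 4, 4), cell_edge=50.0)
        assert vals.min() == 0.0
        assert len(vals) == 64

    def test_uniform_beads_center_on_overall_phi(self, rng):
        """Poisson oracle: cell mean ~ phi, spread ~ sqrt(lam)*v/Vcell."""
        r_box, edge = 300.0, 100.0
        v_bead = 4 / 3 * np.pi * 4.9 ** 3
        phi = 0.05
        n = int(phi * (2 * r_box) ** 3 / v_bead)
        pts = rng.uniform(-r_box, r_box, size=(n, 3))
        vals = cvc_distribution(_chain(pts), grid_shape=(4, 4, 4),
                                cell_edge=edge)
        lam = phi * edge ** 3 / v_bead
        sigma_cell = np.sqrt(lam) * v_bead / edge ** 3
        assert vals.mean() == pytest.approx(phi,
                                            abs=4 * sigma_cell / np.sqrt(64))

    def test_support_physical(self, tiny_chain):
        vals = cvc_distribution(tiny_chain, grid_shape=(3, 3, 3),
                                cell_edge=60.0)
        assert vals.min() >= 0.0
        assert vals.max() <= 0.74

    def test_oversized_grid_warns(self, tiny_chain):
        with pytest.warns(UserWarning):
            cvc_distribution(tiny_chain, grid_shape=(6, 6, 6),
                             cell_edge=120.0)


class TestCoordinationNumbers:
    def test_isolated_and_dimer(self):
        cn = coordination_numbers(_chain([[0, 0, 0], [10, 0, 0],
                                          [500, 0, 0]]), radius=11.5)
        np.testing.assert_array_equal(cn, [1, 1, 0])

    def test_fcc_interior_reaches_twelve(self):
        pts = _fcc_lattice(9.8, 5)
        cn = coordination_numbers(_chain(pts), radius=11.5)
        assert cn.max() == 12

    def test_fixture_range(self, tiny_chain):
        cn = coordination_numbers(tiny_chain)
        assert cn.min() >= 0
        assert cn.max() <= 13  # 12 plus at most a stretched bonded neighbour

    def test_invalid_radius(self, tiny_chain):
        with pytest.raises(ValueError):
            coordination_numbers(tiny_chain, radius=0.0)


class TestPairCorrelation:
    def test_ideal_gas_gives_unit_g_and_cubic_G(self, rng):
        pts = _uniform_sphere(30_000, 200.0, rng)
        prof = pair_correlation(_chain(pts), r_max=60.0, dr=2.0)
        mid = prof.r > 10
        assert np.abs(prof.g[mid] - 1.0).mean() < 0.05
        expected = 4 / 3 * np.pi * prof.r_outer ** 3
        sel = prof.r_outer > 20
        assert np.abs(prof.G[sel] / expected[sel] - 1.0).max() < 0.05

    def test_excluded_volume_hole(self, tiny_chain):
        prof = pair_correlation(tiny_chain, r_max=40.0, dr=0.5)
        hole = prof.r < 9.8 * (1 - 0.01) - 0.5
        assert prof.g[hole].max() < 0.05

    def test_G_monotone(self, tiny_chain):
        prof = pair_correlation(tiny_chain, r_max=50.0, dr=1.0)
        assert np.all(np.diff(prof.G) >= 0)

    def test_tree_matches_bruteforce(self, tiny_chain):
        a = pair_correlation(tiny_chain, r_max=40.0, dr=1.0)
        b = pair_correlation_bruteforce(tiny_chain, r_max=40.0, dr=1.0)
        np.testing.assert_allclose(a.g, b.g, rtol=1e-10)
        np.testing.assert_allclose(a.G, b.G, rtol=1e-10)

    def test_parameter_errors(self, tiny_chain):
        with pytest.raises(ValueError):
            pair_correlation(tiny_chain, r_max=40.0, dr=0.0)
        with pytest.raises(ValueError):
            pair_correlation(tiny_chain, r_max=1e4)


class TestPackingExponent:
    def _profile(self, exponent):
        r = np.arange(1.0, 200.0)
        G = 2.0 * r ** exponent
        return RadialProfile(r=r, g=np.zeros_like(r), G=G, n_centers=1,
                             density=1.0)

    @pytest.mark.parametrize("d", [3.0, 2.0, 2.5])
    def test_exact_recovery(self, d):
        assert packing_exponent(self._profile(d)) == pytest.approx(d)

    def test_range_outside_profile(self):
        prof = self._profile(3.0)
        with pytest.raises(ValueError):
            packing_exponent(prof, (150.0, 400.0))

    def test_annotates_profile(self):
        prof = self._profile(2.5)
        packing_exponent(prof, (40.0, 120.0))
        assert prof.fit_D == pytest.approx(2.5)
        assert prof.fit_range == (40.0, 120.0)


class TestLocalVolumeFraction:
    def test_empty_sphere(self):
        chain = _chain([[500.0, 0, 0], [510.0, 0, 0]])
        assert local_volume_fraction(chain, [0, 0, 0], 100.0) == 0.0

    def test_single_interior_bead(self):
        chain = _chain([[0.0, 0, 0], [500.0, 0, 0]])
        phi = local_volume_fraction(chain, [0, 0, 0], 240.0)
        assert phi == pytest.approx((4.9 / 240.0) ** 3, rel=1e-9)

    def test_boundary_bead_clips_to_exact_lens(self):
        """A bead centred on the probe surface contributes the exact
        sphere-sphere intersection: half its volume minus the convex-
        boundary correction pi r^4 / (4 R)."""
        r0, R = 4.9, 100.0
        chain = _chain([[R, 0, 0], [500.0, 0, 0]])
        phi = local_volume_fraction(chain, [0, 0, 0], R)
        v_probe = 4 / 3 * np.pi * R ** 3
        expected = (0.5 * 4 / 3 * np.pi * r0 ** 3
                    - np.pi * r0 ** 4 / (4 * R)) / v_probe
        assert phi == pytest.approx(expected, rel=1e-9)

    def test_fcc_packing_approaches_crystal_fraction(self):
        pts = _fcc_lattice(9.8, 14)
        chain = _chain(pts)
        phi = local_volume_fraction(chain, [0, 0, 0], 50.0)
        assert phi == pytest.approx(0.7405, abs=0.02)


class TestDiPhiCorrelation:
    def _stats(self, phis, ds):
        return [LocalStats(config_id=i, D_i=d, phi_i=p)
                for i, (p, d) in enumerate(zip(phis, ds))]

    def test_monotone_relation_gives_unit_correlation(self):
        phi = np.linspace(0.05, 0.5, 20)
        _, rho, _ = di_phi_correlation(self._stats(phi, 2 + phi))
        assert rho == pytest.approx(1.0)

    def test_shuffled_pairs_are_uncorrelated(self, rng):
        phi = np.linspace(0.05, 0.5, 200)
        d = 2 + rng.permutation(phi)
        _, rho, _ = di_phi_correlation(self._stats(phi, d))
        assert abs(rho) < 0.2

    def test_degenerate_inputs_flagged(self):
        with pytest.raises(ValueError, match="degenerate"):
            di_phi_correlation(self._stats(np.full(12, 0.2),
                                           np.linspace(2, 3, 12)))

    def test_requires_ten_configs(self):
        with pytest.raises(ValueError):
            di_phi_correlation(self._stats([0.1] * 5, [2.0] * 5))


class TestLocalStats:
    def test_probe_must_exceed_fit_range(self, tiny_chain):
        with pytest.raises(ValueError):
            local_stats(tiny_chain, probe_radius=100.0,
                        fit_range=(40.0, 120.0))

    def test_fixture_values_physical(self, tiny_chain):
        s = local_stats(tiny_chain, probe_radius=80.0, fit_range=(15.0, 45.0))
        assert 0.0 < s.phi_i < 0.74
        assert 1.0 < s.D_i < 4.0
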