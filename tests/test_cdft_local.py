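"""Condensed and grid Fukui functions, dual descriptor, site ranking."""

import numpy as np
import pytest

from cdftkit.cdft_local import (
    condensed_fukui,
    grid_fukui,
    grid_integral,
    rank_sites,
)
from cdftkit.qm_io import ChargeSet, VolumetricGrid
from cdftkit.synthetic import make_charge_triplet, make_grid_triplet


def _charge_set(q, net, scheme="Mulliken", labels=None):
    labels = labels or tuple(f"C{i+1}" for i in range(len(q)))
    return ChargeSet(scheme, tuple(labels), tuple(q), net)


class TestCondensedFukui:
    def test_direct_differences(self):
        cf = condensed_fukui(
            _charge_set([0.0, 0.0], 0),
            _charge_set([0.6, 0.4], 1),
            _charge_set([-0.7, -0.3], -1),
        )
        assert cf.f_minus == pytest.approx((0.6, 0.4))
        assert cf.f_plus == pytest.approx((0.7, 0.3))
        assert cf.dual == pytest.approx((0.1, -0.1))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_per_atom_subtraction_oracle(self, seed):
        q_n, q_cat, q_an = make_charge_triplet(seed, n_atoms=7)
        cf = condensed_fukui(q_n, q_cat, q_an)
        # independent oracle: plain per-atom Python subtraction
        for k in range(7):
            f_minus_k = q_cat.q[k] - q_n.q[k]
            f_plus_k = q_n.q[k] - q_an.q[k]
            assert abs(cf.f_minus[k] - f_minus_k) < 1e-12
            assert abs(cf.f_plus[k] - f_plus_k) < 1e-12
            assert abs(cf.dual[k] - (f_plus_k - f_minus_k)) < 1e-12
        s_minus, s_plus, s_dual = cf.sums()
        assert s_minus == pytest.approx(1.0, abs=1e-6)
        assert s_plus == pytest.approx(1.0, abs=1e-6)
        assert s_dual == pytest.approx(0.0, abs=1e-6)

    def test_conservation_noise_shifts_sums_linearly(self):
        eps = 3e-4
        q_n, q_cat, q_an = make_charge_triplet(11, 9, conservation_noise=eps)
        cf = condensed_fukui(q_n, q_cat, q_an)
        s_minus, s_plus, _ = cf.sums()
        # +eps on the cation inflates sum(f-); +eps on the anion deflates
        # sum(f+) by the same amount
        assert s_minus - 1.0 == pytest.approx(eps, abs=1e-12)
        assert s_plus - 1.0 == pytest.approx(-eps, abs=1e-12)

    def test_scheme_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            condensed_fukui(
                _charge_set([0.0], 0, scheme="Mulliken"),
                _charge_set([1.0], 1, scheme="Hirshfeld"),
                _charge_set([-1.0], -1, scheme="Mulliken"),
            )

    def test_atom_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="atom count"):
            condensed_fukui(
                _charge_set([0.0, 0.0], 0),
                _charge_set([1.0], 1),
                _charge_set([-0.5, -0.5], -1),
            )

    def test_wrong_ionic_charges_rejected(self):
        neutral = _charge_set([0.0], 0)
        anion = _charge_set([-1.0], -1)
        with pytest.raises(ValueError, match="net charge"):
            condensed_fukui(neutral, anion, anion)


class TestGridFukui:
    def test_constructed_blob_identity(self, bundle):
        rho_n, rho_cat, rho_an = bundle.grid_triplet
        f_minus, f_plus, dual = grid_fukui(rho_n, rho_cat, rho_an)
        blob = rho_n.values - rho_cat.values
        assert np.allclose(f_minus.values, blob, atol=1e-14)
        assert np.allclose(dual.values, f_plus.values - f_minus.values, atol=1e-14)

    def test_normalization_against_analytic_construction(self, bundle):
        f_minus, f_plus, dual = grid_fukui(*bundle.grid_triplet)
        assert grid_integral(f_minus) == pytest.approx(1.0, abs=1e-3)
        assert grid_integral(f_plus) == pytest.approx(1.0, abs=1e-3)
        assert grid_integral(dual) == pytest.approx(0.0, abs=1e-3)

    def test_linearity_under_density_scaling(self, bundle):
        rho_n, rho_cat, rho_an = bundle.grid_triplet
        c = 2.5
        scaled = grid_fukui(
            rho_n.with_values(c * rho_n.values),
            rho_cat.with_values(c * rho_cat.values),
            rho_an.with_values(c * rho_an.values),
        )
        plain = grid_fukui(rho_n, rho_cat, rho_an)
        for s, p in zip(scaled, plain):
            assert np.allclose(s.values, c * p.values, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = VolumetricGrid(np.zeros(3), np.eye(3), (2, 2, 2), [], np.ones((2, 2, 2)))
        b = VolumetricGrid(np.zeros(3), np.eye(3), (3, 3, 3), [], np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="congruent"):
            grid_fukui(a, b, a)


class TestGridIntegral:
    def test_uniform_field(self):
        g = VolumetricGrid(np.zeros(3), np.eye(3), (10, 10, 10), [],
                           np.ones((10, 10, 10)))
        assert grid_integral(g) == pytest.approx(1000.0)

    def test_gaussian_closed_form(self):
        # fine grid: Riemann sum vs A (2 pi)^{3/2} sigma^3
        n, L, sigma, amp = 48, 16.0, 1.3, 0.7
        h = L / n
        axis = (np.arange(n) + 0.5) * h - L / 2
        x, y, z = np.meshgrid(axis, axis, axis, indexing="ij")
        vals = amp * np.exp(-(x**2 + y**2 + z**2) / (2 * sigma**2))
        g = VolumetricGrid(np.full(3, h / 2 - L / 2), np.diag([h, h, h]),
                           (n, n, n), [], vals)
        exact = amp * (2 * np.pi) ** 1.5 * sigma**3
        assert grid_integral(g) == pytest.approx(exact, rel=1e-3)

    def test_zero_field_and_linearity(self):
        rng = np.random.default_rng(3)
        counts = (4, 5, 6)
        axes = np.diag(rng.uniform(0.5, 1.5, 3))
        a = VolumetricGrid(np.zeros(3), axes, counts, [], rng.normal(size=counts))
        b = VolumetricGrid(np.zeros(3), axes, counts, [], rng.normal(size=counts))
        zero = a.with_values(np.zeros(counts))
        assert grid_integral(zero) == 0.0
        total = a.with_values(a.values + b.values)
        assert grid_integral(total) == pytest.approx(
            grid_integral(a) + grid_integral(b), abs=1e-12
        )


class TestRankSites:
    @pytest.fixture()
    def cf(self):
        return condensed_fukui(
            _charge_set([0.0, 0.0, 0.0], 0),
            _charge_set([0.1, 0.5, 0.4], 1),
            _charge_set([-0.2, -0.3, -0.5], -1),
        )

    def test_top_k_descending(self, cf):
        assert rank_sites(cf, "f_minus", 2) == [(2, pytest.approx(0.5)),
                                                (3, pytest.approx(0.4))]

    def test_tie_breaks_toward_lower_index(self):
        cf = condensed_fukui(
            _charge_set([0.0, 0.0], 0),
            _charge_set([0.5, 0.5], 1),
            _charge_set([-0.5, -0.5], -1),
        )
        assert rank_sites(cf, "f_minus", 1) == [(1, pytest.approx(0.5))]

    def test_k_zero_and_bounds(self, cf):
        assert rank_sites(cf, "f_plus", 0) == []
        with pytest.raises(ValueError, match="out of range"):
            rank_sites(cf, "f_plus", 4)
        with pytest.raises(ValueError, match="selector"):
            rank_sites(cf, "f_sideways", 1)
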