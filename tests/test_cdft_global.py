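"""Global reactivity descriptors, lambda_max and KID diagnostics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cdftkit.cdft_global import (
    DegenerateFrontierError,
    FrontierEnergies,
    finite_difference_ia,
    frontier_from_spectrum,
    global_descriptors,
    kid_diagnostics,
    lambda_max,
    vertical_ia,
)
from cdftkit.qm_io import OrbitalSpectrum
from cdftkit.units import HARTREE_TO_EV, HC_EV_NM

TALTOBULIN_FRONTIER = FrontierEnergies(e_homo=-6.240, e_lumo=-1.733)

frontiers = st.tuples(
    st.floats(-15.0, -1.0), st.floats(0.05, 12.0)
).map(lambda t: FrontierEnergies(t[0], t[0] + t[1]))


class TestFrontierExtraction:
    def test_frontier_from_spectrum(self, bundle):
        f = frontier_from_spectrum(bundle.spectrum)
        assert f.e_homo == pytest.approx(-6.240, abs=1e-12)
        assert f.e_lumo == pytest.approx(-1.733, abs=1e-9)

    def test_degenerate_homo(self):
        spec = OrbitalSpectrum((-5.0, -5.0, 1.0), (2, 2, 0), 4)
        assert frontier_from_spectrum(spec).e_homo == -5.0

    def test_fully_occupied_spectrum_rejected(self):
        spec = OrbitalSpectrum((-5.0, -4.0), (2, 2), 4)
        with pytest.raises(ValueError, match="unoccupied"):
            frontier_from_spectrum(spec)

    def test_gap_must_be_positive(self):
        with pytest.raises(ValueError, match="exceed"):
            FrontierEnergies(-5.0, -5.0)

    @pytest.mark.parametrize(
        "f,expected",
        [
            (TALTOBULIN_FRONTIER, (6.240, 1.733)),
            (FrontierEnergies(-4.2, 0.0), (4.2, 0.0)),
            (FrontierEnergies(-6.0, 1.0), (6.0, -1.0)),  # unbound anion, A < 0
        ],
    )
    def test_vertical_ia_signs(self, f, expected):
        assert vertical_ia(f) == pytest.approx(expected)


class TestGlobalDescriptors:
    def test_taltobulin_block_matches_reference(self):
        d = global_descriptors(TALTOBULIN_FRONTIER)
        assert d.chi == pytest.approx(3.986, abs=0.005)
        assert d.eta == pytest.approx(4.507, abs=1e-12)
        assert d.omega == pytest.approx(1.763, abs=0.005)
        assert d.omega_minus == pytest.approx(5.800, abs=0.005)
        assert d.omega_plus == pytest.approx(1.814, abs=0.005)
        assert d.net_electrophilicity == pytest.approx(7.614, abs=0.005)
        assert d.mu == -d.chi
        assert d.softness == pytest.approx(1.0 / d.eta)

    def test_hand_forced_arithmetic(self):
        d = global_descriptors(FrontierEnergies(-2.0, 0.0))
        assert d.chi == 1.0
        assert d.eta == 2.0
        assert d.omega == 0.25
        assert d.omega_minus == 1.125
        assert d.omega_plus == 0.125
        assert d.net_electrophilicity == 1.25
        assert d.omega_minus - d.omega_plus == pytest.approx(d.chi, abs=1e-15)

    def test_degenerate_gap_raises(self):
        f = FrontierEnergies(-5.0, -5.0 + 1e-12)
        with pytest.raises(DegenerateFrontierError, match="degenerate"):
            global_descriptors(f)

    @given(frontiers)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_donating_accepting_identity(self, f):
        d = global_descriptors(f)
        assert abs((d.omega_minus - d.omega_plus) - d.chi) < 1e-10
        assert d.net_electrophilicity == d.omega_minus + d.omega_plus
        assert d.eta > 0

    def test_donating_exceeds_accepting_for_electron_rich(self):
        # I > A > 0 and chi > 0 implies omega- >= omega+
        for f in (TALTOBULIN_FRONTIER, FrontierEnergies(-8.0, -0.5)):
            d = global_descriptors(f)
            assert d.omega_minus >= d.omega_plus

    def test_monotone_in_ionization_energy(self):
        # chi is monotone in I everywhere; omega- is once I > 7A/3 and
        # omega+ only past I = 5A (d/dI has a sign change at each of
        # those points), so monotonicity is asserted on ranges where it
        # actually holds
        a = 1.0
        prev = None
        for i in [3.0, 5.0, 8.0, 12.0]:
            d = global_descriptors(FrontierEnergies(-i, -a))
            if prev is not None:
                assert d.chi > prev.chi
                assert d.omega_minus > prev.omega_minus
            prev = d
        prev = None
        for i in [6.0, 8.0, 12.0]:  # past 5A
            d = global_descriptors(FrontierEnergies(-i, -a))
            if prev is not None:
                assert d.omega_plus > prev.omega_plus
            prev = d


class TestLambdaMax:
    def test_taltobulin_wavelength(self):
        lam = lambda_max(TALTOBULIN_FRONTIER)
        assert lam == pytest.approx(275.09, abs=0.01)
        assert round(lam) == 275

    def test_two_ev_gap(self):
        assert lambda_max(FrontierEnergies(-3.0, -1.0)) == pytest.approx(
            619.921, abs=1e-3
        )

    @given(st.floats(0.1, 15.0))
    @settings(deadline=None, derandomize=True)
    def test_wavelength_gap_product_is_hc(self, gap):
        f = FrontierEnergies(-gap, 0.0)
        assert abs(lambda_max(f) * f.gap - HC_EV_NM) < 1e-9


class TestKidDiagnostics:
    def test_exact_koopmans_limit_is_zero(self):
        # Delta-SCF gaps of exactly 1.0 and 0.5 hartree make the float
        # arithmetic exact, so the diagnostics are exactly zero.
        f = FrontierEnergies(-HARTREE_TO_EV, -0.5 * HARTREE_TO_EV)
        k = kid_diagnostics(e_n=-100.0, e_nm1=-99.0, e_np1=-100.5, f=f)
        assert (k.j_i, k.j_a, k.j_hl) == (0.0, 0.0, 0.0)

    def test_fixture_energies_koopmans_consistent(self, bundle):
        f = frontier_from_spectrum(bundle.spectrum)
        k = kid_diagnostics(
            bundle.qm_results["N"].total_energy,
            bundle.qm_results["N-1"].total_energy,
            bundle.qm_results["N+1"].total_energy,
            f,
        )
        assert k.j_hl < 1e-9

    def test_hand_arithmetic_hypotenuse(self):
        # 0.2 eV deviation on each leg -> sqrt(0.08)
        f = FrontierEnergies(-6.0, -1.7)
        e_n = 0.0
        e_nm1 = (6.0 + 0.2) / HARTREE_TO_EV
        e_np1 = -(1.7 + 0.2) / HARTREE_TO_EV
        k = kid_diagnostics(e_n, e_nm1, e_np1, f)
        assert k.j_i == pytest.approx(0.2, abs=1e-9)
        assert k.j_a == pytest.approx(0.2, abs=1e-9)
        assert k.j_hl == pytest.approx(0.28284, abs=1e-5)
        assert k.j_hl == pytest.approx(math.hypot(k.j_i, k.j_a), abs=1e-12)

    def test_missing_ion_energy_rejected(self):
        f = FrontierEnergies(-6.0, -1.7)
        with pytest.raises(ValueError, match="e_nm1"):
            kid_diagnostics(0.0, None, -0.1, f)


class TestFiniteDifferenceIA:
    def test_ev_inputs(self):
        i, a = finite_difference_ia(-100.00, -99.77, -100.06, unit="eV")
        assert (i, a) == (pytest.approx(0.23), pytest.approx(0.06))

    def test_hartree_conversion(self):
        i, a = finite_difference_ia(-10.00, -9.99, -10.01)
        assert i == pytest.approx(0.27211386, abs=1e-8)
        assert a == pytest.approx(0.27211386, abs=1e-8)

    def test_symmetric_case_degenerates_downstream(self):
        i, a = finite_difference_ia(0.0, 0.1, -0.1)
        assert i == pytest.approx(a)
        with pytest.raises(ValueError):
            FrontierEnergies(-i, -a)

    def test_missing_input_rejected(self):
        with pytest.raises(ValueError, match="e_np1"):
            finite_difference_ia(0.0, 0.1, None)
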