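"""Global reactivity descriptors from frontier-orbital energies.

Within conceptual DFT the first ionization energy I and electron affinity
A of a species determine a family of global reactivity indices.  Under the
Koopmans-like frontier approximation (valid for range-separated functionals
tuned so that -e_HOMO ~ I and -e_LUMO ~ A) these become functions of the
HOMO and LUMO energies alone:

    I = -e_HOMO                 A = -e_LUMO
    chi = (I + A) / 2           electronegativity,  mu = -chi
    eta = I - A                 global hardness (full-gap convention)
    S = 1 / eta                 global softness
    omega  = chi^2 / (2 eta)    electrophilicity index
    omega- = (3I + A)^2 / (16 eta)   electrodonating power
    omega+ = (I + 3A)^2 / (16 eta)   electroaccepting power
    d_omega = omega- + omega+   net electrophilicity

The identity omega- - omega+ = chi holds algebraically and is used as a
consistency invariant.  The HOMO-LUMO gap also yields a zeroth-order
estimate of the lowest excitation energy, hence a maximum-absorption
wavelength lambda_max = hc / gap.

The quality of the frontier approximation for a given model chemistry is
quantified by the Koopmans-in-DFT (KID) diagnostics, which compare the
frontier energies against Delta-SCF energies of the N-1/N+1 electron
states:

    J_I  = |e_HOMO + E(N-1) - E(N)|
    J_A  = |e_LUMO + E(N) - E(N+1)|
    J_HL = sqrt(J_I^2 + J_A^2)

Values of a few tenths of an eV or less justify using the frontier route.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .qm_io import OrbitalSpectrum
from .units import HARTREE_TO_EV, HC_EV_NM

__all__ = [
    "DegenerateFrontierError",
    "FrontierEnergies",
    "GlobalDescriptors",
    "KidDiagnostics",
    "frontier_from_spectrum",
    "vertical_ia",
    "global_descriptors",
    "lambda_max",
    "kid_diagnostics",
    "finite_difference_ia",
]

#: Below this HOMO-LUMO gap (eV) the hardness-based descriptors diverge.
GAP_TOLERANCE_EV = 1e-9


class DegenerateFrontierError(ValueError):
    """HOMO-LUMO gap too small for hardness-based descriptors."""


@dataclass(frozen=True)
class FrontierEnergies:
    """HOMO and LUMO energies in eV; the gap must be strictly positive."""

    e_homo: float
    e_lumo: float

    def __post_init__(self) -> None:
        if not self.e_lumo > self.e_homo:
            raise ValueError(
                f"e_lumo ({self.e_lumo}) must exceed e_homo ({self.e_homo})"
            )

    @property
    def gap(self) -> float:
        return self.e_lumo - self.e_homo


@dataclass(frozen=True)
class GlobalDescriptors:
    """The full global-reactivity record for one species (eV except as noted)."""

    i_vertical: float
    a_vertical: float
    chi: float
    mu: float
    eta: float
    softness: float  # eV^-1
    omega: float
    omega_minus: float
    omega_plus: float
    net_electrophilicity: float
    lambda_max: float  # nm

    def as_dict(self) -> dict[str, float]:
        return {
            "I_eV": self.i_vertical,
            "A_eV": self.a_vertical,
            "chi_eV": self.chi,
            "mu_eV": self.mu,
            "eta_eV": self.eta,
            "S_eV^-1": self.softness,
            "omega_eV": self.omega,
            "omega_minus_eV": self.omega_minus,
            "omega_plus_eV": self.omega_plus,
            "net_electrophilicity_eV": self.net_electrophilicity,
            "lambda_max_nm": self.lambda_max,
        }


@dataclass(frozen=True)
class KidDiagnostics:
    """Koopmans-in-DFT agreement diagnostics (eV, all non-negative)."""

    j_i: float
    j_a: float
    j_hl: float


def frontier_from_spectrum(spectrum: OrbitalSpectrum) -> FrontierEnergies:
    """Extract HOMO/LUMO energies from an orbital spectrum.

    HOMO is the highest-energy orbital with occupation > 0; LUMO the
    lowest-energy one with occupation 0.
    """
    occ = [e for e, o in zip(spectrum.energies, spectrum.occupations) if o > 0]
    virt = [e for e, o in zip(spectrum.energies, spectrum.occupations) if o == 0]
    if not occ:
        raise ValueError("spectrum has no occupied orbital")
    if not virt:
        raise ValueError("spectrum has no unoccupied orbital: cannot place a LUMO")
    return FrontierEnergies(e_homo=max(occ), e_lumo=min(virt))


def vertical_ia(f: FrontierEnergies) -> tuple[float, float]:
    """Vertical I and A in the frontier approximation: (-e_HOMO, -e_LUMO).

    A negative A (positive LUMO: unbound anion) is allowed and passed
    through unchanged.
    """
    return (-f.e_homo, -f.e_lumo)


def global_descriptors(f: FrontierEnergies) -> GlobalDescriptors:
    """Compute the full global descriptor block from frontier energies.

    Values are kept unrounded; the reporting layer rounds eV quantities to
    3 decimals and lambda_max to integer nm.
    """
    i, a = vertical_ia(f)
    eta = i - a
    if eta <= GAP_TOLERANCE_EV:
        raise DegenerateFrontierError(
            f"degenerate frontier: gap {eta:.3e} eV <= {GAP_TOLERANCE_EV} eV"
        )
    chi = 0.5 * (i + a)
    omega_minus = (3.0 * i + a) ** 2 / (16.0 * eta)
    omega_plus = (i + 3.0 * a) ** 2 / (16.0 * eta)
    return GlobalDescriptors(
        i_vertical=i,
        a_vertical=a,
        chi=chi,
        mu=-chi,
        eta=eta,
        softness=1.0 / eta,
        omega=chi * chi / (2.0 * eta),
        omega_minus=omega_minus,
        omega_plus=omega_plus,
        net_electrophilicity=omega_minus + omega_plus,
        lambda_max=lambda_max(f),
    )


def lambda_max(f: FrontierEnergies) -> float:
    """Maximum-absorption wavelength (nm) from the HOMO-LUMO gap."""
    if f.gap <= 0:
        raise DegenerateFrontierError("non-positive gap: no excitation wavelength")
    return HC_EV_NM / f.gap


def kid_diagnostics(
    e_n: float, e_nm1: float, e_np1: float, f: FrontierEnergies
) -> KidDiagnostics:
    """KID diagnostics from N/N-1/N+1 total energies (hartree) and frontier eV.

    All three energies must come from the same model chemistry at the same
    geometry for the diagnostics to be meaningful.
    """
    for name, val in (("e_n", e_n), ("e_nm1", e_nm1), ("e_np1", e_np1)):
        if val is None:
            raise ValueError(f"missing total energy {name!r} for KID diagnostics")
    i_scf = (e_nm1 - e_n) * HARTREE_TO_EV
    a_scf = (e_n - e_np1) * HARTREE_TO_EV
    j_i = abs(f.e_homo + i_scf)
    j_a = abs(f.e_lumo + a_scf)
    return KidDiagnostics(j_i=j_i, j_a=j_a, j_hl=math.hypot(j_i, j_a))


def finite_difference_ia(
    e_n: float, e_nm1: float, e_np1: float, unit: str = "hartree"
) -> tuple[float, float]:
    """Delta-SCF I and A (eV) from N/N-1/N+1 total energies.

    I = E(N-1) - E(N), A = E(N) - E(N+1).  The pair can seed
    :func:`global_descriptors` via ``FrontierEnergies(-I, -A)`` as the
    opt-in alternative to the frontier route.
    """
    for name, val in (("e_n", e_n), ("e_nm1", e_nm1), ("e_np1", e_np1)):
        if val is None:
            raise ValueError(f"missing total energy {name!r}")
    scale = {"hartree": HARTREE_TO_EV, "au": HARTREE_TO_EV, "ev": 1.0}.get(unit.lower())
    if scale is None:
        raise ValueError(f"unknown energy unit {unit!r}")
    return ((e_nm1 - e_n) * scale, (e_n - e_np1) * scale)
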