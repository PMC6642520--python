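"""Physical constants and unit conversions used across the package.

Energy policy: orbital energies are stored in electron-volts, total
electronic energies in hartree; every hartree→eV conversion goes through
the single constant below.
"""

#: 1 hartree in electron-volts (CODATA, truncated to the precision used here).
HARTREE_TO_EV: float = 27.211386

#: h*c in eV·nm, for converting an excitation energy to a wavelength.
HC_EV_NM: float = 1239.841984


def ev_from_hartree(e_hartree: float) -> float:
    return e_hartree * HARTREE_TO_EV


def hartree_from_ev(e_ev: float) -> float:
    return e_ev / HARTREE_TO_EV
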