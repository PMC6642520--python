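"""Seeded generators for every input the pipeline consumes.

Real runs of this pipeline start from quantum-chemistry artifacts that are
expensive to produce and too large to ship.  This module generates
structurally faithful stand-ins — orbital spectra with a prescribed
frontier, charge triplets that conserve their net charges exactly, and
density-grid triplets whose ionization/attachment difference is a sum of
analytically normalized Gaussians — so the whole analysis is exercisable
and checkable offline.  Ground truths for tests are recorded at
generation time from closed forms, never recomputed by the code under
test.

The generated objects emulate the *bookkeeping* of real QM output (units,
orderings, conservation laws, file formats), not its physics: the spectra
are not self-consistent-field solutions and the densities are not
molecular densities.  Every generator is deterministic given its seed.

:func:`taltobulin_fixture` packages the published Taltobulin record — the
frontier energies, neutral total energy, drug-likeness property block and
six bioactivity scores — together with synthetic charge/density triplets,
and self-validates the transcribed SMILES against the published molecular
weight and heavy-atom count before returning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import druglikeness
from .qm_io import (
    ChargeSet,
    OrbitalSpectrum,
    QMResult,
    VolumetricGrid,
    format_charges,
    format_frequencies,
    format_orbital_energies,
    write_cube,
)
from .units import HARTREE_TO_EV

__all__ = [
    "FixtureBundle",
    "make_spectrum",
    "make_charge_triplet",
    "make_grid_triplet",
    "taltobulin_fixture",
    "write_bundle",
    "TALTOBULIN_SMILES",
]

#: Taltobulin (HTI-286) structure, transcribed from its public record;
#: validated at fixture load against MW 473.66 Da and 34 heavy atoms.
TALTOBULIN_SMILES = (
    r"C/C(=C\[C@H](C(C)C)N(C)C(=O)[C@@H](NC(=O)[C@H](NC)C(C)(C)"
    r"C1=CC=CC=C1)C(C)(C)C)/C(=O)O"
)

#: Published Taltobulin reference values used by the acceptance suite.
#: 'chi'..'net_electrophilicity' and the property block are reported
#: numbers; the bundle's synthetic components are built to reproduce the
#: frontier entries by construction.
_TALTOBULIN_EXPECTED = {
    "total_energy_au": -1517.422,
    "e_homo_ev": -6.240,
    "e_lumo_ev": -1.733,
    "lambda_max_nm": 275,
    "chi_ev": 3.986,
    "eta_ev": 4.507,
    "omega_ev": 1.763,
    "omega_minus_ev": 5.800,
    "omega_plus_ev": 1.814,
    "net_electrophilicity_ev": 7.614,
    "milogp": 4.43,
    "tpsa": 98.73,
    "n_atoms": 34,
    "n_on": 7,
    "n_ohnh": 3,
    "nviol": 0,
    "nrotb": 11,
    "volume": 479.94,
    "mw": 473.66,
    "bioactivity": {
        "gpcr": 0.43,
        "ion_channel": 0.15,
        "kinase": -0.12,
        "nuclear_receptor": 0.19,
        "protease": 0.68,
        "enzyme": 0.42,
    },
    "bioactivity_categories": {
        "gpcr": "active",
        "ion_channel": "active",
        "kinase": "moderately active",
        "nuclear_receptor": "active",
        "protease": "active",
        "enzyme": "active",
    },
}


@dataclass
class FixtureBundle:
    """Everything one pipeline run needs, plus construction ground truths.

    ``expected`` holds values known by construction or from the published
    record — it is filled at generation time so tests never compare the
    code under test against itself.
    """

    seed: int
    qm_results: dict[str, QMResult]
    spectrum: OrbitalSpectrum
    charge_triplet: tuple[ChargeSet, ChargeSet, ChargeSet]
    grid_triplet: tuple[VolumetricGrid, VolumetricGrid, VolumetricGrid]
    smiles: str
    bioactivity_inputs: dict[str, float]
    expected: dict = field(default_factory=dict)


def make_spectrum(
    seed: int,
    n_occ: int = 5,
    n_virt: int = 5,
    e_homo: float = -6.240,
    gap: float = 4.507,
) -> OrbitalSpectrum:
    """A closed-shell orbital spectrum with a prescribed frontier.

    The highest occupied orbital sits exactly at ``e_homo`` and the lowest
    virtual at ``e_homo + gap``; the remaining levels are random but
    deterministic per seed, spaced 0.5-2.0 eV apart.
    """
    if n_occ < 1 or n_virt < 1:
        raise ValueError("need at least one occupied and one virtual orbital")
    if gap <= 0:
        raise ValueError(f"gap must be positive, got {gap}")
    rng = np.random.default_rng(seed)
    below = e_homo - np.cumsum(rng.uniform(0.5, 2.0, size=n_occ - 1))
    above = e_homo + gap + np.concatenate(
        [[0.0], np.cumsum(rng.uniform(0.5, 2.0, size=n_virt - 1))]
    )
    energies = tuple(np.sort(below).tolist()) + (e_homo,) + tuple(above.tolist())
    occupations = (2.0,) * n_occ + (0.0,) * n_virt
    return OrbitalSpectrum(energies, occupations, n_electrons=2 * n_occ)


def make_charge_triplet(
    seed: int,
    n_atoms: int,
    scheme: str = "Mulliken",
    conservation_noise: float = 0.0,
) -> tuple[ChargeSet, ChargeSet, ChargeSet]:
    """Exactly conserving (neutral, cation, anion) partial-charge sets.

    The neutral set sums to 0, the cation to +1 and the anion to -1, with
    the last atom absorbing floating-point residue.  ``conservation_noise``
    deliberately breaks the cation/anion sums by +eps (added to the first
    atom) so validation machinery can be probed; it is zero for all
    normal use.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    labels = tuple(f"C{i + 1}" for i in range(n_atoms))

    q_neutral = rng.normal(0.0, 0.3, size=n_atoms)
    q_neutral[-1] -= q_neutral.sum()

    def unit_transfer() -> np.ndarray:
        w = rng.uniform(0.05, 1.0, size=n_atoms)
        w /= w.sum()
        w[-1] += 1.0 - w.sum()
        return w

    q_cation = q_neutral + unit_transfer()
    q_anion = q_neutral - unit_transfer()
    if conservation_noise:
        q_cation = q_cation.copy()
        q_cation[0] += conservation_noise
        q_anion = q_anion.copy()
        q_anion[0] += conservation_noise

    def make(qv: np.ndarray, net: int) -> ChargeSet:
        return ChargeSet(scheme, labels, tuple(qv.tolist()), net)

    return (make(q_neutral, 0), make(q_cation, 1), make(q_anion, -1))


#: Box edge (bohr) for synthetic density grids.
_BOX_LENGTH = 12.0
#: Blob centers keep a 4-sigma margin from every face so the in-box mass
#: of each normalized Gaussian is 1 to ~2e-4, comfortably inside the
#: 1e-3 integration check.
_SIGMA_MARGIN = 4.0


def _gaussian_field(points, centers, sigmas, weights) -> np.ndarray:
    out = np.zeros(points.shape[:-1])
    for c, s, w in zip(centers, sigmas, weights):
        r2 = ((points - c) ** 2).sum(axis=-1)
        amp = w / ((2.0 * np.pi) ** 1.5 * s**3)
        out += amp * np.exp(-r2 / (2.0 * s * s))
    return out


def make_grid_triplet(
    seed: int,
    counts: tuple[int, int, int] = (32, 32, 32),
    n_blobs: int = 2,
    n_electrons: float = 10.0,
) -> tuple[VolumetricGrid, VolumetricGrid, VolumetricGrid]:
    """Density-grid triplet (rho_N, rho_{N-1}, rho_{N+1}) on a cubic box.

    rho_{N-1} = rho_N - g1 and rho_{N+1} = rho_N + g2 where g1, g2 are
    sums of Gaussians analytically normalized to integrate to one
    electron, so the derived Fukui fields integrate to 1 by construction.
    Counts below 16 per axis are rejected as too coarse for the 1e-3
    integration checks.
    """
    counts = tuple(int(c) for c in counts)
    if any(c < 16 for c in counts):
        raise ValueError(f"grid too coarse for integration checks: {counts}")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    L = _BOX_LENGTH
    spacing = np.array([L / c for c in counts])
    axes = np.diag(spacing)
    origin = spacing / 2.0  # cell-centred sampling

    idx = np.indices(counts).transpose(1, 2, 3, 0)
    points = origin + idx * spacing

    sigma_max = 1.2
    if L - 2 * _SIGMA_MARGIN * sigma_max <= 0:
        raise ValueError("box too small to keep blobs inside the margin")

    def blob_set():
        sigmas = rng.uniform(0.8, sigma_max, size=n_blobs)
        lo = _SIGMA_MARGIN * sigmas
        centers = np.array(
            [rng.uniform(lo[i], L - lo[i], size=3) for i in range(n_blobs)]
        )
        weights = np.full(n_blobs, 1.0 / n_blobs)
        return centers, sigmas, weights

    # smooth neutral background carrying n_electrons
    bg_sigma = L / 6.0
    center = np.full(3, L / 2.0)
    rho_n_vals = _gaussian_field(points, [center], [bg_sigma], [n_electrons])

    g1 = _gaussian_field(points, *blob_set())
    g2 = _gaussian_field(points, *blob_set())

    atoms = [(6, 6.0, (L / 2.0, L / 2.0, L / 2.0))]

    def grid(vals: np.ndarray) -> VolumetricGrid:
        return VolumetricGrid(origin, axes, counts, list(atoms), vals)

    return (grid(rho_n_vals), grid(rho_n_vals - g1), grid(rho_n_vals + g2))


def taltobulin_fixture(seed: int = 0) -> FixtureBundle:
    """The Taltobulin analysis bundle with published reference values.

    The orbital spectrum reproduces the published frontier (HOMO
    -6.240 eV, LUMO -1.733 eV) by construction; the neutral total energy
    is the published -1517.422 hartree.  The N-1/N+1 total energies are
    *synthetic*: the published record does not include them, so they are
    constructed Koopmans-consistently (E(N-1) = E(N) - e_HOMO,
    E(N+1) = E(N) + e_LUMO, in hartree), making the KID diagnostics
    exactly zero.  Charge and density triplets are synthetic stand-ins
    sized to the molecule (34 atoms).

    Raises if the transcribed SMILES fails validation against the
    published MW (473.66 +/- 0.01) or heavy-atom count (34).
    """
    mol = druglikeness.parse_smiles(TALTOBULIN_SMILES)
    mw = druglikeness.molecular_weight(mol)
    if abs(mw - _TALTOBULIN_EXPECTED["mw"]) > 0.01:
        raise ValueError(
            f"fixture SMILES failed MW self-validation: {mw:.4f} vs "
            f"{_TALTOBULIN_EXPECTED['mw']}"
        )
    if mol.n_heavy_atoms != _TALTOBULIN_EXPECTED["n_atoms"]:
        raise ValueError(
            f"fixture SMILES failed atom-count self-validation: "
            f"{mol.n_heavy_atoms} vs {_TALTOBULIN_EXPECTED['n_atoms']}"
        )

    e_homo = _TALTOBULIN_EXPECTED["e_homo_ev"]
    e_lumo = _TALTOBULIN_EXPECTED["e_lumo_ev"]
    spectrum = make_spectrum(
        seed, n_occ=5, n_virt=5, e_homo=e_homo, gap=e_lumo - e_homo
    )
    e_n = _TALTOBULIN_EXPECTED["total_energy_au"]
    e_nm1 = e_n - e_homo / HARTREE_TO_EV  # Koopmans-consistent cation
    e_np1 = e_n + e_lumo / HARTREE_TO_EV  # Koopmans-consistent anion
    freqs = tuple(np.sort(np.random.default_rng(seed).uniform(20.0, 3200.0, 96)).tolist())

    qm_results = {
        "N": QMResult("taltobulin", 0, 1, e_n, spectrum=spectrum, frequencies=freqs),
        "N-1": QMResult("taltobulin_cation", 1, 2, e_nm1),
        "N+1": QMResult("taltobulin_anion", -1, 2, e_np1),
    }
    expected = dict(_TALTOBULIN_EXPECTED)
    expected["e_nm1_au"] = e_nm1
    expected["e_np1_au"] = e_np1
    return FixtureBundle(
        seed=seed,
        qm_results=qm_results,
        spectrum=spectrum,
        charge_triplet=make_charge_triplet(seed, n_atoms=34),
        grid_triplet=make_grid_triplet(seed),
        smiles=TALTOBULIN_SMILES,
        bioactivity_inputs=dict(_TALTOBULIN_EXPECTED["bioactivity"]),
        expected=expected,
    )


def write_bundle(bundle: FixtureBundle, directory) -> dict[str, str]:
    """Serialize a bundle to plain-text artifacts under ``directory``.

    Writes the fixture-dialect orbital/charge/frequency files, the cube
    triplet, the SMILES, a JSON 'expected' sidecar and a ready-to-run
    pipeline config; returns a name → path map.
    """
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def put(name: str, filename: str, text: str) -> None:
        p = directory / filename
        p.write_text(text)
        paths[name] = str(p)

    put("orbitals", "orbitals.txt", format_orbital_energies(bundle.spectrum))
    q_n, q_cat, q_an = bundle.charge_triplet
    put("charges_n", "charges_n.txt", format_charges(q_n))
    put("charges_cation", "charges_cation.txt", format_charges(q_cat))
    put("charges_anion", "charges_anion.txt", format_charges(q_an))
    g_n, g_cat, g_an = bundle.grid_triplet
    put("cube_n", "rho_n.cube", write_cube(g_n, "rho_N synthetic density"))
    put("cube_cation", "rho_cation.cube", write_cube(g_cat, "rho_N-1 synthetic density"))
    put("cube_anion", "rho_anion.cube", write_cube(g_an, "rho_N+1 synthetic density"))
    neutral = bundle.qm_results["N"]
    if neutral.frequencies:
        put("frequencies", "frequencies.txt", format_frequencies(neutral.frequencies))
    put("smiles", "molecule.smi", bundle.smiles + "\n")
    put("expected", "expected.json", json.dumps(bundle.expected, indent=2, sort_keys=True))

    config = {
        "orbitals": paths["orbitals"],
        "charges_n": paths["charges_n"],
        "charges_cation": paths["charges_cation"],
        "charges_anion": paths["charges_anion"],
        "cube_n": paths["cube_n"],
        "cube_cation": paths["cube_cation"],
        "cube_anion": paths["cube_anion"],
        "smiles": bundle.smiles,
        "label": neutral.label,
        "energy_n": neutral.total_energy,
        "energy_cation": bundle.qm_results["N-1"].total_energy,
        "energy_anion": bundle.qm_results["N+1"].total_energy,
        "seed": bundle.seed,
    }
    if neutral.frequencies:
        config["frequencies"] = paths["frequencies"]
    for target, score in bundle.bioactivity_inputs.items():
        config[f"score_{target}"] = score
    if "milogp" in bundle.expected:
        config["milogp"] = bundle.expected["milogp"]
    if "volume" in bundle.expected:
        config["volume"] = bundle.expected["volume"]
    import yaml

    put("config", "config.yaml", yaml.safe_dump(config, sort_keys=True))
    return paths
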