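"""Ingestion of quantum-chemistry artifacts.

This module reads and validates the electronic-structure outputs the rest of
the pipeline consumes: molecular-orbital spectra, per-atom partial charges,
vibrational frequency lists, total electronic energies and volumetric
scalar fields (Gaussian cube files).  It also performs conformer
bookkeeping (minimum verification, lowest-energy selection).

Fixture dialect
---------------
Because vendor log formats are large and proprietary-ish, the package
defines a small plain-text *fixture dialect* (``dialect="fixture"``) that
every test and synthetic bundle uses.  It is line-oriented; ``#`` starts a
comment; keys and values are whitespace-separated.

Orbital files::

    unit eV            # or "hartree"
    nelectrons 20      # optional; defaults to the sum of occupations
    orbital -10.000000 2
    orbital  -6.240000 2
    orbital  -1.733000 0

Charge files::

    scheme Mulliken
    net_charge 0
    atom C1  -0.123456
    atom N2   0.045000

Frequency files: one wavenumber (cm^-1) per line; imaginary modes are
written as negative numbers, the usual log-file convention.

Cube files follow the standard Gaussian layout: two comment lines, the
atom count + grid origin, three axis lines, one line per atom
(atomic number, nuclear charge, x, y, z), then the scalar values in
z-fastest order, six per line.  Lengths are in bohr.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .units import HARTREE_TO_EV

__all__ = [
    "QMParseError",
    "UnknownDialectError",
    "OrbitalSpectrum",
    "ChargeSet",
    "QMResult",
    "VolumetricGrid",
    "parse_orbital_energies",
    "format_orbital_energies",
    "parse_charges",
    "format_charges",
    "parse_frequencies",
    "format_frequencies",
    "read_cube",
    "write_cube",
    "check_minimum",
    "select_lowest_conformer",
]


class QMParseError(ValueError):
    """Raised when a QM artifact cannot be parsed or fails validation."""


class UnknownDialectError(QMParseError):
    """Raised when a parser is asked for a dialect it does not implement."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrbitalSpectrum:
    """Ordered molecular-orbital energies (eV) with occupations.

    ``energies`` must be ascending; occupations are electron counts per
    orbital (0, 1 or 2) and must sum to ``n_electrons``.
    """

    energies: tuple[float, ...]
    occupations: tuple[float, ...]
    n_electrons: int

    def __post_init__(self) -> None:
        if len(self.energies) != len(self.occupations):
            raise ValueError("energies and occupations differ in length")
        if any(b < a for a, b in zip(self.energies, self.energies[1:])):
            raise ValueError("orbital energies must be sorted ascending")
        if not any(o > 0 for o in self.occupations):
            raise ValueError("spectrum has no occupied orbital")
        if abs(sum(self.occupations) - self.n_electrons) > 1e-9:
            raise ValueError(
                f"occupations sum to {sum(self.occupations)} but "
                f"n_electrons = {self.n_electrons}"
            )


@dataclass(frozen=True)
class ChargeSet:
    """Per-atom partial charges (e) for one species under one scheme."""

    scheme: str
    atom_labels: tuple[str, ...]
    q: tuple[float, ...]
    net_charge: int

    def __post_init__(self) -> None:
        if len(self.atom_labels) != len(self.q):
            raise ValueError("atom_labels and q differ in length")
        if abs(sum(self.q) - self.net_charge) > 1e-3:
            raise ValueError(
                f"charges sum to {sum(self.q):.6f}, expected net charge "
                f"{self.net_charge} (tolerance 1e-3 e)"
            )

    def __len__(self) -> int:
        return len(self.q)


@dataclass(frozen=True)
class QMResult:
    """One converged electronic-structure result for one species/conformer."""

    label: str
    net_charge: int
    multiplicity: int
    total_energy: float  # hartree
    spectrum: OrbitalSpectrum | None = None
    frequencies: tuple[float, ...] | None = None
    charges: tuple[ChargeSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass
class VolumetricGrid:
    """A Gaussian-cube-style scalar field on a regular 3-D grid.

    ``origin`` and ``axes`` are in bohr; ``values`` has shape
    ``counts`` = (nx, ny, nz) with the z index fastest when flattened,
    matching the cube-file value ordering.  ``atoms`` is a list of
    ``(atomic_number, nuclear_charge, (x, y, z))``.
    """

    origin: np.ndarray
    axes: np.ndarray
    counts: tuple[int, int, int]
    atoms: list[tuple[int, float, tuple[float, float, float]]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.counts = tuple(int(c) for c in self.counts)
        if any(c <= 0 for c in self.counts):
            raise ValueError(f"grid counts must be positive, got {self.counts}")
        self.values = np.asarray(self.values, dtype=float).reshape(self.counts)
        if self.voxel_volume <= 0:
            raise ValueError("axes are singular: voxel volume must be > 0")

    @property
    def voxel_volume(self) -> float:
        return abs(float(np.linalg.det(self.axes)))

    def same_geometry(self, other: "VolumetricGrid", tol: float = 1e-8) -> bool:
        return (
            self.counts == other.counts
            and np.allclose(self.origin, other.origin, atol=tol, rtol=0)
            and np.allclose(self.axes, other.axes, atol=tol, rtol=0)
        )

    def with_values(self, values: np.ndarray) -> "VolumetricGrid":
        """A new grid sharing this geometry and atom list."""
        return VolumetricGrid(
            origin=self.origin.copy(),
            axes=self.axes.copy(),
            counts=self.counts,
            atoms=list(self.atoms),
            values=np.asarray(values, dtype=float),
        )


# ---------------------------------------------------------------------------
# fixture-dialect parsers
# ---------------------------------------------------------------------------

def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def _content_lines(text: str) -> list[list[str]]:
    out = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line.split())
    return out


def parse_orbital_energies(source, dialect: str = "fixture") -> OrbitalSpectrum:
    """Parse an orbital-energy block into an :class:`OrbitalSpectrum`.

    Energies given in hartree (``unit hartree``) are converted to eV.
    ``source`` may be a string or a readable text stream.
    """
    if dialect != "fixture":
        raise UnknownDialectError(f"unrecognized orbital dialect {dialect!r}")
    unit = "eV"
    n_electrons: int | None = None
    rows: list[tuple[float, float]] = []
    for tok in _content_lines(_as_text(source)):
        key = tok[0].lower()
        if key == "unit":
            unit = tok[1]
        elif key == "nelectrons":
            n_electrons = int(tok[1])
        elif key == "orbital":
            if len(tok) != 3:
                raise QMParseError(f"malformed orbital line: {' '.join(tok)}")
            rows.append((float(tok[1]), float(tok[2])))
        else:
            raise QMParseError(f"unknown key {key!r} in orbital block")
    if not rows:
        raise QMParseError("no orbital block found")
    if unit.lower() in ("hartree", "au", "a.u."):
        rows = [(e * HARTREE_TO_EV, o) for e, o in rows]
    elif unit.lower() != "ev":
        raise QMParseError(f"unknown energy unit {unit!r}")
    rows.sort(key=lambda r: r[0])
    energies = tuple(e for e, _ in rows)
    occupations = tuple(o for _, o in rows)
    if n_electrons is None:
        n_electrons = int(round(sum(occupations)))
    return OrbitalSpectrum(energies, occupations, n_electrons)


def format_orbital_energies(spectrum: OrbitalSpectrum) -> str:
    """Serialize a spectrum to the fixture dialect (always in eV)."""
    lines = ["unit eV", f"nelectrons {spectrum.n_electrons}"]
    for e, o in zip(spectrum.energies, spectrum.occupations):
        occ = int(o) if float(o).is_integer() else o
        lines.append(f"orbital {e:.9f} {occ}")
    return "\n".join(lines) + "\n"


def parse_charges(source) -> ChargeSet:
    """Parse a fixture-dialect charge file into a :class:`ChargeSet`."""
    scheme = None
    net_charge = 0
    labels: list[str] = []
    q: list[float] = []
    for tok in _content_lines(_as_text(source)):
        key = tok[0].lower()
        if key == "scheme":
            scheme = tok[1]
        elif key == "net_charge":
            net_charge = int(tok[1])
        elif key == "atom":
            labels.append(tok[1])
            q.append(float(tok[2]))
        else:
            raise QMParseError(f"unknown key {key!r} in charge block")
    if scheme is None:
        raise QMParseError("charge block missing 'scheme'")
    if not q:
        raise QMParseError("no atom charges found")
    return ChargeSet(scheme, tuple(labels), tuple(q), net_charge)


def format_charges(cs: ChargeSet) -> str:
    lines = [f"scheme {cs.scheme}", f"net_charge {cs.net_charge}"]
    lines += [f"atom {lab} {v:.12f}" for lab, v in zip(cs.atom_labels, cs.q)]
    return "\n".join(lines) + "\n"


def parse_frequencies(source) -> tuple[float, ...]:
    """Parse a frequency list (one cm^-1 value per line; negatives = imaginary)."""
    vals: list[float] = []
    for tok in _content_lines(_as_text(source)):
        vals.extend(float(t) for t in tok)
    return tuple(vals)


def format_frequencies(freqs) -> str:
    return "\n".join(f"{f:.4f}" for f in freqs) + "\n"


# ---------------------------------------------------------------------------
# Gaussian cube I/O
# ---------------------------------------------------------------------------

def read_cube(source) -> VolumetricGrid:
    """Read a Gaussian cube file into a :class:`VolumetricGrid`.

    The orbital-cube convention (negative atom count plus a trailing
    orbital-index record) is rejected: this package only handles plain
    scalar fields.
    """
    text = _as_text(source)
    lines = text.splitlines()
    if len(lines) < 6:
        raise QMParseError("truncated cube file: header incomplete")
    try:
        hdr = lines[2].split()
        natoms = int(hdr[0])
        origin = np.array([float(x) for x in hdr[1:4]])
        axes = np.zeros((3, 3))
        counts = [0, 0, 0]
        for i in range(3):
            tok = lines[3 + i].split()
            counts[i] = int(tok[0])
            axes[i] = [float(x) for x in tok[1:4]]
    except (IndexError, ValueError) as exc:
        raise QMParseError(f"malformed cube header: {exc}") from exc
    if natoms < 0:
        raise QMParseError(
            "negative atom count (orbital-cube convention) is not supported"
        )
    if any(c <= 0 for c in counts):
        raise QMParseError(f"non-positive grid counts {tuple(counts)}")
    atoms = []
    for i in range(natoms):
        tok = lines[6 + i].split()
        if len(tok) < 5:
            raise QMParseError(f"malformed atom line {i + 1}")
        atoms.append(
            (int(tok[0]), float(tok[1]), (float(tok[2]), float(tok[3]), float(tok[4])))
        )
    nval = counts[0] * counts[1] * counts[2]
    flat = " ".join(lines[6 + natoms :]).split()
    if len(flat) < nval:
        raise QMParseError(
            f"truncated value section: expected {nval} values, found {len(flat)}"
        )
    if len(flat) > nval:
        raise QMParseError(
            f"trailing data: expected {nval} values, found {len(flat)}"
        )
    values = np.array([float(v) for v in flat]).reshape(counts)
    return VolumetricGrid(origin, axes, tuple(counts), atoms, values)


def write_cube(grid: VolumetricGrid, comment: str = "cdftkit scalar field") -> str:
    """Serialize a grid to Gaussian cube text (bohr, z-fastest, %13.5E)."""
    out = io.StringIO()
    out.write(f"{comment}\n")
    out.write("generated by cdftkit\n")
    ox, oy, oz = grid.origin
    out.write(f"{len(grid.atoms):5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
    for count, axis in zip(grid.counts, grid.axes):
        out.write(f"{count:5d}{axis[0]:12.6f}{axis[1]:12.6f}{axis[2]:12.6f}\n")
    for z, q, (x, y, zc) in grid.atoms:
        out.write(f"{z:5d}{q:12.6f}{x:12.6f}{y:12.6f}{zc:12.6f}\n")
    flat = grid.values.reshape(-1)  # z fastest by C order
    for start in range(0, flat.size, 6):
        chunk = flat[start : start + 6]
        out.write("".join(f"{v:13.5E}" for v in chunk) + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# conformer bookkeeping
# ---------------------------------------------------------------------------

def check_minimum(frequencies) -> bool:
    """True iff every vibrational frequency is real (all values > 0 cm^-1).

    Imaginary modes are encoded as negative wavenumbers.  An empty list
    cannot certify a minimum and raises.
    """
    freqs = list(frequencies)
    if not freqs:
        raise ValueError("cannot certify a minimum from an empty frequency list")
    return all(f > 0 for f in freqs)


def select_lowest_conformer(results) -> QMResult:
    """Pick the lowest-total-energy conformer from a homogeneous set.

    All candidates must share net charge and multiplicity.  Exact energy
    ties resolve to the earliest list position.
    """
    results = list(results)
    if not results:
        raise ValueError("no conformers given")
    ref = results[0]
    for r in results[1:]:
        if r.net_charge != ref.net_charge or r.multiplicity != ref.multiplicity:
            raise ValueError(
                "conformer set mixes charge/multiplicity: "
                f"({ref.net_charge},{ref.multiplicity}) vs "
                f"({r.net_charge},{r.multiplicity})"
            )
    return min(results, key=lambda r: r.total_energy)
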