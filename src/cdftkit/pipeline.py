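"""End-to-end orchestration: artifacts in, structured reactivity report out.

The full analysis chain is: parse orbital/charge/frequency artifacts →
verify the structure is a true minimum → extract the frontier → global
reactivity descriptors and lambda_max (frontier route by default, Delta-SCF
opt-in) → KID diagnostics → condensed and grid Fukui functions → drug-
likeness block → bioactivity-score bands.

A run is configured by a flat :class:`AnalysisConfig` (mirroring a flat
YAML config file; CLI flags override file keys).  The frontier source is
mandatory; every other stage runs only when its inputs are present and is
otherwise marked ``skipped`` in the report.  A stage whose inputs are
present but invalid is marked ``failed`` with a stage-tagged message, and
the remaining stages still run — corrupt cubes must not take down the
global-descriptor block.

Rounding happens only at render time: eV quantities to 3 decimals,
lambda_max to integer nm, MW/TPSA to 2 decimals (round-half-even).  The
underlying report always carries the unrounded values, and rendering the
same report twice is byte-identical.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from . import __version__
from .cdft_global import (
    FrontierEnergies,
    GlobalDescriptors,
    KidDiagnostics,
    finite_difference_ia,
    frontier_from_spectrum,
    global_descriptors,
    kid_diagnostics,
)
from .cdft_local import condensed_fukui, grid_fukui, grid_integral, rank_sites
from .druglikeness import (
    BIOACTIVITY_TARGETS,
    BioactivityScores,
    drug_profile,
    parse_smiles,
)
from .qm_io import (
    check_minimum,
    parse_charges,
    parse_frequencies,
    parse_orbital_energies,
    read_cube,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "PipelineError", "run_pipeline",
           "render_report", "report_from_dict"]


class PipelineError(RuntimeError):
    """A mandatory pipeline input is missing or invalid."""


@dataclass
class AnalysisConfig:
    """Flat run configuration; every field mirrors a config-file key."""

    label: str = "species"
    # frontier source (one of the two is mandatory)
    orbitals: str | None = None          # fixture-dialect orbital file
    e_homo: float | None = None          # direct frontier energies (eV)
    e_lumo: float | None = None
    ia_mode: str = "vertical"            # "vertical" | "delta_scf"
    # total energies (hartree) for KID / Delta-SCF
    energy_n: float | None = None
    energy_cation: float | None = None
    energy_anion: float | None = None
    # other artifact paths
    frequencies: str | None = None
    charges_n: str | None = None
    charges_cation: str | None = None
    charges_anion: str | None = None
    cube_n: str | None = None
    cube_cation: str | None = None
    cube_anion: str | None = None
    smiles: str | None = None
    # external pass-through values
    milogp: float | None = None
    volume: float | None = None
    score_gpcr: float | None = None
    score_ion_channel: float | None = None
    score_kinase: float | None = None
    score_nuclear_receptor: float | None = None
    score_protease: float | None = None
    score_enzyme: float | None = None
    # misc
    top_k: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.ia_mode not in ("vertical", "delta_scf"):
            raise ValueError(f"ia_mode must be vertical|delta_scf, got {self.ia_mode!r}")

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        """Load a flat YAML config; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Structured result of one pipeline run.

    ``stages`` maps stage name → ``{"status": ok|skipped|failed,
    "message": ...}``.  Scalar payloads live in the stage-specific fields;
    every rounded number a renderer prints derives from the unrounded
    values kept here.
    """

    label: str
    provenance: dict
    stages: dict = field(default_factory=dict)
    total_energy_au: float | None = None
    minimum_verified: bool | None = None
    frontier: dict | None = None         # e_homo/e_lumo (eV)
    descriptors: dict | None = None      # GlobalDescriptors.as_dict()
    kid: dict | None = None              # j_i/j_a/j_hl (eV)
    fukui: dict | None = None            # sums, top sites per selector
    grid_fukui_integrals: dict | None = None
    drug_profile: dict | None = None
    bioactivity: dict | None = None      # score + category per target

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def ok(self) -> bool:
        return not any(s["status"] == "failed" for s in self.stages.values())


def report_from_dict(data: dict) -> AnalysisReport:
    return AnalysisReport(**data)


def _round_half_even(x: float, ndigits: int) -> float:
    return float(round(x, ndigits))


def run_pipeline(config: AnalysisConfig) -> AnalysisReport:
    """Execute every stage the configuration enables.

    Raises :class:`PipelineError` when no frontier source is configured;
    all other stage errors are recorded in the report (stage-tagged) and
    do not interrupt the remaining stages.
    """
    report = AnalysisReport(
        label=config.label,
        provenance={
            "package": "cdftkit",
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "ia_mode": config.ia_mode,
        },
    )

    def mark(stage: str, status: str, message: str = "") -> None:
        report.stages[stage] = {"status": status, "message": message}

    def run_stage(stage: str, enabled: bool, fn) -> None:
        if not enabled:
            mark(stage, "skipped", "inputs not configured")
            return
        try:
            fn()
            mark(stage, "ok")
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            mark(stage, "failed", f"{stage}: {exc}")

    # --- frontier (mandatory) ------------------------------------------
    frontier: FrontierEnergies | None = None
    have_energies = all(
        v is not None
        for v in (config.energy_n, config.energy_cation, config.energy_anion)
    )
    try:
        if config.ia_mode == "delta_scf":
            if not have_energies:
                raise PipelineError(
                    "frontier: delta_scf mode needs energy_n/energy_cation/energy_anion"
                )
            i, a = finite_difference_ia(
                config.energy_n, config.energy_cation, config.energy_anion
            )
            frontier = FrontierEnergies(e_homo=-i, e_lumo=-a)
        elif config.orbitals is not None:
            with open(config.orbitals) as fh:
                frontier = frontier_from_spectrum(parse_orbital_energies(fh))
        elif config.e_homo is not None and config.e_lumo is not None:
            frontier = FrontierEnergies(config.e_homo, config.e_lumo)
        else:
            raise PipelineError(
                "frontier: no source configured (orbitals file or e_homo/e_lumo)"
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"frontier: {exc}") from exc
    mark("frontier", "ok")
    report.frontier = {"e_homo_eV": frontier.e_homo, "e_lumo_eV": frontier.e_lumo}
    report.total_energy_au = config.energy_n

    # --- minimum check -------------------------------------------------
    def _minimum() -> None:
        with open(config.frequencies) as fh:
            report.minimum_verified = check_minimum(parse_frequencies(fh))

    run_stage("minimum_check", config.frequencies is not None, _minimum)

    # --- global descriptors --------------------------------------------
    def _global() -> None:
        d: GlobalDescriptors = global_descriptors(frontier)
        report.descriptors = d.as_dict()

    run_stage("global_descriptors", True, _global)

    # --- KID diagnostics -------------------------------------------------
    def _kid() -> None:
        k: KidDiagnostics = kid_diagnostics(
            config.energy_n, config.energy_cation, config.energy_anion, frontier
        )
        report.kid = {"J_I_eV": k.j_i, "J_A_eV": k.j_a, "J_HL_eV": k.j_hl}

    run_stage("kid", have_energies and config.ia_mode == "vertical", _kid)

    # --- condensed Fukui -------------------------------------------------
    have_charges = all(
        p is not None
        for p in (config.charges_n, config.charges_cation, config.charges_anion)
    )

    def _condensed() -> None:
        sets = []
        for p in (config.charges_n, config.charges_cation, config.charges_anion):
            with open(p) as fh:
                sets.append(parse_charges(fh))
        cf = condensed_fukui(*sets)
        s_minus, s_plus, s_dual = cf.sums()
        k = min(config.top_k, len(cf))
        report.fukui = {
            "scheme": cf.scheme,
            "n_atoms": len(cf),
            "sum_f_minus": s_minus,
            "sum_f_plus": s_plus,
            "sum_dual": s_dual,
            # lists (not tuples) so the JSON rendering is lossless
            "top_f_minus": [list(t) for t in rank_sites(cf, "f_minus", k)],
            "top_f_plus": [list(t) for t in rank_sites(cf, "f_plus", k)],
            "top_dual": [list(t) for t in rank_sites(cf, "dual", k)],
        }

    run_stage("condensed_fukui", have_charges, _condensed)

    # --- grid Fukui ------------------------------------------------------
    have_cubes = all(
        p is not None for p in (config.cube_n, config.cube_cation, config.cube_anion)
    )

    def _grids() -> None:
        grids = []
        for p in (config.cube_n, config.cube_cation, config.cube_anion):
            with open(p) as fh:
                grids.append(read_cube(fh))
        f_minus, f_plus, dual = grid_fukui(*grids)
        report.grid_fukui_integrals = {
            "f_minus": grid_integral(f_minus),
            "f_plus": grid_integral(f_plus),
            "dual": grid_integral(dual),
        }

    run_stage("grid_fukui", have_cubes, _grids)

    # --- drug-likeness ---------------------------------------------------
    def _druglike() -> None:
        mol = parse_smiles(config.smiles)
        report.drug_profile = drug_profile(
            mol, milogp=config.milogp, volume=config.volume
        ).as_dict()

    run_stage("druglikeness", config.smiles is not None, _druglike)

    # --- bioactivity bands ----------------------------------------------
    scores = {
        t: getattr(config, f"score_{t}") for t in BIOACTIVITY_TARGETS
    }
    have_scores = all(v is not None for v in scores.values())

    def _bioactivity() -> None:
        bs = BioactivityScores(**scores)
        cats = bs.categories
        report.bioactivity = {
            t: {"score": scores[t], "category": cats[t]} for t in BIOACTIVITY_TARGETS
        }

    run_stage("bioactivity", have_scores, _bioactivity)

    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_EV_KEYS = {
    "I_eV", "A_eV", "chi_eV", "mu_eV", "eta_eV", "omega_eV", "omega_minus_eV",
    "omega_plus_eV", "net_electrophilicity_eV", "J_I_eV", "J_A_eV", "J_HL_eV",
    "e_homo_eV", "e_lumo_eV",
}


def _rounded_scalars(report: AnalysisReport) -> dict:
    """Flatten the report to printed-precision scalars (render layer only)."""
    out: dict[str, object] = {"label": report.label}
    if report.total_energy_au is not None:
        out["total_energy_au"] = _round_half_even(report.total_energy_au, 3)
    if report.minimum_verified is not None:
        out["minimum_verified"] = report.minimum_verified
    for block in (report.frontier, report.descriptors, report.kid):
        if not block:
            continue
        for key, val in block.items():
            if key == "lambda_max_nm":
                out[key] = int(round(val))
            elif key == "S_eV^-1":
                out[key] = _round_half_even(val, 3)
            elif key in _EV_KEYS:
                out[key] = _round_half_even(val, 3)
            else:
                out[key] = val
    if report.drug_profile:
        for key, val in report.drug_profile.items():
            if val is None:
                continue
            if key in ("MW", "TPSA", "volume"):
                out[key] = _round_half_even(val, 2)
            elif key in ("miLogP", "logP_calc"):
                out[key] = _round_half_even(val, 2)
            else:
                out[key] = val
    if report.fukui:
        for key in ("sum_f_minus", "sum_f_plus", "sum_dual"):
            out[key] = _round_half_even(report.fukui[key], 6)
    if report.grid_fukui_integrals:
        for key, val in report.grid_fukui_integrals.items():
            out[f"grid_integral_{key}"] = _round_half_even(val, 6)
    if report.bioactivity:
        for target, rec in report.bioactivity.items():
            out[f"score_{target}"] = rec["score"]
            out[f"category_{target}"] = rec["category"]
    return out


def render_report(report: AnalysisReport, format: str = "json") -> str:
    """Serialize a report: lossless ``json``, flat ``csv``, or ``markdown``.

    JSON round-trips to an equal report via :func:`report_from_dict`; CSV
    and Markdown present the printed-precision scalar view.
    """
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format == "csv":
        scalars = _rounded_scalars(report)
        buf = io.StringIO()
        buf.write(",".join(scalars.keys()) + "\n")
        buf.write(",".join(str(v) for v in scalars.values()) + "\n")
        return buf.getvalue()
    if format == "markdown":
        scalars = _rounded_scalars(report)
        lines = [
            f"# Reactivity report: {report.label}",
            "",
            "| quantity | value |",
            "| --- | --- |",
        ]
        lines += [f"| {k} | {v} |" for k, v in scalars.items() if k != "label"]
        lines += ["", "## Stages", "", "| stage | status | message |", "| --- | --- | --- |"]
        lines += [
            f"| {name} | {st['status']} | {st['message']} |"
            for name, st in report.stages.items()
        ]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")
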