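# Methods

## Scope and model

cdftkit implements the descriptor stage of a conceptual-DFT (CDFT)
reactivity study: everything downstream of the electronic-structure
calculation. The electronic-structure inputs themselves — orbital
energies, N/N±1 total energies, partial charges, densities — are taken
as given (for Taltobulin they come from a range-separated meta-GGA
model chemistry with implicit water solvation); running or driving a QM
engine is out of scope, as are TD-DFT excitation spectra, solvation
models and conformer searching.

### Global descriptors

With I = −ε_HOMO and A = −ε_LUMO (the vertical, Koopmans-like route,
which is the default):

| symbol | formula | meaning | units |
| --- | --- | --- | --- |
| χ | (I + A)/2 | electronegativity | eV |
| μ | −χ | electronic chemical potential | eV |
| η | I − A | global hardness | eV |
| S | 1/η | global softness | eV⁻¹ |
| ω | χ²/2η | electrophilicity index | eV |
| ω⁻ | (3I + A)²/16η | electrodonating power | eV |
| ω⁺ | (I + 3A)²/16η | electroaccepting power | eV |
| Δω± | ω⁻ + ω⁺ | net electrophilicity | eV |
| λmax | hc/(ε_LUMO − ε_HOMO) | gap-based absorption estimate | nm |

Conventions worth stating explicitly:

- **Hardness carries no ½ factor**: η equals the full HOMO–LUMO gap.
  Both conventions exist in the literature; the full-gap form is the one
  consistent with the reference values this package reproduces (for the
  Taltobulin frontier, η = 4.507 eV = the gap itself).
- **ω⁺ is reported in eV** like the other energy-dimensioned indices.
- **A may be negative** (positive LUMO, unbound anion); the formulas are
  still evaluated and the sign is passed through.
- The identity ω⁻ − ω⁺ = χ holds algebraically
  ((3I+A)² − (I+3A)² = 8(I+A)(I−A)); it is enforced as an invariant to
  1 × 10⁻¹⁰ eV and Δω± is computed on the same floating path as its
  terms, so Δω± = ω⁻ + ω⁺ is exact.
- ω⁻ and ω⁺ are *not* monotone in I everywhere: dω⁻/dI changes sign at
  I = 7A/3 and dω⁺/dI at I = 5A. Monotonicity tests therefore cover
  only ranges where the derivative is positive.
- λmax uses hc = 1239.841984 eV·nm and is rounded to integer nm at
  report time.

### Koopmans-in-DFT diagnostics and the ΔSCF route

J_I = |ε_HOMO + E(N−1) − E(N)|, J_A = |ε_LUMO + E(N) − E(N+1)| and
J_HL = √(J_I² + J_A²) measure how well the frontier energies stand in
for ΔSCF ionization energy and electron affinity; values up to a few
tenths of an eV are generally taken to justify the frontier route. The
ΔSCF route itself (I = E(N−1) − E(N), A = E(N) − E(N+1), fed into the
same descriptor formulas) is available as the opt-in `ia_mode:
delta_scf`; vertical mode is the default.

### Local descriptors

Condensed Fukui functions are defined from partial charges q rather
than electron populations p = Z − q:

    f⁻_k = q_k(N−1) − q_k(N)     (electrophilic attack)
    f⁺_k = q_k(N) − q_k(N+1)     (nucleophilic attack)
    Δf_k = f⁺_k − f⁻_k

Worked sign check (2 atoms): q(N) = [0, 0], q(N−1) = [0.6, 0.4],
q(N+1) = [−0.7, −0.3] gives f⁻ = [0.6, 0.4], f⁺ = [0.7, 0.3],
Δf = [0.1, −0.1] — positive f⁻ at the site that loses the most density
on ionization. The charge-based and population-based conventions differ
only by this global sign bookkeeping, but published tables mix them, so
the choice is pinned here. The sum rules Σf⁻ = Σf⁺ = 1 and ΣΔf = 0 are
exact whenever each charge set conserves its net charge exactly, and
deviations scale linearly with any conservation error (+ε on the cation
shifts Σf⁻ by +ε; +ε on the anion shifts Σf⁺ by −ε).

Grid Fukui fields are plain voxelwise differences of congruent density
cubes (congruence tolerance 1 × 10⁻⁸ bohr on origin and axes; no
resampling or interpolation). Grid-to-atom condensation (Becke/Voronoi
weighting) is deliberately not provided: condensed values come only
from charge triplets. Site ranking sorts descending by value with ties
broken toward the lower (1-based) atom index.

### Drug-likeness block

Definitions follow the Molinspiration conventions: nON is the N+O atom
count, nOHNH the count of hydrogens on N or O, nrotb the acyclic single
bonds between non-terminal heavy atoms excluding amide C–N bonds, TPSA
the Ertl fragment-contribution sum over N/O environments, MW the
average-isotope weight with implicit hydrogens. The structure layer is
RDKit; the rotatable-bond rule is implemented directly on the bond
graph because RDKit's built-in patterns draw the amide/terminal
boundaries slightly differently (for Taltobulin: 11 under the rule
above).

logP is the Wildman–Crippen atom-contribution estimate — an open,
documented stand-in for the proprietary miLogP model, expected to agree
with it only to about ±1 log unit (Taltobulin: 3.60 computed vs 4.43
external). When an external miLogP value is supplied it is preferred
for rule counting and reported alongside the computed value. Molecular
volume is likewise proprietary and is pass-through only. Rule-of-Five
limits (MW 500, logP 5, donors 5, acceptors 10) are boundary-inclusive:
a property violates its rule only strictly above the limit.

Bioactivity scores are **inputs, never computed** (the upstream
target-class models are undisclosed). Banding: score > 0 active;
−5.0 ≤ score ≤ 0.0 moderately active (both boundaries included — the
band endpoints are not specified more finely anywhere, so the closed
interval is this package's documented choice); score < −5.0 inactive.

## Synthetic data: what it emulates and what it does not

The `synthetic` module generates every pipeline input deterministically
from a seed:

- **Orbital spectra** with a prescribed frontier: the HOMO sits exactly
  at `e_homo`, the LUMO at `e_homo + gap`, other levels randomly spaced
  0.5–2.0 eV apart. Defaults are the Taltobulin frontier
  (−6.240 / −1.733 eV, gap 4.507 eV) with 5 occupied + 5 virtual levels.
- **Charge triplets** whose neutral/cation/anion sums are exactly
  0/+1/−1 (the last atom absorbs floating-point residue), neutral
  charges drawn from N(0, 0.3 e); an optional `conservation_noise`
  parameter breaks conservation on purpose to exercise the validation
  machinery.
- **Density triplets** on a 12-bohr cubic box (default 32³ voxels,
  cell-centred sampling): ρ_{N−1} = ρ_N − g₁ and ρ_{N+1} = ρ_N + g₂
  with g₁, g₂ sums of Gaussians analytically normalized to one
  electron, σ ∈ [0.8, 1.2] bohr. Blob centres keep a **4σ margin** from
  every box face: the mass a normalized 3-D Gaussian leaves outside a
  3σ-margin box is ≈0.8%, which would swamp the 10⁻³ normalization
  checks, while 4σ leaves ≈2 × 10⁻⁴. Grids coarser than 16 voxels per
  axis are rejected for the same reason.
- **The Taltobulin bundle** packages the published record (frontier,
  neutral total energy −1517.422 hartree, property block, six
  bioactivity scores) with synthetic charge/density triplets sized to
  the molecule. The N±1 total energies are not part of the published
  record and are constructed Koopmans-consistently
  (E(N±1) = E(N) ∓ ε_frontier/27.211386 hartree), which makes the KID
  diagnostics zero by construction — they validate the diagnostic
  plumbing, not the functional. The transcribed SMILES is validated at
  load time against MW 473.66 ± 0.01 Da and 34 heavy atoms and fails
  loudly on mismatch.

These generators reproduce the *bookkeeping* of QM output — units,
orderings, conservation laws, file formats — not its physics. Spectra
are not SCF solutions, charges are not population analyses of real
densities, and the density blobs are isotropic Gaussians rather than
molecular densities. Passing tests therefore demonstrate that the
descriptor algebra, validation and I/O are correct on inputs whose
ground truth is known in closed form; they say nothing about the
quality of any particular model chemistry on real molecules.

## Numerical choices

- Unit policy: orbital energies in eV, total energies in hartree,
  1 hartree = 27.211386 eV, centralized in `cdftkit.units`.
- Descriptors are computed and stored unrounded; rounding happens only
  at render time (eV quantities 3 decimals, λmax integer nm, MW/TPSA
  2 decimals, Python's round-half-even).
- Degenerate frontier: gaps ≤ 10⁻⁹ eV raise rather than return inf.
- Cube files: bohr, z-fastest values, `%13.5E` six-per-line emission;
  the parser is whitespace-tolerant and rejects truncated value
  sections, non-positive counts and the negative-atom-count orbital
  convention. Round-trips preserve geometry to the `%12.6f` header
  precision and values to ~10⁻⁵ relative.
- Conformer selection breaks exact energy ties by list position;
  minimum verification requires a non-empty frequency list and treats
  negative wavenumbers as imaginary modes.
- Charge-set ingestion tolerates |Σq − net| ≤ 10⁻³ e (typical log-file
  print precision); Fukui sum rules are checked at 10⁻⁶.
- Pipeline stage isolation: the frontier source is mandatory and fatal
  if absent; every other stage is skipped when unconfigured and failures
  are recorded per stage without aborting the rest of the run.

## Known limitations

- The frontier route inherits all limitations of the Koopmans-like
  approximation; the KID diagnostics quantify but do not remove them.
- Condensed Fukui values depend strongly on the charge-partition scheme
  (Mulliken vs Hirshfeld etc.); the scheme is carried as metadata and
  triplets from different schemes are rejected, but no scheme is
  endorsed.
- TPSA covers N/O environments only (no 3-D PSA, no S/P polar terms in
  the reported block); the logP stand-in is not miLogP; Veber/Ghose
  filters and any QSAR modelling are out of scope.
- Reactive-site rankings on synthetic charge triplets are validated by
  construction only; no per-atom reference values exist to compare
  against.
- Cube fields are exported for external rendering; no isosurface
  imaging is provided.
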