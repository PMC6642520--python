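# cdftkit

Conceptual-DFT reactivity descriptors, Fukui functions and drug-likeness
profiling for small peptides and drug-like molecules — built around the
published characterization of **Taltobulin** (HTI-286), a synthetic
hemiasterlin analogue and tubulin-polymerization inhibitor.

The package turns quantum-chemistry artifacts (orbital spectra, N/N±1
total energies, per-atom partial charges, electron-density cubes) and a
SMILES string into a single structured reactivity report. It is aimed at
computational chemists who already run the electronic-structure
calculations elsewhere and want the descriptor algebra, bookkeeping,
validation and reporting handled reproducibly.

## What it computes

**Global reactivity descriptors** from the frontier orbital energies,
under the Koopmans-like approximation I = −ε_HOMO, A = −ε_LUMO:

- electronegativity χ = (I + A)/2, chemical potential μ = −χ
- global hardness η = I − A (full-gap convention) and softness S = 1/η
- electrophilicity ω = χ²/2η
- electrodonating power ω⁻ = (3I + A)²/16η and electroaccepting power
  ω⁺ = (I + 3A)²/16η, with net electrophilicity Δω± = ω⁻ + ω⁺
- a gap-based absorption estimate λmax = hc/(ε_LUMO − ε_HOMO)
- Koopmans-in-DFT diagnostics J_I, J_A, J_HL that quantify how well the
  frontier energies agree with ΔSCF ionization energies; a ΔSCF
  (finite-difference) descriptor route is available as an opt-in mode.

**Local reactivity**: condensed Fukui functions f⁻_k = q_k(N−1) − q_k(N),
f⁺_k = q_k(N) − q_k(N+1) and the dual descriptor Δf = f⁺ − f⁻ from charge
triplets, grid Fukui fields from density-cube triplets, normalization
checks (Σf⁻ = Σf⁺ = 1, ΣΔf = 0) and reactive-site ranking.

**Drug-likeness**: the Molinspiration-style property block (MW, nAtoms,
nON, nOHNH, nrotb, Ertl TPSA, an open Wildman–Crippen logP stand-in for
the proprietary miLogP), Lipinski Rule-of-Five violation counting, and
banding of externally supplied bioactivity scores (> 0 active, −5 to 0
moderately active, < −5 inactive).

## Worked example

```python
from cdftkit import FrontierEnergies, global_descriptors, lambda_max

f = FrontierEnergies(e_homo=-6.240, e_lumo=-1.733)   # Taltobulin, eV
d = global_descriptors(f)
print(f"chi    = {d.chi:.3f} eV")
print(f"eta    = {d.eta:.3f} eV")
print(f"omega  = {d.omega:.3f} eV")
print(f"omega- = {d.omega_minus:.3f} eV")
print(f"omega+ = {d.omega_plus:.3f} eV")
print(f"dw+-   = {d.net_electrophilicity:.3f} eV")
print(f"lmax   = {lambda_max(f):.0f} nm")
```

prints

```
chi    = 3.987 eV
eta    = 4.507 eV
omega  = 1.763 eV
omega- = 5.801 eV
omega+ = 1.815 eV
dw+-   = 7.616 eV
lmax   = 275 nm
```

i.e. a moderately hard, strongly electrodonating species (ω⁻ ≫ ω⁺) whose
HOMO–LUMO gap corresponds to near-UV absorption. The drug-likeness side:

```python
from cdftkit import parse_smiles, drug_profile
from cdftkit.synthetic import TALTOBULIN_SMILES

profile = drug_profile(parse_smiles(TALTOBULIN_SMILES), milogp=4.43)
print(profile.as_dict())
# {'miLogP': 4.43, 'logP_calc': 3.597..., 'TPSA': 98.74, 'nAtoms': 34,
#  'nON': 7, 'nOHNH': 3, 'nviol': 0, 'nrotb': 11, 'volume': None,
#  'MW': 473.658...}
```

Zero Rule-of-Five violations: despite being a tripeptide, Taltobulin
profiles as an orally druggable molecule.

The same analysis runs end to end from the command line:

```bash
cdftkit fixtures --seed 1 --out scratch/bundle     # synthetic artifacts
cdftkit run --config scratch/bundle/config.yaml --format markdown
cdftkit global --homo -6.240 --lumo -1.733
cdftkit druglike --smiles 'CC(=O)Nc1ccc(O)cc1' --milogp 0.5
```

## Layout

- `cdftkit.qm_io` — artifact ingestion: orbital/charge/frequency fixture
  dialect, Gaussian cube read/write, minimum verification, conformer
  selection
- `cdftkit.cdft_global` — global descriptors, λmax, KID diagnostics,
  ΔSCF route
- `cdftkit.cdft_local` — condensed and grid Fukui functions, dual
  descriptor, site ranking
- `cdftkit.druglikeness` — property block, Ro5, bioactivity bands
- `cdftkit.synthetic` — seeded generators and the Taltobulin bundle
- `cdftkit.pipeline` / `cdftkit.cli` — orchestration, reports, CLI

See `docs/methods.md` for the model conventions, numerical choices and
known limitations.
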