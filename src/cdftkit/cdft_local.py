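"""Local reactivity: Fukui functions and the dual descriptor.

Two computation routes are provided, matching the two kinds of artifact a
QM run produces:

* **Condensed (per-atom)** values from partial-charge triplets of the N,
  N-1 and N+1 electron states.  Working with charges q (not electron
  populations p = Z - q) the finite-difference forms are::

      f-_k = q_k(N-1) - q_k(N)      susceptibility to electrophilic attack
      f+_k = q_k(N)   - q_k(N+1)    susceptibility to nucleophilic attack
      df_k = f+_k - f-_k            dual descriptor

  With this sign choice the condensed values are positive where electron
  density responds, and they inherit the exact sum rules
  sum(f-) = sum(f+) = 1, sum(df) = 0 whenever each charge set conserves
  its own net charge exactly.  (The literature mixes population- and
  charge-based conventions; see the worked example in the docs.)

* **Grid-based** fields from electron-density cubes::

      f-(r) = rho_N(r)   - rho_{N-1}(r)
      f+(r) = rho_{N+1}(r) - rho_N(r)
      df(r) = f+(r) - f-(r)

  each of which integrates to 1 (resp. 0) when the densities integrate to
  their electron counts.  No condensation from grids to atoms is done
  here; condensed values come only from charge triplets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qm_io import ChargeSet, VolumetricGrid

__all__ = [
    "CondensedFukui",
    "condensed_fukui",
    "grid_fukui",
    "grid_integral",
    "rank_sites",
]


@dataclass(frozen=True)
class CondensedFukui:
    """Per-atom Fukui values f-, f+ and dual descriptor for one scheme."""

    scheme: str
    atom_labels: tuple[str, ...]
    f_minus: tuple[float, ...]
    f_plus: tuple[float, ...]
    dual: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.f_minus)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular view: 1-based atom index, label, f-, f+, dual."""
        return pd.DataFrame(
            {
                "atom": np.arange(1, len(self) + 1),
                "label": list(self.atom_labels),
                "f_minus": self.f_minus,
                "f_plus": self.f_plus,
                "dual": self.dual,
            }
        )

    def sums(self) -> tuple[float, float, float]:
        return (float(sum(self.f_minus)), float(sum(self.f_plus)), float(sum(self.dual)))


def condensed_fukui(
    q_n: ChargeSet, q_nm1: ChargeSet, q_np1: ChargeSet
) -> CondensedFukui:
    """Condensed Fukui functions from an N / N-1 / N+1 charge triplet.

    The three sets must share scheme, atom count and labels, and the ionic
    sets must differ from the neutral one by exactly +1 (cation) and -1
    (anion) elementary charges.
    """
    if not (q_n.scheme == q_nm1.scheme == q_np1.scheme):
        raise ValueError(
            f"charge scheme mismatch: {q_n.scheme}/{q_nm1.scheme}/{q_np1.scheme}"
        )
    if not (len(q_n) == len(q_nm1) == len(q_np1)):
        raise ValueError(
            f"atom count mismatch: {len(q_n)}/{len(q_nm1)}/{len(q_np1)}"
        )
    if q_n.atom_labels != q_nm1.atom_labels or q_n.atom_labels != q_np1.atom_labels:
        raise ValueError("atom labels differ between charge sets")
    if q_nm1.net_charge != q_n.net_charge + 1:
        raise ValueError(
            f"N-1 set must carry net charge {q_n.net_charge + 1}, "
            f"got {q_nm1.net_charge}"
        )
    if q_np1.net_charge != q_n.net_charge - 1:
        raise ValueError(
            f"N+1 set must carry net charge {q_n.net_charge - 1}, "
            f"got {q_np1.net_charge}"
        )
    qn = np.asarray(q_n.q)
    f_minus = np.asarray(q_nm1.q) - qn
    f_plus = qn - np.asarray(q_np1.q)
    dual = f_plus - f_minus
    return CondensedFukui(
        scheme=q_n.scheme,
        atom_labels=q_n.atom_labels,
        f_minus=tuple(f_minus.tolist()),
        f_plus=tuple(f_plus.tolist()),
        dual=tuple(dual.tolist()),
    )


def grid_fukui(
    rho_n: VolumetricGrid, rho_nm1: VolumetricGrid, rho_np1: VolumetricGrid
) -> tuple[VolumetricGrid, VolumetricGrid, VolumetricGrid]:
    """Voxelwise Fukui fields (f-, f+, dual) from a density-cube triplet.

    The three grids must be congruent (identical origin, axes and counts
    to 1e-8 bohr); no resampling is attempted.
    """
    for name, g in (("rho_nm1", rho_nm1), ("rho_np1", rho_np1)):
        if not rho_n.same_geometry(g):
            raise ValueError(
                f"grid {name} is not congruent with rho_n "
                f"(counts {g.counts} vs {rho_n.counts})"
            )
    f_minus = rho_n.values - rho_nm1.values
    f_plus = rho_np1.values - rho_n.values
    return (
        rho_n.with_values(f_minus),
        rho_n.with_values(f_plus),
        rho_n.with_values(f_plus - f_minus),
    )


def grid_integral(g: VolumetricGrid) -> float:
    """Riemann integral of a grid field: sum(values) * voxel volume."""
    return float(g.values.sum() * g.voxel_volume)


def rank_sites(
    cf: CondensedFukui, which: str = "f_minus", k: int | None = None
) -> list[tuple[int, float]]:
    """Top-k reactive sites as (1-based atom index, value), descending.

    ``which`` selects ``f_minus`` (electrophilic attack), ``f_plus``
    (nucleophilic attack) or ``dual``.  Ties break toward the lower atom
    index.
    """
    try:
        values = getattr(cf, which)
    except AttributeError:
        raise ValueError(f"unknown selector {which!r}") from None
    if which not in ("f_minus", "f_plus", "dual"):
        raise ValueError(f"unknown selector {which!r}")
    n = len(values)
    if k is None:
        k = n
    if not 0 <= k <= n:
        raise ValueError(f"k = {k} out of range for {n} atoms")
    order = sorted(range(n), key=lambda i: (-values[i], i))
    return [(i + 1, float(values[i])) for i in order[:k]]
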