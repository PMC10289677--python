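"""Conversion between cytosolic dry-mass density and volume occupancy.

Treating the dry mass as a two-component protein/RNA mixture, the specific
density of dry mass is the mass-fraction-weighted combination

    D(r) = rho_protein / (1 + r) + rho_RNA * r / (1 + r),

where r is the RNA/protein mass ratio, and the volume occupancy follows as
rho = rho_DM / D(r) from the measured cytosolic dry-mass density rho_DM.
The RNA specific density is derived from the ribosome (1.637 g/mL, 61.87%
RNA by mass) by the same linear mixing rule, giving 1.81 g/mL.  The growth
law r = 0.087 + mu / (4.5 h^-1) supplies r when only the growth rate is
known; alternatively a user-supplied (mu, r) table is interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CompositionDensities",
    "DensityPoint",
    "rna_density_from_ribosome",
    "specific_dry_mass_density",
    "occupancy_from_density",
    "rna_protein_ratio",
]


@dataclass(frozen=True)
class CompositionDensities:
    """Specific densities (g/mL) of the dry-mass components."""

    protein_density: float = 1.35
    ribosome_density: float = 1.637
    ribosome_rna_mass_fraction: float = 0.6187

    @property
    def rna_density(self) -> float:
        return rna_density_from_ribosome(self)


DEFAULT_DENSITIES = CompositionDensities()


def rna_density_from_ribosome(cd: CompositionDensities = DEFAULT_DENSITIES) -> float:
    """RNA specific density from the ribosome's density and composition.

    Solves the linear mass-fraction mixing rule
    rho_ribo = f_RNA * rho_RNA + (1 - f_RNA) * rho_protein for rho_RNA.
    """
    f = cd.ribosome_rna_mass_fraction
    if not 0.0 < f < 1.0:
        raise ValueError("ribosome RNA mass fraction must lie strictly in (0, 1)")
    return (cd.ribosome_density - (1.0 - f) * cd.protein_density) / f


def specific_dry_mass_density(r: float,
                              cd: CompositionDensities = DEFAULT_DENSITIES,
                              rna_density: float | None = None) -> float:
    """Specific density D (g/mL) of dry mass at RNA/protein mass ratio r.

    Convex combination of the protein and RNA specific densities weighted
    by their mass shares 1/(1+r) and r/(1+r); strictly increasing in r.
    By default the RNA density is the 1.81 g/mL derived from the ribosome
    rather than the rounded printed value.
    """
    if r < 0:
        raise ValueError(f"RNA/protein ratio must be >= 0, got {r}")
    rho_rna = rna_density_from_ribosome(cd) if rna_density is None else rna_density
    return (cd.protein_density + rho_rna * r) / (1.0 + r)


def occupancy_from_density(rho_dm: float, r: float,
                           cd: CompositionDensities = DEFAULT_DENSITIES,
                           rna_density: float | None = None) -> float:
    """Volume occupancy rho = rho_DM / D(r) from dry-mass density (g/mL)."""
    if rho_dm < 0:
        raise ValueError(f"dry-mass density must be >= 0, got {rho_dm}")
    return rho_dm / specific_dry_mass_density(r, cd, rna_density)


def rna_protein_ratio(mu: float, law: str = "scott",
                      table: Sequence[tuple[float, float]] | None = None) -> float:
    """RNA/protein mass ratio at growth rate mu (h^-1).

    ``law='scott'`` applies the linear growth law r = 0.087 + mu/4.5;
    ``law='table'`` linearly interpolates a user-supplied (mu, r) table,
    clamping at its endpoints.
    """
    if mu < 0:
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    if law == "scott":
        return 0.087 + mu / 4.5
    if law == "table":
        if not table:
            raise ValueError("table mode requires a non-empty (mu, r) table")
        pts = sorted(table)
        mus = np.array([p[0] for p in pts], dtype=float)
        rs = np.array([p[1] for p in pts], dtype=float)
        return float(np.interp(mu, mus, rs))
    raise ValueError(f"unknown law {law!r}")


@dataclass(frozen=True)
class DensityPoint:
    """One converted measurement: (mu, r, rho_DM) -> (D, rho)."""

    rho_dm: float
    r: float
    D: float
    rho: float
    mu: float | None = None

    @classmethod
    def from_measurement(cls, rho_dm: float, r: float | None = None,
                         mu: float | None = None, law: str = "scott",
                         table: Sequence[tuple[float, float]] | None = None,
                         cd: CompositionDensities = DEFAULT_DENSITIES) -> "DensityPoint":
        if r is None:
            if mu is None:
                raise ValueError("either r or mu must be given")
            r = rna_protein_ratio(mu, law=law, table=table)
        D = specific_dry_mass_density(r, cd)
        return cls(rho_dm=rho_dm, r=r, D=D, rho=rho_dm / D, mu=mu)
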