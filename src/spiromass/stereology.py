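"""Stereology of ribosome counts in thin sections.

Ribosomes (~20 nm) are the only cytoplasmic particles resolvable in thin
sections of freeze-substituted cells, so their number per section area can
be converted to a number per volume and then to a per-cell count. Two
corrections matter at these scales:

* beam-induced shrinkage -- the resin section thins by a factor of ~2 under
  irradiation, so the thickness measured from section folds must be scaled
  back up to the pre-irradiation value;
* the Holmes effect -- a sphere is counted whenever it intersects the slab,
  so the effective sampling thickness is the section thickness plus one
  sphere diameter, nu = n_A / (T_corrected + d).

The resulting number density feeds the per-cell ribosome count, ribosomal
mass and rRNA base budget, which can be cross-checked against the bulk
chemical RNA fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .constants import (
    DA_PER_NT_RNA,
    RIBOSOME_DIAMETER_NM,
    RIBOSOME_MASS_MDA,
    RIBOSOME_RNA_MASS_FRACTION,
)
from .exceptions import InconsistentInputsError, InvalidParameterError

__all__ = [
    "SectionCountData",
    "RibosomeBudget",
    "corrected_thickness",
    "number_density",
    "ribosome_budget",
    "chemical_rna_crosscheck",
    "read_section_counts_csv",
]


@dataclass(frozen=True)
class SectionCountData:
    """Ribosome profile counts for one section, with thickness metadata."""

    n_profiles: int
    counted_area_um2: float
    T_measured_nm: float                 # post-irradiation, from folds
    shrinkage_factor: float = 2.0
    d_ribosome_nm: float = RIBOSOME_DIAMETER_NM

    def __post_init__(self) -> None:
        if self.n_profiles < 0:
            raise InvalidParameterError("counts must be >= 0")
        if self.counted_area_um2 <= 0 or self.T_measured_nm <= 0:
            raise InvalidParameterError("area and thickness must be > 0")
        if self.shrinkage_factor < 1:
            raise InvalidParameterError("shrinkage factor must be >= 1")

    @property
    def n_A(self) -> float:
        """Profiles per um^2."""
        return self.n_profiles / self.counted_area_um2

    @property
    def T_corrected_nm(self) -> float:
        return corrected_thickness(self.T_measured_nm, self.shrinkage_factor)


@dataclass(frozen=True)
class RibosomeBudget:
    """Per-cell ribosome numbers, mass and rRNA content."""

    nu_per_um3: float
    N_per_cell: float
    volume_fraction: float
    M_ribosome_total_da: float
    rRNA_mass_da: float
    rRNA_bases: float

    def __post_init__(self) -> None:
        if self.volume_fraction >= 1:
            raise InconsistentInputsError(
                "ribosome volume fraction >= 1; inputs are inconsistent")


def corrected_thickness(T_measured_nm: float, shrinkage: float) -> float:
    """Pre-irradiation section thickness from the measured (shrunk) one."""
    if T_measured_nm <= 0 or shrinkage <= 0:
        raise InvalidParameterError("thickness and shrinkage must be > 0")
    return T_measured_nm * shrinkage


def number_density(n_A_per_um2: float, T_corrected_nm: float,
                   d_ribosome_nm: float = RIBOSOME_DIAMETER_NM) -> float:
    """Particles per um^3 from profiles per um^2, with the Holmes-effect
    effective thickness (T + d): any sphere intersecting the slab is seen."""
    if n_A_per_um2 < 0:
        raise InvalidParameterError("areal density must be >= 0")
    if T_corrected_nm <= 0 or d_ribosome_nm < 0:
        raise InvalidParameterError("thickness must be > 0, diameter >= 0")
    t_eff_um = (T_corrected_nm + d_ribosome_nm) * 1e-3
    return n_A_per_um2 / t_eff_um


def ribosome_budget(nu_per_um3: float, V_cell_nm3: float,
                    d_ribosome_nm: float = RIBOSOME_DIAMETER_NM,
                    m_ribosome_mda: float = RIBOSOME_MASS_MDA,
                    rna_mass_fraction: float = RIBOSOME_RNA_MASS_FRACTION,
                    ) -> RibosomeBudget:
    """Scale the number density up to the whole cell and convert to
    ribosomal mass and rRNA bases."""
    if nu_per_um3 < 0 or V_cell_nm3 <= 0:
        raise InvalidParameterError("density >= 0 and volume > 0 required")
    V_cell_um3 = V_cell_nm3 * 1e-9
    N = nu_per_um3 * V_cell_um3
    v_ribosome_um3 = (4.0 / 3.0) * math.pi * (d_ribosome_nm * 1e-3 / 2.0) ** 3
    volume_fraction = nu_per_um3 * v_ribosome_um3
    M_total = N * m_ribosome_mda * 1e6
    rRNA = rna_mass_fraction * M_total
    return RibosomeBudget(
        nu_per_um3=nu_per_um3,
        N_per_cell=N,
        volume_fraction=volume_fraction,
        M_ribosome_total_da=M_total,
        rRNA_mass_da=rRNA,
        rRNA_bases=rRNA / DA_PER_NT_RNA,
    )


def chemical_rna_crosscheck(M_cell_da: float, f_RNA: float,
                            m_ribosome_mda: float = RIBOSOME_MASS_MDA,
                            rna_mass_fraction: float = RIBOSOME_RNA_MASS_FRACTION,
                            ) -> tuple[float, float]:
    """Independent RNA estimate from bulk chemistry: the cell's RNA mass
    expressed as ribosome equivalents and as nucleotide bases.

    Returns ``(ribosome_equivalents, bases)``.
    """
    if not 0 <= f_RNA < 1:
        raise InvalidParameterError("f_RNA must be in [0, 1)")
    rna_mass = M_cell_da * f_RNA
    equivalents = rna_mass / (rna_mass_fraction * m_ribosome_mda * 1e6)
    return equivalents, rna_mass / DA_PER_NT_RNA


def read_section_counts_csv(path) -> list[SectionCountData]:
    """Read a count table with columns
    (section_id, n_profiles, area_um2, T_measured_nm[, shrinkage_factor])."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(SectionCountData(
            n_profiles=int(row["n_profiles"]),
            counted_area_um2=float(row["area_um2"]),
            T_measured_nm=float(row["T_measured_nm"]),
            shrinkage_factor=float(row.get("shrinkage_factor", 2.0) or 2.0),
        ))
    return out
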