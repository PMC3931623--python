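"""Integration of all measurements into a per-cell budget.

The helical symmetry lets local mass densities be extrapolated to the whole
cell: mass-per-length times contour length gives the total cell mass,
mass-per-area times membrane surface gives the membrane mass, and
ribbon mass-per-length times ribbon length gives the cytoskeleton mass.
Together with the stereological ribosome budget, the DNA-based genome
estimate and the hydration result, these close the budget: the component
mass fractions - each measured independently - should sum to ~1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

from .composition import GenomeEstimate
from .constants import (
    FIB_MONOMER_KDA,
    FIB_PER_TETRAMER,
    FIBRILS_PER_RIBBON,
    G_PER_CM3_PER_DA_PER_NM3,
    G_PER_DA,
    TETRAMER_REPEAT_NM,
)
from .exceptions import InconsistentInputsError, InvalidParameterError
from .geometry import propagate_ratio_sd
from .hydrodynamics import HydrationResult
from .stereology import RibosomeBudget

__all__ = [
    "CellInventory",
    "ClosureEntry",
    "cell_mass",
    "dry_density_geometric",
    "membrane_budget",
    "ribbon_budget",
    "closure_report",
    "build_inventory",
    "format_inventory_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClosureEntry:
    """One independently measured component of the mass budget."""

    component: str
    fraction: float
    sd: float


@dataclass
class CellInventory:
    """The integrated per-cell budget."""

    M_cell_da: float
    M_cell_g: float
    sd_M_cell_da: float
    M_memb_da: float
    f_memb: float
    M_R_da: float
    f_R: float
    N_fib_mass: float
    N_fib_geometric: float
    ribosomes: RibosomeBudget | None = None
    genome: GenomeEstimate | None = None
    hydration: HydrationResult | None = None
    closure: list[ClosureEntry] = field(default_factory=list)
    closure_residual: float | None = None

    def to_json(self, path) -> None:
        def default(o):
            return asdict(o)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=default)


# ---------------------------------------------------------------------------
# scale-up operations
# ---------------------------------------------------------------------------

def cell_mass(m_cell_mda_nm: float, L_cell_nm: float) -> tuple[float, float]:
    """Total cell mass in Da and in g from mass-per-length and contour
    length: M_cell = m_cell * L_cell."""
    if m_cell_mda_nm < 0 or L_cell_nm < 0:
        raise InvalidParameterError("inputs must be >= 0")
    M_da = m_cell_mda_nm * 1e6 * L_cell_nm
    return M_da, M_da * G_PER_DA


def dry_density_geometric(m_cell_mda_nm: float, d_nm: float) -> float:
    """Dry mass per hydrated cell volume (g/cm^3): mass-per-length divided
    by the tube cross-sectional area. Comparable to the dry mass fraction
    when the hydrated density is close to 1."""
    if m_cell_mda_nm < 0 or d_nm <= 0:
        raise InvalidParameterError("need mass >= 0 and diameter > 0")
    da_per_nm3 = m_cell_mda_nm * 1e6 / (math.pi * (d_nm / 2.0) ** 2)
    return da_per_nm3 * G_PER_CM3_PER_DA_PER_NM3


def membrane_budget(mu_memb_kda_nm2: float, S_cell_nm2: float,
                    M_cell_da: float) -> tuple[float, float]:
    """Membrane mass (Da) and membrane mass fraction of the cell:
    M_memb = mu * S_cell, f_memb = M_memb / M_cell."""
    if mu_memb_kda_nm2 < 0 or S_cell_nm2 <= 0 or M_cell_da <= 0:
        raise InvalidParameterError(
            "need mu >= 0, surface and cell mass > 0")
    M_memb = mu_memb_kda_nm2 * 1e3 * S_cell_nm2
    f = M_memb / M_cell_da
    if f > 1:
        raise InconsistentInputsError(
            f"membrane fraction {f:.2f} > 1; inputs are inconsistent")
    return M_memb, f


def ribbon_budget(m_R_kda_nm: float, L_R_nm: float, M_cell_da: float,
                  fib_mass_kda: float = FIB_MONOMER_KDA,
                  ) -> tuple[float, float, float, float]:
    """Cytoskeletal ribbon mass, its cell-mass fraction, and the Fib copy
    number by two independent routes.

    mass route:      N = M_R / fib monomer mass
    geometric route: N = 7 fibrils * 4 per tetramer * (L_R / 9 nm repeat)

    Returns ``(M_R_da, f_R, N_fib_mass, N_fib_geometric)``.
    """
    if min(m_R_kda_nm, L_R_nm) < 0 or M_cell_da <= 0:
        raise InvalidParameterError("invalid ribbon inputs")
    M_R_kda = m_R_kda_nm * L_R_nm
    M_R_da = M_R_kda * 1e3
    f_R = M_R_da / M_cell_da
    N_mass = M_R_kda / fib_mass_kda
    N_geom = FIBRILS_PER_RIBBON * FIB_PER_TETRAMER * (L_R_nm / TETRAMER_REPEAT_NM)
    return M_R_da, f_R, N_mass, N_geom


def closure_report(M_cell_da: float, components: dict[str, tuple[float, float]],
                   sd_M_cell_da: float = 0.0,
                   ) -> tuple[list[ClosureEntry], float]:
    """Mass fractions of independently measured components and the budget
    residual 1 - sum(fractions) (not forced to zero).

    ``components`` maps names to (mass_da, sd_da).
    """
    if M_cell_da <= 0:
        raise InvalidParameterError("M_cell must be > 0")
    entries = []
    for name, (mass, sd) in components.items():
        if mass < 0:
            raise InvalidParameterError(f"negative mass for {name!r}")
        if mass > M_cell_da:
            raise InconsistentInputsError(
                f"component {name!r} exceeds the total cell mass")
        frac = mass / M_cell_da
        sd_frac = (propagate_ratio_sd(mass, sd, M_cell_da, sd_M_cell_da)
                   if mass > 0 else 0.0)
        entries.append(ClosureEntry(name, frac, sd_frac))
    residual = 1.0 - sum(e.fraction for e in entries)
    return entries, residual


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_inventory(*, m_cell_mda_nm: float, sd_m_cell: float,
                    L_cell_nm: float, sd_L_cell: float,
                    mu_memb_kda_nm2: float, sd_mu_memb: float,
                    S_cell_nm2: float,
                    m_R_kda_nm: float, sd_m_R: float, L_R_nm: float,
                    ribosomes: RibosomeBudget | None = None,
                    sd_M_ribosome_da: float = 0.0,
                    genome: GenomeEstimate | None = None,
                    sd_M_DNA_da: float = 0.0,
                    hydration: HydrationResult | None = None,
                    ) -> CellInventory:
    """Assemble the full per-cell inventory with a closure report."""
    from .geometry import propagate_product_sd

    M_cell_da, M_cell_g = cell_mass(m_cell_mda_nm, L_cell_nm)
    sd_M_cell = propagate_product_sd(m_cell_mda_nm * 1e6, sd_m_cell * 1e6,
                                     L_cell_nm, sd_L_cell)
    M_memb, f_memb = membrane_budget(mu_memb_kda_nm2, S_cell_nm2, M_cell_da)
    sd_M_memb = sd_mu_memb / mu_memb_kda_nm2 * M_memb
    M_R, f_R, N_mass, N_geom = ribbon_budget(m_R_kda_nm, L_R_nm, M_cell_da)
    sd_M_R = sd_m_R / m_R_kda_nm * M_R

    components = {
        "membrane": (M_memb, sd_M_memb),
        "cytoskeleton": (M_R, sd_M_R),
    }
    if ribosomes is not None:
        components["ribosomes"] = (ribosomes.M_ribosome_total_da,
                                   sd_M_ribosome_da)
    if genome is not None:
        components["DNA"] = (genome.M_DNA_da, sd_M_DNA_da)
    closure, residual = closure_report(M_cell_da, components, sd_M_cell)

    return CellInventory(
        M_cell_da=M_cell_da, M_cell_g=M_cell_g, sd_M_cell_da=sd_M_cell,
        M_memb_da=M_memb, f_memb=f_memb,
        M_R_da=M_R, f_R=f_R,
        N_fib_mass=N_mass, N_fib_geometric=N_geom,
        ribosomes=ribosomes, genome=genome, hydration=hydration,
        closure=closure, closure_residual=residual,
    )


def format_inventory_table(inv: CellInventory) -> str:
    """Human-readable summary mirroring the reference table layout."""
    lines = [
        f"{'Quantity':42s} {'Value':>12s}  Units",
        "-" * 68,
        f"{'Mass per cell (M_cell)':42s} {inv.M_cell_da/1e9:12.3g}  GDa",
        f"{'Mass per cell (M_cell)':42s} {inv.M_cell_g:12.3g}  g",
        f"{'Membrane mass per cell (M_memb)':42s} {inv.M_memb_da/1e9:12.3g}  GDa",
        f"{'Membrane mass fraction (f_memb)':42s} {inv.f_memb:12.3g}",
        f"{'Ribbon mass per cell (M_R)':42s} {inv.M_R_da/1e3:12.4g}  kDa",
        f"{'Ribbon mass fraction (f_R)':42s} {inv.f_R:12.3g}",
        f"{'Fib copies (mass route)':42s} {inv.N_fib_mass:12.0f}",
        f"{'Fib copies (geometric route)':42s} {inv.N_fib_geometric:12.0f}",
    ]
    if inv.ribosomes is not None:
        r = inv.ribosomes
        lines += [
            f"{'Ribosomes per cell (N_ribosome)':42s} {r.N_per_cell:12.0f}",
            f"{'Ribosomal mass per cell (M_ribosome)':42s} {r.M_ribosome_total_da/1e9:12.3g}  GDa",
            f"{'rRNA bases per cell':42s} {r.rRNA_bases:12.3g}",
        ]
    if inv.genome is not None:
        lines += [
            f"{'DNA mass per cell (M_DNA)':42s} {inv.genome.M_DNA_da/1e9:12.3g}  GDa",
            f"{'Genome size':42s} {inv.genome.bp:12.3g}  bp",
        ]
    if inv.hydration is not None:
        h = inv.hydration
        lines += [
            f"{'Hydrated cell mass':42s} {h.hydrated_mass_g:12.3g}  g",
            f"{'Dry mass fraction':42s} {h.dry_fraction:12.3g}",
            f"{'Hydrated density':42s} {h.rho_hydrated_g_cm3:12.4g}  g/cm^3",
            f"{'Dry-component density':42s} {h.rho_dry_g_cm3:12.4g}  g/cm^3",
        ]
    if inv.closure:
        lines.append("-" * 68)
        for e in inv.closure:
            lines.append(f"{'Mass fraction: ' + e.component:42s} "
                         f"{e.fraction:12.3g}  +/- {e.sd:.2g}")
        lines.append(f"{'Closure residual (1 - sum)':42s} "
                     f"{inv.closure_residual:12.3g}")
    return "\n".join(lines)
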