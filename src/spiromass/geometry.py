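"""Analytic geometry of a helically coiled tubular cell.

A Spiroplasma cell is modelled as a tube of diameter ``d`` whose centerline
is a helix of pitch ``P`` and coil (centerline) diameter ``D`` with ``n``
turns. Because the cell is helically symmetric, lengths, volumes and
surfaces of the whole cell follow from one helical repeat:

    L_C  = sqrt((pi*D)^2 + P^2)          centerline length per turn
    l_R  = sqrt((pi*(D-d))^2 + P^2)      inner (shortest) line per turn,
                                         the path of the cytoskeletal ribbon
    V_C  = pi*(d/2)^2 * L_C              open-tube volume per turn
    S_C  = pi*d * L_C                    membrane surface per turn
    r    = n*P / (D + d)                 axial ratio of the coiled cell

Uncertainties are carried as SDs and propagated to first order, products and
ratios through the relative-error-in-quadrature rule that the source
measurements themselves used.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "HelicalCellParams",
    "GeometryDerived",
    "MembraneThicknessEstimate",
    "centerline_length_per_turn",
    "ribbon_length_per_turn",
    "cell_geometry",
    "propagate_product_sd",
    "propagate_ratio_sd",
    "membrane_thickness",
    "read_helix_params_csv",
    "write_geometry",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelicalCellParams:
    """Measured helix parameters of an average cell (all lengths in nm)."""

    pitch_P: float
    coil_centerline_diameter_Dcoil: float
    tube_diameter_d: float
    n_turns: float
    sd_P: float = 0.0
    sd_Dcoil: float = 0.0
    sd_d: float = 0.0
    sd_n: float = 0.0

    def __post_init__(self) -> None:
        if min(self.pitch_P, self.coil_centerline_diameter_Dcoil,
               self.tube_diameter_d, self.n_turns) <= 0:
            raise InvalidParameterError("all helix parameters must be > 0")
        if min(self.sd_P, self.sd_Dcoil, self.sd_d, self.sd_n) < 0:
            raise InvalidParameterError("SDs must be >= 0")

    @property
    def coil_outer_diameter(self) -> float:
        """D + d, the outer envelope diameter of the coiled cell."""
        return self.coil_centerline_diameter_Dcoil + self.tube_diameter_d

    @property
    def coil_inner_diameter(self) -> float:
        """D - d, the diameter of the innermost helical line."""
        return self.coil_centerline_diameter_Dcoil - self.tube_diameter_d


@dataclass(frozen=True)
class GeometryDerived:
    """Lengths, volumes and surfaces of one repeat and of the whole cell,
    each with a first-order propagated SD."""

    L_C: float
    L_cell: float
    V_C: float
    V_cell: float
    S_C: float
    S_cell: float
    axial_ratio_r: float
    nP_axial_length: float
    l_R: float
    L_R: float
    sd_L_C: float = 0.0
    sd_L_cell: float = 0.0
    sd_V_C: float = 0.0
    sd_V_cell: float = 0.0
    sd_S_C: float = 0.0
    sd_S_cell: float = 0.0
    sd_axial_ratio_r: float = 0.0
    sd_nP_axial_length: float = 0.0
    sd_l_R: float = 0.0
    sd_L_R: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as (name, mean, sd, units) rows."""
        units = {
            "L_C": "nm", "L_cell": "nm", "V_C": "nm^3", "V_cell": "nm^3",
            "S_C": "nm^2", "S_cell": "nm^2", "axial_ratio_r": "",
            "nP_axial_length": "nm", "l_R": "nm", "L_R": "nm",
        }
        d = asdict(self)
        rows = [(k, d[k], d["sd_" + k], units[k]) for k in units]
        return pd.DataFrame(rows, columns=["name", "mean", "sd", "units"])


@dataclass(frozen=True)
class MembraneThicknessEstimate:
    """Membrane thickness from differential-staining diameter comparison."""

    mean_diameter_UA: float        # unstained-membrane (cytoplasm) diameter, px
    mean_diameter_stained: float   # stained-membrane outer diameter, px
    pixel_size: float              # nm/px
    delta_d: float = field(init=False)
    t_memb: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.mean_diameter_UA < self.mean_diameter_stained:
            raise InvalidParameterError(
                "stained diameter must exceed the unstained diameter")
        dd = (self.mean_diameter_stained - self.mean_diameter_UA) * self.pixel_size
        object.__setattr__(self, "delta_d", dd)
        object.__setattr__(self, "t_memb", dd / 2.0)


# ---------------------------------------------------------------------------
# error propagation
# ---------------------------------------------------------------------------

def propagate_product_sd(X: float, sdX: float, Y: float, sdY: float) -> float:
    """SD of the product X*Y of two independent measured quantities.

    Uses |XY|*sqrt((sdX/X)^2 + (sdY/Y)^2); at a zero mean it falls back to
    the equivalent absolute form sqrt((Y*sdX)^2 + (X*sdY)^2).
    """
    if sdX < 0 or sdY < 0:
        raise InvalidParameterError("SDs must be >= 0")
    if X == 0 or Y == 0:
        return math.hypot(Y * sdX, X * sdY)
    return abs(X * Y) * math.hypot(sdX / X, sdY / Y)


def propagate_ratio_sd(X: float, sdX: float, Y: float, sdY: float) -> float:
    """SD of the ratio X/Y (same relative-quadrature rule as the product)."""
    if Y == 0:
        raise InvalidParameterError("ratio undefined for Y == 0")
    return abs(X / Y) * math.hypot(sdX / X if X else 0.0, sdY / Y)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def centerline_length_per_turn(P: float, Dcoil: float) -> float:
    """Arc length of the helical centerline over one pitch (nm)."""
    if P <= 0:
        raise InvalidParameterError(f"pitch must be > 0, got {P}")
    if Dcoil < 0:
        raise InvalidParameterError(f"coil diameter must be >= 0, got {Dcoil}")
    return math.hypot(math.pi * Dcoil, P)


def ribbon_length_per_turn(P: float, Dcoil: float, d: float) -> float:
    """Arc length per turn of the inner (shortest) helical line, the track
    followed by the cytoskeletal ribbon (nm)."""
    if P <= 0:
        raise InvalidParameterError(f"pitch must be > 0, got {P}")
    if not Dcoil > d >= 0:
        raise InvalidParameterError(
            f"need Dcoil > d >= 0, got Dcoil={Dcoil}, d={d}")
    return math.hypot(math.pi * (Dcoil - d), P)


def membrane_thickness(d_UA: float, d_stained: float,
                       pixel_size: float) -> MembraneThicknessEstimate:
    """Membrane thickness as half the projected-diameter difference between
    membrane-stained and membrane-unstained circular cross-sections."""
    return MembraneThicknessEstimate(d_UA, d_stained, pixel_size)


def cell_geometry(params: HelicalCellParams) -> GeometryDerived:
    """Derive the full geometric inventory of the cell from the measured
    helix parameters, with first-order SD propagation."""
    P, D, d, n = (params.pitch_P, params.coil_centerline_diameter_Dcoil,
                  params.tube_diameter_d, params.n_turns)
    sP, sD, sd_, sn = params.sd_P, params.sd_Dcoil, params.sd_d, params.sd_n

    L_C = centerline_length_per_turn(P, D)
    l_R = ribbon_length_per_turn(P, D, d)
    V_C = math.pi * (d / 2.0) ** 2 * L_C
    S_C = math.pi * d * L_C
    nP = n * P
    axial = nP / (D + d)

    # analytic partials for the helix arc lengths
    sd_L_C = math.hypot(P / L_C * sP, math.pi**2 * D / L_C * sD)
    sd_l_R = math.sqrt((P / l_R * sP) ** 2
                       + (math.pi**2 * (D - d) / l_R) ** 2 * (sD**2 + sd_**2))
    # products/ratios via the quadrature rule
    sd_V_C = propagate_product_sd(d * d, 2 * d * sd_, math.pi / 4 * L_C,
                                  math.pi / 4 * sd_L_C)
    sd_S_C = propagate_product_sd(math.pi * d, math.pi * sd_, L_C, sd_L_C)
    sd_nP = propagate_product_sd(n, sn, P, sP)
    sd_axial = propagate_ratio_sd(nP, sd_nP, D + d, math.hypot(sD, sd_))

    return GeometryDerived(
        L_C=L_C, L_cell=n * L_C,
        V_C=V_C, V_cell=n * V_C,
        S_C=S_C, S_cell=n * S_C,
        axial_ratio_r=axial, nP_axial_length=nP,
        l_R=l_R, L_R=n * l_R,
        sd_L_C=sd_L_C,
        sd_L_cell=propagate_product_sd(n, sn, L_C, sd_L_C),
        sd_V_C=sd_V_C,
        sd_V_cell=propagate_product_sd(n, sn, V_C, sd_V_C),
        sd_S_C=sd_S_C,
        sd_S_cell=propagate_product_sd(n, sn, S_C, sd_S_C),
        sd_axial_ratio_r=sd_axial,
        sd_nP_axial_length=sd_nP,
        sd_l_R=sd_l_R,
        sd_L_R=propagate_product_sd(n, sn, l_R, sd_l_R),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PARAM_ALIASES = {
    "P": "pitch_P", "pitch": "pitch_P", "pitch_P": "pitch_P",
    "D": "coil_centerline_diameter_Dcoil", "Dcoil": "coil_centerline_diameter_Dcoil",
    "coil_centerline_diameter_Dcoil": "coil_centerline_diameter_Dcoil",
    "d": "tube_diameter_d", "tube_diameter_d": "tube_diameter_d",
    "n": "n_turns", "n_turns": "n_turns",
}

_SD_FIELD = {"pitch_P": "sd_P", "coil_centerline_diameter_Dcoil": "sd_Dcoil",
             "tube_diameter_d": "sd_d", "n_turns": "sd_n"}


def read_helix_params_csv(path) -> HelicalCellParams:
    """Read a helix parameter table with columns (name, mean, sd, units).

    Accepted names: P/pitch, D/Dcoil, d, n (or the full field names).
    """
    df = pd.read_csv(path)
    kwargs: dict[str, float] = {}
    for _, row in df.iterrows():
        name = str(row["name"]).strip()
        if name not in _PARAM_ALIASES:
            raise InvalidParameterError(f"unknown helix parameter {name!r}")
        fld = _PARAM_ALIASES[name]
        kwargs[fld] = float(row["mean"])
        kwargs[_SD_FIELD[fld]] = float(row.get("sd", 0.0) or 0.0)
    return HelicalCellParams(**kwargs)


def write_geometry(derived: GeometryDerived, path, fmt: str = "csv") -> None:
    """Write the derived geometry as CSV (name, mean, sd, units) or JSON."""
    if fmt == "csv":
        derived.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(asdict(derived), fh, indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}")
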