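"""Sedimentation-velocity and light-scattering analysis of whole cells.

Whole live cells sediment at ~10^4 S while diffusing negligibly on the
experiment's timescale, so boundary data are modelled as superpositions of
Lamm-equation solutions for *non-diffusing* species (the ls-g*(s) approach):
each species contributes a step boundary at

    r_b(t) = r_meniscus * exp(s * omega^2 * t)

with the plateau diluting as c0 * exp(-2 s omega^2 t) in the sector-shaped
cell. Fitting a non-negative superposition over an s-grid yields the
sedimentation-coefficient distribution and its peak.

The average translational diffusion coefficient comes from a DLS
autocorrelation trace fitted as a single-exponential decay,
g2 - 1 = A * exp(-2 D q^2 tau). The Svedberg equation m_b = s k_B T / D
then gives the buoyant mass of a cell and, because the cell volume is known
independently from geometry, the full hydration budget: hydrated mass,
dry-mass fraction, and hydrated and dry densities.

Units: radii in cm, times in s, omega in rad/s, s in Svedberg (1e-13 s),
D in cm^2/s, masses in g, densities in g/cm^3 (CGS throughout).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, lsq_linear

from .constants import (
    CM3_PER_NM3,
    G_PER_DA,
    K_B_ERG_PER_K,
    NM_PER_CM,
    POISE_PER_MPAS,
    SVEDBERG_S,
)
from .exceptions import FitError, InconsistentInputsError, InvalidParameterError

__all__ = [
    "SedimentationProfileSet",
    "SDistribution",
    "DLSTrace",
    "HydrationResult",
    "rpm_to_omega",
    "scattering_vector_q",
    "simulate_nondiffusing_profiles",
    "fit_ls_g_star",
    "fit_dls_single_exponential",
    "stokes_einstein_diameter",
    "diffusion_from_diameter",
    "svedberg_buoyant_mass",
    "hydration_analysis",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SedimentationProfileSet:
    """Radial concentration profiles at a series of times."""

    radii: np.ndarray          # cm, strictly increasing
    times: np.ndarray          # s
    signal: np.ndarray         # (n_times, n_radii), fringe units
    omega: float               # rad/s
    meniscus_radius: float     # cm
    base_radius: float         # cm

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, float)
        self.times = np.asarray(self.times, float)
        self.signal = np.asarray(self.signal, float)
        if not np.all(np.diff(self.radii) > 0):
            raise InvalidParameterError("radii must be strictly increasing")
        if self.meniscus_radius >= self.base_radius:
            raise InvalidParameterError("meniscus must lie above the base")
        if self.omega <= 0:
            raise InvalidParameterError("omega must be > 0")
        if self.signal.shape != (len(self.times), len(self.radii)):
            raise InvalidParameterError("signal shape must be (n_times, n_radii)")


@dataclass
class SDistribution:
    """Sedimentation-coefficient distribution on a fixed s-grid."""

    s_grid: np.ndarray         # Svedberg
    weights: np.ndarray        # signal units per grid point, >= 0

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, float)
        self.weights = np.asarray(self.weights, float)
        if np.any(self.weights < -1e-12):
            raise InvalidParameterError("distribution weights must be >= 0")

    @property
    def peak_s(self) -> float:
        return float(self.s_grid[int(np.argmax(self.weights))])


@dataclass
class DLSTrace:
    """Normalized intensity autocorrelation decay, g2(tau) - 1."""

    lag_times: np.ndarray          # s
    g2_minus_1: np.ndarray
    angle_deg: float = 90.0
    wavelength_nm: float = 633.0
    temperature_K: float = 293.0
    solvent_viscosity_mpas: float = 1.0183
    refractive_index: float = 1.331

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, float)
        self.g2_minus_1 = np.asarray(self.g2_minus_1, float)
        if np.any(self.lag_times <= 0):
            raise InvalidParameterError("lag times must be > 0")

    @property
    def q_inv_cm(self) -> float:
        return scattering_vector_q(self.angle_deg, self.wavelength_nm,
                                   self.refractive_index)


@dataclass(frozen=True)
class HydrationResult:
    """Per-cell mass and density budget from the Svedberg route."""

    buoyant_mass_g: float
    hydrated_mass_g: float
    dry_mass_g: float
    dry_fraction: float
    rho_hydrated_g_cm3: float
    rho_dry_g_cm3: float
    buffer_density_g_cm3: float
    temperature_K: float = field(default=293.0)


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------

def rpm_to_omega(rpm: float) -> float:
    """Rotor speed in rpm to angular velocity in rad/s."""
    return rpm * 2.0 * math.pi / 60.0


def scattering_vector_q(angle_deg: float, wavelength_nm: float,
                        refractive_index: float) -> float:
    """DLS scattering vector magnitude q = 4 pi n sin(theta/2) / lambda,
    in cm^-1."""
    lam_cm = wavelength_nm / NM_PER_CM
    return (4.0 * math.pi * refractive_index / lam_cm
            * math.sin(math.radians(angle_deg) / 2.0))


# ---------------------------------------------------------------------------
# sedimentation: forward model and ls-g*(s) fit
# ---------------------------------------------------------------------------

def simulate_nondiffusing_profiles(s_svedberg: float, c0: float, omega: float,
                                   times, radii, meniscus: float,
                                   base: float | None = None,
                                   ) -> SedimentationProfileSet:
    """Step-boundary profiles of a single non-diffusing species in a
    sector-shaped cell.

    The boundary sits at r_b(t) = meniscus * exp(s w^2 t); behind it the
    signal is zero, ahead of it the plateau is c0 * exp(-2 s w^2 t)
    (radial dilution).
    """
    if s_svedberg <= 0:
        raise InvalidParameterError("s must be > 0")
    radii = np.asarray(radii, float)
    times = np.asarray(times, float)
    if np.any(radii < meniscus):
        raise InvalidParameterError("all radii must be >= meniscus")
    base = float(base) if base is not None else float(radii[-1])

    s_sec = s_svedberg * SVEDBERG_S
    tau = s_sec * omega**2 * times                     # dimensionless s*w^2*t
    r_b = meniscus * np.exp(tau)
    if np.any(r_b > base):
        warnings.warn("boundary reached the base; profiles truncated",
                      stacklevel=2)
    plateau = c0 * np.exp(-2.0 * tau)
    signal = np.where(radii[None, :] >= r_b[:, None],
                      plateau[:, None], 0.0)
    return SedimentationProfileSet(radii=radii, times=times, signal=signal,
                                   omega=omega, meniscus_radius=meniscus,
                                   base_radius=base)


def solution_column_mass(profiles: SedimentationProfileSet) -> np.ndarray:
    """Sector-geometry mass integral of each scan, integral of c r dr over
    (meniscus, base). Decreases over time as material pellets at the base."""
    return np.trapezoid(profiles.signal * profiles.radii[None, :],
                        profiles.radii, axis=1)


def default_s_grid(n: int = 100, s_min: float = 500.0,
                   s_max: float = 30000.0) -> np.ndarray:
    """Log-spaced s-grid in Svedberg units."""
    return np.geomspace(s_min, s_max, n)


def fit_ls_g_star(profiles: SedimentationProfileSet,
                  s_grid=None, regularization: float = 0.0,
                  fit_ti_noise: bool = False,
                  fit_ri_noise: bool = False) -> SDistribution:
    """Least-squares sedimentation-coefficient distribution.

    Fits the scan set as a non-negative superposition of unit-amplitude
    non-diffusing boundaries over ``s_grid``. Optional unconstrained terms
    absorb systematic noise: a time-invariant radial offset (one value per
    radius) and a radius-invariant per-scan offset. ``regularization`` adds
    a Tikhonov penalty on the distribution weights.
    """
    if len(profiles.times) < 2:
        raise InvalidParameterError("need at least 2 scans")
    s_grid = default_s_grid() if s_grid is None else np.asarray(s_grid, float)
    n_t, n_r = profiles.signal.shape

    cols = []
    with warnings.catch_warnings():
        # fully sedimented basis species are legitimate (zero) columns
        warnings.simplefilter("ignore", UserWarning)
        for s in s_grid:
            basis = simulate_nondiffusing_profiles(
                s, 1.0, profiles.omega, profiles.times, profiles.radii,
                profiles.meniscus_radius, profiles.base_radius)
            cols.append(basis.signal.ravel())
    n_s = len(cols)
    if fit_ti_noise:
        for j in range(n_r):
            col = np.zeros((n_t, n_r))
            col[:, j] = 1.0
            cols.append(col.ravel())
    if fit_ri_noise:
        for i in range(n_t):
            col = np.zeros((n_t, n_r))
            col[i, :] = 1.0
            cols.append(col.ravel())

    A = np.column_stack(cols)
    b = profiles.signal.ravel()

    if regularization == 0.0 and np.linalg.matrix_rank(A) < A.shape[1]:
        regularization = 1e-8 * float(np.abs(A).max()) ** 2
        logger.info("ill-conditioned ls-g*(s) design; raising Tikhonov "
                    "weight to %.3g", regularization)
    if regularization > 0.0:
        reg = np.zeros((n_s, A.shape[1]))
        reg[:, :n_s] = math.sqrt(regularization) * np.eye(n_s)
        A = np.vstack([A, reg])
        b = np.concatenate([b, np.zeros(n_s)])

    lb = np.full(A.shape[1], -np.inf)
    lb[:n_s] = 0.0
    res = lsq_linear(A, b, bounds=(lb, np.full(A.shape[1], np.inf)))
    weights = np.clip(res.x[:n_s], 0.0, None)
    return SDistribution(s_grid=s_grid, weights=weights)


# ---------------------------------------------------------------------------
# DLS
# ---------------------------------------------------------------------------

def fit_dls_single_exponential(trace: DLSTrace) -> float:
    """Average translational diffusion coefficient (cm^2/s) from a
    single-exponential fit g2-1 = A exp(-2 D q^2 tau)."""
    tau = trace.lag_times
    y = trace.g2_minus_1
    if len(tau) < 5:
        raise InvalidParameterError("need at least 5 lag points")
    if y[0] <= 0:
        raise FitError("non-positive initial amplitude")
    q2 = trace.q_inv_cm**2

    # fit the decay rate gamma = 2 D q^2 (order 10^2..10^3 s^-1), which is
    # far better conditioned than D (~1e-9) itself
    below = np.nonzero(y < y[0] / math.e)[0]
    tau_e = tau[below[0]] if below.size else tau[-1]
    p0 = (float(y[0]), 1.0 / tau_e)

    def model(t, A, gamma):
        return A * np.exp(-gamma * t)

    try:
        popt, _ = curve_fit(model, tau, y, p0=p0,
                            bounds=([0.0, 0.0], [np.inf, np.inf]),
                            maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"DLS fit did not converge: {exc}") from exc
    A, gamma = popt
    if gamma <= 0 or not np.isfinite(gamma):
        raise FitError("fitted trace does not decay")
    return float(gamma / (2.0 * q2))


def stokes_einstein_diameter(D_cm2_s: float, T_K: float,
                             viscosity_mpas: float) -> float:
    """Hydrodynamic (Stokes) diameter in nm from D via
    d = k_B T / (3 pi eta D)."""
    if min(D_cm2_s, T_K, viscosity_mpas) <= 0:
        raise InvalidParameterError("all inputs must be > 0")
    eta_poise = viscosity_mpas * POISE_PER_MPAS
    d_cm = K_B_ERG_PER_K * T_K / (3.0 * math.pi * eta_poise * D_cm2_s)
    return d_cm * NM_PER_CM


def diffusion_from_diameter(d_nm: float, T_K: float,
                            viscosity_mpas: float) -> float:
    """Inverse Stokes-Einstein: D (cm^2/s) of a sphere of diameter d_nm."""
    if min(d_nm, T_K, viscosity_mpas) <= 0:
        raise InvalidParameterError("all inputs must be > 0")
    eta_poise = viscosity_mpas * POISE_PER_MPAS
    return (K_B_ERG_PER_K * T_K
            / (3.0 * math.pi * eta_poise * d_nm / NM_PER_CM))


# ---------------------------------------------------------------------------
# Svedberg route to hydration
# ---------------------------------------------------------------------------

def svedberg_buoyant_mass(s_svedberg: float, T_K: float,
                          D_cm2_s: float) -> float:
    """Buoyant mass (g) of a particle via the Svedberg equation,
    m_b = s k_B T / D, assuming identical frictional coefficients for
    sedimentation and diffusion."""
    if s_svedberg < 0 or T_K <= 0 or D_cm2_s <= 0:
        raise InvalidParameterError("require s >= 0, T > 0, D > 0")
    return s_svedberg * SVEDBERG_S * K_B_ERG_PER_K * T_K / D_cm2_s


def hydration_analysis(m_b_g: float, V_cell_nm3: float,
                       rho_buffer_g_cm3: float, M_dry_da: float,
                       T_K: float = 293.0) -> HydrationResult:
    """Per-cell hydration budget from buoyant mass and known cell volume.

    hydrated mass = m_b + V_cell * rho_buffer (the displaced-buffer mass
    replaces the usual partial-specific volume); the dry fraction is the
    STEM dry mass over the hydrated mass; the dry density divides the dry
    mass by the volume not occupied by cell water, taking the intracellular
    water density equal to the buffer density.
    """
    if min(m_b_g, V_cell_nm3, rho_buffer_g_cm3, M_dry_da) < 0 or V_cell_nm3 == 0:
        raise InvalidParameterError("inputs must be positive")
    V_cm3 = V_cell_nm3 * CM3_PER_NM3
    hydrated = m_b_g + V_cm3 * rho_buffer_g_cm3
    dry = M_dry_da * G_PER_DA
    if dry >= hydrated:
        raise InconsistentInputsError("dry mass must be below hydrated mass")
    water = hydrated - dry
    water_volume = water / rho_buffer_g_cm3
    dry_volume = V_cm3 - water_volume
    if dry_volume <= 0:
        raise InconsistentInputsError(
            "computed water volume exceeds the cell volume")
    return HydrationResult(
        buoyant_mass_g=m_b_g,
        hydrated_mass_g=hydrated,
        dry_mass_g=dry,
        dry_fraction=dry / hydrated,
        rho_hydrated_g_cm3=hydrated / V_cm3,
        rho_dry_g_cm3=dry / dry_volume,
        buffer_density_g_cm3=rho_buffer_g_cm3,
        temperature_K=T_K,
    )
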