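import math

import numpy as np
import pytest

from spiromass import (
    DLSTrace,
    FitError,
    InconsistentInputsError,
    InvalidParameterError,
    fit_dls_single_exponential,
    fit_ls_g_star,
    hydration_analysis,
    simulate_nondiffusing_profiles,
    stokes_einstein_diameter,
    svedberg_buoyant_mass,
)
from spiromass.constants import K_B_ERG_PER_K, SVEDBERG_S
from spiromass.hydrodynamics import (
    default_s_grid,
    diffusion_from_diameter,
    rpm_to_omega,
    solution_column_mass,
)

OMEGA_3000 = rpm_to_omega(3000.0)     # 314.16 rad/s


def make_profiles(s=9930.0, times=None, n_r=200, noise=0.0, seed=0):
    times = np.linspace(0, 3600, 10) if times is None else times
    radii = np.linspace(6.0, 7.2, n_r)
    p = simulate_nondiffusing_profiles(s, 1.0, OMEGA_3000, times, radii,
                                       6.0, 7.2)
    if noise:
        p.signal = p.signal + np.random.default_rng(seed).normal(
            0, noise, p.signal.shape)
    return p


# ------------------------------------------------------------- simulator

def test_initial_scan_is_uniform_plateau():
    p = make_profiles(times=np.array([0.0, 600.0]))
    assert np.allclose(p.signal[0], 1.0)


def test_boundary_position_and_radial_dilution():
    # at s = 9,930 S, 3,000 rpm, t = 600 s: r_b/meniscus = exp(0.0588)
    tau = 9930 * SVEDBERG_S * OMEGA_3000**2 * 600.0
    assert tau == pytest.approx(0.0588, rel=0.01)
    p = make_profiles(times=np.array([0.0, 600.0]), n_r=2000)
    r_b_expected = 6.0 * math.exp(tau)
    first = p.radii[np.nonzero(p.signal[1] > 0)[0][0]]
    assert first == pytest.approx(r_b_expected, abs=1e-3)
    plateau = p.signal[1].max()
    assert plateau == pytest.approx(math.exp(-2 * tau), rel=1e-9)
    assert plateau == pytest.approx(0.889, rel=1e-3)


def test_sector_mass_conservation_with_pellet():
    """Solution-column mass + pelleted mass is conserved to 0.1%.

    The plateau dilutes radially while material pellets at the base at
    rate c_p s w^2 b^2, so the conserved quantity includes the pellet
    integral c0 b^2 (1 - exp(-2 s w^2 t)) / 2 (valid until the boundary
    itself reaches the base, ~1,860 s here).
    """
    p = make_profiles(n_r=4000, times=np.linspace(0, 1500, 8))
    s_sec = 9930 * SVEDBERG_S
    tau = s_sec * OMEGA_3000**2 * p.times
    pellet = 1.0 * p.base_radius**2 * (1 - np.exp(-2 * tau)) / 2
    total = solution_column_mass(p) + pellet
    assert np.allclose(total, total[0], rtol=1e-3)


def test_truncation_warning_when_boundary_passes_base():
    with pytest.warns(UserWarning):
        simulate_nondiffusing_profiles(
            50000.0, 1.0, OMEGA_3000, np.array([0.0, 36000.0]),
            np.linspace(6.0, 7.2, 50), 6.0, 7.2)


# ------------------------------------------------------------- ls-g*(s)

def test_ls_g_star_recovers_monodisperse_peak():
    p = make_profiles(s=9930.0)
    grid = default_s_grid(100, 500, 30000)
    dist = fit_ls_g_star(p, grid)
    step = grid[1] / grid[0]
    assert abs(math.log(dist.peak_s / 9930.0)) <= math.log(step)


def test_ls_g_star_recovers_mixture_modes():
    times = np.linspace(0, 3600, 10)
    radii = np.linspace(6.0, 7.2, 200)
    a = simulate_nondiffusing_profiles(4000.0, 0.5, OMEGA_3000, times, radii,
                                       6.0, 7.2)
    b = simulate_nondiffusing_profiles(10000.0, 0.5, OMEGA_3000, times, radii,
                                       6.0, 7.2)
    a.signal = a.signal + b.signal
    grid = default_s_grid(80, 1000, 20000)
    dist = fit_ls_g_star(a, grid)
    w = dist.weights / dist.weights.sum()
    # mass near each true mode (within one grid step either side)
    for s_true in (4000.0, 10000.0):
        near = np.abs(np.log(grid / s_true)) <= 1.5 * math.log(grid[1] / grid[0])
        assert w[near].sum() > 0.2


def test_ls_g_star_zero_signal_gives_zero_weights():
    p = make_profiles()
    p.signal = np.zeros_like(p.signal)
    dist = fit_ls_g_star(p, default_s_grid(40, 2000, 20000))
    assert np.allclose(dist.weights, 0.0, atol=1e-10)


def test_ls_g_star_with_systematic_offsets():
    p = make_profiles(s=9930.0, noise=0.0)
    rng = np.random.default_rng(5)
    radial_offset = rng.normal(0, 0.05, p.signal.shape[1])   # TI noise
    scan_offset = rng.normal(0, 0.05, p.signal.shape[0])     # RI noise
    p.signal = p.signal + radial_offset[None, :] + scan_offset[:, None]
    grid = default_s_grid(60, 2000, 20000)
    dist = fit_ls_g_star(p, grid, fit_ti_noise=True, fit_ri_noise=True)
    step = grid[1] / grid[0]
    assert abs(math.log(dist.peak_s / 9930.0)) <= math.log(step)


# ------------------------------------------------------------------ DLS

def make_trace(D=6.1e-9, noise=0.0, tau=None, seed=0, A=0.95):
    tau = np.geomspace(1e-6, 5e-2, 100) if tau is None else tau
    t = DLSTrace(lag_times=tau, g2_minus_1=np.zeros_like(tau))
    clean = A * np.exp(-2 * D * t.q_inv_cm**2 * tau)
    if noise:
        clean = clean + np.random.default_rng(seed).normal(0, noise, clean.shape)
    t.g2_minus_1 = clean
    return t


def test_dls_fit_recovers_diffusion_coefficient():
    assert fit_dls_single_exponential(make_trace()) == pytest.approx(
        6.1e-9, rel=1e-6)
    noisy = make_trace(noise=0.005, seed=2)
    assert fit_dls_single_exponential(noisy) == pytest.approx(6.1e-9, rel=0.01)


def test_dls_fit_rejects_flat_or_empty_trace():
    t = make_trace(A=0.0)
    with pytest.raises(FitError):
        fit_dls_single_exponential(t)


def test_dls_scale_invariance_q2_D_tau():
    """Doubling all lags with D halved yields the identical trace."""
    tau = np.geomspace(1e-6, 5e-2, 50)
    a = make_trace(D=6.1e-9, tau=tau)
    b = make_trace(D=3.05e-9, tau=2 * tau)
    assert np.allclose(a.g2_minus_1, b.g2_minus_1)


# --------------------------------------------------- Stokes-Einstein route

def test_stokes_einstein_reference_diameter():
    # D = 6.1e-9 cm^2/s at 293 K in 1.0183 mPa*s -> ~700 nm sphere
    d = stokes_einstein_diameter(6.1e-9, 293.0, 1.0183)
    assert d == pytest.approx(700.0, rel=0.02)
    # inverse route: a 400 nm sphere diffuses at ~1.06e-8 cm^2/s
    assert diffusion_from_diameter(400.0, 293.0, 1.0183) == pytest.approx(
        1.06e-8, rel=0.01)
    # algebraic identity: d * D is fixed at given T, eta
    assert stokes_einstein_diameter(2 * 6.1e-9, 293.0, 1.0183) == pytest.approx(
        d / 2, rel=1e-12)


def test_svedberg_buoyant_mass():
    m_b = svedberg_buoyant_mass(9930.0, 293.0, 6.1e-9)
    assert m_b == pytest.approx(6.59e-15, rel=0.005)
    assert svedberg_buoyant_mass(0.0, 293.0, 6.1e-9) == 0.0
    assert svedberg_buoyant_mass(9930.0, 293.0, 2 * 6.1e-9) == pytest.approx(
        m_b / 2, rel=1e-12)
    # exact consistency: m_b * D / (k_B T) = s in seconds
    assert m_b * 6.1e-9 / (K_B_ERG_PER_K * 293.0) == pytest.approx(
        9930.0 * SVEDBERG_S, rel=1e-12)


def test_hydration_analysis_reference_budget():
    m_b = svedberg_buoyant_mass(9930.0, 293.0, 6.1e-9)
    h = hydration_analysis(m_b, 1.65e8, 1.00741, 22.2e9)
    assert h.rho_dry_g_cm3 == pytest.approx(1.23, rel=0.01)
    assert h.dry_fraction == pytest.approx(0.213, rel=0.01)
    assert h.rho_hydrated_g_cm3 == pytest.approx(1.047, rel=0.005)
    assert h.rho_dry_g_cm3 > h.rho_hydrated_g_cm3 > h.buffer_density_g_cm3


def test_hydration_analysis_internal_balance():
    """Dry + water mass = hydrated mass; dry + water volume = cell volume."""
    h = hydration_analysis(6.59e-15, 1.65e8, 1.00741, 22.2e9)
    water_mass = h.hydrated_mass_g - h.dry_mass_g
    assert h.dry_mass_g + water_mass == pytest.approx(
        h.hydrated_mass_g, rel=1e-12)
    water_volume = water_mass / h.buffer_density_g_cm3
    dry_volume = h.dry_mass_g / h.rho_dry_g_cm3
    assert water_volume + dry_volume == pytest.approx(1.65e8 * 1e-21, rel=1e-12)


def test_hydration_analysis_rejects_empty_particle():
    # neutrally buoyant, massless particle: dry density undefined
    with pytest.raises((InconsistentInputsError, InvalidParameterError)):
        hydration_analysis(0.0, 1.65e8, 1.00741, 0.0)
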