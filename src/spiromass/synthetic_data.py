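"""Synthetic instrument data with known ground truth.

Each generator emulates one of the study's instruments at the statistical
structure the analysis assumes, so that every estimator in the package can
be tested for recovery without any external data:

* ``gen_cell_population``   -- truncated-normal helix parameters;
* ``gen_darkfield_image``   -- straight tube segments, TMV rods and flat
  vesicle patches rendered with pixel intensity proportional to projected
  mass plus Poisson shot noise at the nominal electron dose;
* ``gen_sedimentation_data``-- superposed non-diffusing boundaries with
  radial dilution, Gaussian fringe noise and optional systematic offsets;
* ``gen_dls_trace``         -- single-exponential autocorrelation decay;
* ``gen_ribosome_sections`` -- Poisson sphere fields sectioned into slabs
  with any-intersection (Holmes) visibility;
* ``gen_composition_table`` -- the bulk-chemistry table with replicate
  measurement noise.

All generators take a ``GeneratorConfig`` whose defaults are the measured
study conditions (see ``spiromass.params``) and an integer seed; outputs
are bit-reproducible for a fixed seed and carry their ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import params
from .constants import TMV_DIAMETER_NM, TMV_LENGTH_NM, TMV_MPL_MDA_PER_NM
from .exceptions import InvalidParameterError
from .geometry import HelicalCellParams
from .hydrodynamics import (
    DLSTrace,
    SedimentationProfileSet,
    rpm_to_omega,
    simulate_nondiffusing_profiles,
)
from .stem_massmap import DarkFieldImage, SegmentROI
from .stereology import SectionCountData

__all__ = [
    "GeneratorConfig",
    "gen_cell_population",
    "gen_darkfield_image",
    "gen_sedimentation_data",
    "gen_dls_trace",
    "gen_ribosome_sections",
    "gen_composition_table",
]


@dataclass
class GeneratorConfig:
    """True parameter set and noise settings for all generators.

    Defaults are the measured study conditions; a fixed seed makes every
    generator bit-reproducible.
    """

    seed: int = 0

    # helix population (mean, SD)
    pitch_nm: tuple[float, float] = params.HELIX_PITCH_NM
    coil_diameter_nm: tuple[float, float] = params.HELIX_COIL_DIAMETER_NM
    tube_diameter_nm: tuple[float, float] = params.HELIX_TUBE_DIAMETER_NM
    n_turns: tuple[float, float] = params.HELIX_N_TURNS

    # STEM truth and imaging
    m_cell_mda_nm: tuple[float, float] = params.CELL_MASS_PER_LENGTH_MDA_NM
    mu_memb_kda_nm2: tuple[float, float] = params.MEMBRANE_MASS_PER_AREA_KDA_NM2
    m_R_kda_nm: tuple[float, float] = params.RIBBON_MASS_PER_LENGTH_KDA_NM
    electron_dose_per_nm2: float = params.ELECTRON_DOSE_PER_NM2
    pixel_size_nm: float = params.IMAGE_PIXEL_NM
    image_size_px: int = params.IMAGE_SIZE_PX
    # scattering efficiency (detector counts per incident electron per
    # Da/nm^2 of projected mass) and carbon-film background fraction
    scattering_per_da_nm2: float = 2e-6
    background_fraction: float = 5e-3
    shot_noise: bool = True

    # hydrodynamics truth
    s_species: tuple[tuple[float, float], ...] = ((params.SEDIMENTATION_S, 1.0),)
    rotor_rpm: float = params.ROTOR_RPM
    fringe_noise_sd: float = 0.0
    D_cm2_s: float = params.DIFFUSION_CM2_S
    dls_noise_sd: float = 0.005
    dls_amplitude: float = 0.95

    # stereology truth
    nu_ribosome_per_um3: float = 8754.0
    section_T_true_nm: float = 90.0
    section_shrinkage: float = params.SECTION_SHRINKAGE_FACTOR
    d_ribosome_nm: float = 20.0
    section_area_um2: float = 25.0

    # composition truth
    total_dry_mass_ug: float = params.TOTAL_DRY_MASS_UG
    composition_noise: bool = True

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# helix population
# ---------------------------------------------------------------------------

def gen_cell_population(config: GeneratorConfig,
                        n_cells: int = 100) -> list[HelicalCellParams]:
    """Draw a population of helix parameter sets (truncated normal,
    rejecting non-physical draws with P, D, d, n <= 0 or D <= d)."""
    rng = config.rng()
    out: list[HelicalCellParams] = []
    while len(out) < n_cells:
        P = rng.normal(*config.pitch_nm)
        D = rng.normal(*config.coil_diameter_nm)
        d = rng.normal(*config.tube_diameter_nm)
        n = rng.normal(*config.n_turns)
        if min(P, D, d, n) <= 0 or D <= d:
            continue
        out.append(HelicalCellParams(
            pitch_P=P, coil_centerline_diameter_Dcoil=D,
            tube_diameter_d=d, n_turns=n,
            sd_P=config.pitch_nm[1], sd_Dcoil=config.coil_diameter_nm[1],
            sd_d=config.tube_diameter_nm[1], sd_n=config.n_turns[1]))
    return out


# ---------------------------------------------------------------------------
# dark-field image
# ---------------------------------------------------------------------------

def _expected_counts(mass_da_per_nm2: np.ndarray,
                     config: GeneratorConfig) -> np.ndarray:
    """Expected detector counts per pixel: dose * pixel area * (carbon-film
    background + scattering efficiency * projected mass density)."""
    a_px = config.pixel_size_nm**2
    return (config.electron_dose_per_nm2 * a_px
            * (config.background_fraction
               + config.scattering_per_da_nm2 * mass_da_per_nm2))


def gen_darkfield_image(config: GeneratorConfig,
                        n_segments: int = 2, n_tmv: int = 2,
                        n_patches: int = 1,
                        ) -> tuple[DarkFieldImage, list[SegmentROI], dict]:
    """Render a dark-field field of view with straight Spiroplasma tube
    segments, TMV calibration rods and flat collapsed-vesicle patches.

    Projected mass is spread uniformly across each object's width (the
    linear-mass model); per-pixel counts are Poisson at the configured
    electron dose. Returns the image, matching ROI annotations and a
    ground-truth dict with the per-object true densities.
    """
    rng = config.rng()
    size = config.image_size_px
    px = config.pixel_size_nm
    mass = np.zeros((size, size))       # projected mass density, Da/nm^2

    rois: list[SegmentROI] = []
    truth: dict = {"m_cell_true": [], "mu_memb_true": [],
                   "tmv_mpl": TMV_MPL_MDA_PER_NM}

    tube_w_px = max(3, int(round(params.HELIX_TUBE_DIAMETER_NM[0] / px)))
    tmv_w_px = max(2, int(round(TMV_DIAMETER_NM / px)))
    tmv_len_px = int(round(TMV_LENGTH_NM / px))

    n_rows = n_segments + n_tmv + n_patches
    patch_h_px = tube_w_px
    row_h = size // max(n_rows, 1)
    band = 5.0   # default ROI background band width, px
    if row_h < tube_w_px + 2 * band + 4:
        raise InvalidParameterError(
            "image too small for the requested number of objects")

    def row_center(i):
        return int((i + 0.5) * row_h)

    def paint_linear(roi: SegmentROI, mpl_mda_nm: float) -> None:
        # spread the ROI's total mass uniformly over its own pixel mask so
        # the noiseless measurement is exact by construction
        m = roi.mask(mass.shape)
        total_da = mpl_mda_nm * 1e6 * roi.length_px * px
        mass[m] += total_da / (m.sum() * px**2)

    def paint_patch(roi: SegmentROI, mu_kda_nm2: float) -> None:
        mass[roi.mask(mass.shape)] += mu_kda_nm2 * 1e3

    idx = 0
    for _ in range(n_segments):
        m_true = 0.0
        while m_true <= 0:
            m_true = rng.normal(*config.m_cell_mda_nm)       # MDa/nm
        y = row_center(idx); idx += 1
        length_px = int(0.7 * size)
        x0 = (size - length_px) // 2
        roi = SegmentROI(kind="tube_segment", p0=(x0, y),
                         p1=(x0 + length_px, y), width=float(tube_w_px))
        paint_linear(roi, m_true)
        rois.append(roi)
        truth["m_cell_true"].append(m_true)

    for _ in range(n_tmv):
        y = row_center(idx); idx += 1
        x0 = (size - tmv_len_px) // 2
        roi = SegmentROI(kind="tmv_rod", p0=(x0, y),
                         p1=(x0 + tmv_len_px, y), width=float(tmv_w_px))
        paint_linear(roi, TMV_MPL_MDA_PER_NM)
        rois.append(roi)

    for _ in range(n_patches):
        mu_true = 0.0
        while mu_true <= 0:
            mu_true = rng.normal(*config.mu_memb_kda_nm2)    # kDa/nm^2
        y = row_center(idx); idx += 1
        w_px = int(0.5 * size)
        x0 = (size - w_px) // 2
        half = patch_h_px // 2
        poly = np.array([[x0, y - half], [x0 + w_px, y - half],
                         [x0 + w_px, y + half], [x0, y + half]], float)
        roi = SegmentROI(kind="vesicle_patch", polygon=poly)
        paint_patch(roi, mu_true)
        rois.append(roi)
        truth["mu_memb_true"].append(mu_true)

    expected = _expected_counts(mass, config)
    counts = rng.poisson(expected).astype(float) if config.shot_noise else expected
    image = DarkFieldImage(intensity=counts, pixel_size=px,
                           metadata={"dose_e_per_nm2": config.electron_dose_per_nm2})
    return image, rois, truth


# ---------------------------------------------------------------------------
# sedimentation and DLS
# ---------------------------------------------------------------------------

def gen_sedimentation_data(config: GeneratorConfig,
                           times_s=None, radii_cm=None,
                           meniscus_cm: float = 6.0, base_cm: float = 7.2,
                           ) -> SedimentationProfileSet:
    """Superposition of non-diffusing boundaries for the configured species
    list ((s_svedberg, c0) pairs), plus optional Gaussian fringe noise."""
    rng = config.rng()
    omega = rpm_to_omega(config.rotor_rpm)
    if times_s is None:
        times_s = np.linspace(0.0, 3600.0, 13)
    if radii_cm is None:
        radii_cm = np.linspace(meniscus_cm, base_cm, 240)
    total = None
    for s, c0 in config.s_species:
        p = simulate_nondiffusing_profiles(s, c0, omega, times_s, radii_cm,
                                           meniscus_cm, base_cm)
        total = p.signal if total is None else total + p.signal
    if config.fringe_noise_sd > 0:
        total = total + rng.normal(0.0, config.fringe_noise_sd, total.shape)
    return SedimentationProfileSet(radii=np.asarray(radii_cm, float),
                                   times=np.asarray(times_s, float),
                                   signal=total, omega=omega,
                                   meniscus_radius=meniscus_cm,
                                   base_radius=base_cm)


def gen_dls_trace(config: GeneratorConfig, tau_s=None) -> DLSTrace:
    """Single-exponential g2-1 decay at 90 deg / 633 nm / 293 K with
    additive Gaussian noise."""
    rng = config.rng()
    if tau_s is None:
        tau_s = np.geomspace(1e-6, 5e-2, 120)
    trace = DLSTrace(lag_times=np.asarray(tau_s, float),
                     g2_minus_1=np.zeros(len(tau_s)),
                     angle_deg=params.DLS_ANGLE_DEG,
                     wavelength_nm=params.DLS_WAVELENGTH_NM,
                     temperature_K=params.TEMPERATURE_K,
                     solvent_viscosity_mpas=params.DLS_VISCOSITY_MPAS,
                     refractive_index=params.REFRACTIVE_INDEX)
    q2 = trace.q_inv_cm**2
    clean = config.dls_amplitude * np.exp(
        -2.0 * config.D_cm2_s * q2 * trace.lag_times)
    noise = (rng.normal(0.0, config.dls_noise_sd, clean.shape)
             if config.dls_noise_sd > 0 else 0.0)
    trace.g2_minus_1 = clean + noise
    return trace


# ---------------------------------------------------------------------------
# stereology
# ---------------------------------------------------------------------------

def gen_ribosome_sections(config: GeneratorConfig,
                          n_sections: int = 8) -> list[SectionCountData]:
    """Place Poisson sphere centers at the true number density in a 3-D
    box and count spheres intersecting a central slab of the true section
    thickness (visibility = any intersection, so the expected areal count
    is nu * (T + d)). The reported thickness is the post-shrinkage value
    T_true / shrinkage, as a fold measurement would give."""
    rng = config.rng()
    nu = config.nu_ribosome_per_um3
    T_um = config.section_T_true_nm * 1e-3
    d_um = config.d_ribosome_nm * 1e-3
    area = config.section_area_um2
    side = math.sqrt(area)
    depth = T_um + 2 * d_um            # box tall enough for edge spheres
    out = []
    for _ in range(n_sections):
        n_pts = rng.poisson(nu * area * depth)
        z = rng.uniform(0.0, depth, n_pts)
        # slab occupies [d, d+T]; a sphere of diameter d intersects it when
        # its center lies within d/2 of the slab
        lo, hi = d_um - d_um / 2.0, d_um + T_um + d_um / 2.0
        count = int(np.count_nonzero((z > lo) & (z < hi)))
        out.append(SectionCountData(
            n_profiles=count, counted_area_um2=area,
            T_measured_nm=config.section_T_true_nm / config.section_shrinkage,
            shrinkage_factor=config.section_shrinkage,
            d_ribosome_nm=config.d_ribosome_nm))
    return out


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def gen_composition_table(config: GeneratorConfig) -> pd.DataFrame:
    """Bulk-chemistry table drawn around the measured weights.

    With ``composition_noise`` off (or all SDs zero) the measured table is
    reproduced exactly; otherwise each weight is drawn normally around its
    true value with the stated replicate SD, truncated at zero.
    """
    rng = config.rng()
    df = params.composition_table().copy()
    scale = config.total_dry_mass_ug / params.TOTAL_DRY_MASS_UG
    df["weight_ug"] *= scale
    df["sd_ug"] *= scale
    if config.composition_noise:
        drawn = rng.normal(df.weight_ug, df.sd_ug)
        df["weight_ug"] = np.clip(drawn, 0.0, None)
    return df
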