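"""Quantitative annular dark-field (STEM) mass mapping.

In low-dose annular dark-field STEM the detector signal is, to a good
approximation, proportional to the projected dry mass in each pixel.
Integrating the background-subtracted signal over a region of interest and
dividing by the tobacco-mosaic-virus internal standard (0.131 MDa/nm, from
39.3 MDa over 300 nm) therefore converts image intensity directly to mass.
Because specimen and standard share the image, the calibration cancels the
detector gain and the uniform carbon-film background.

Workflow: ``net_signal`` integrates a ROI above its local background (the
median of a surrounding band), ``calibrate_with_tmv`` turns the TMV rods'
per-length signals into a Da-per-detector-unit factor, and
``mass_per_length`` / ``mass_per_area`` apply it to straight tube segments
(MDa/nm) and flat collapsed-vesicle patches (kDa/nm^2), attaching a
Gaussian fit to the resulting population histogram.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.draw import polygon2mask

from .constants import TMV_MPL_MDA_PER_NM
from .exceptions import CalibrationError, InvalidParameterError

__all__ = [
    "DarkFieldImage",
    "SegmentROI",
    "MassCalibration",
    "NetSignal",
    "MassHistogram",
    "net_signal",
    "calibrate_with_tmv",
    "mass_per_length",
    "mass_per_area",
    "fit_gaussian_histogram",
    "read_darkfield_tiff",
    "write_darkfield_tiff",
    "load_rois_json",
    "save_rois_json",
]

ROI_KINDS = ("tube_segment", "tmv_rod", "vesicle_patch")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DarkFieldImage:
    """A dark-field detector image with its pixel calibration."""

    intensity: np.ndarray        # 2-D, detector units, >= 0
    pixel_size: float            # nm per pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, float)
        if self.intensity.ndim != 2:
            raise InvalidParameterError("image must be 2-D")
        if np.any(self.intensity < 0):
            raise InvalidParameterError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel size must be > 0")


@dataclass
class SegmentROI:
    """A measured region: a linear ROI (axis endpoints + width, for tube
    segments and TMV rods) or a polygon patch (for vesicle areas).

    Coordinates are 0-based pixel units, (x, y) with y increasing downward.
    """

    kind: str
    p0: tuple[float, float] | None = None     # linear ROI axis start (x, y)
    p1: tuple[float, float] | None = None     # linear ROI axis end
    width: float | None = None                # px, full width
    polygon: np.ndarray | None = None         # (N, 2) array of (x, y)
    background_band_width: float = 5.0        # px

    def __post_init__(self) -> None:
        if self.kind not in ROI_KINDS:
            raise InvalidParameterError(f"unknown ROI kind {self.kind!r}")
        if self.is_linear:
            if self.p0 is None or self.p1 is None or not self.width:
                raise InvalidParameterError(
                    "linear ROI needs p0, p1 and width")
            if self.length_px <= 0:
                raise InvalidParameterError("linear ROI length must be > 0")
        else:
            if self.polygon is None:
                raise InvalidParameterError("patch ROI needs a polygon")
            self.polygon = np.asarray(self.polygon, float)
            if self.polygon.shape[0] < 3:
                raise InvalidParameterError("polygon needs >= 3 vertices")

    @property
    def is_linear(self) -> bool:
        return self.kind in ("tube_segment", "tmv_rod")

    @property
    def length_px(self) -> float:
        dx = self.p1[0] - self.p0[0]
        dy = self.p1[1] - self.p0[1]
        return float(np.hypot(dx, dy))

    # -- masks -------------------------------------------------------------
    def _axis_coords(self, shape):
        """Along-axis (t) and perpendicular (u) coordinates of every pixel."""
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        ex = (self.p1[0] - self.p0[0]) / self.length_px
        ey = (self.p1[1] - self.p0[1]) / self.length_px
        rx = xx - self.p0[0]
        ry = yy - self.p0[1]
        t = rx * ex + ry * ey
        u = -rx * ey + ry * ex
        return t, u

    def mask(self, shape) -> np.ndarray:
        """Boolean foreground mask of the ROI on an image of ``shape``."""
        if self.is_linear:
            t, u = self._axis_coords(shape)
            return (t >= 0) & (t <= self.length_px) & (np.abs(u) <= self.width / 2)
        return polygon2mask(shape, self.polygon[:, ::-1])   # (row, col)

    def background_mask(self, shape) -> np.ndarray:
        """Band of pixels surrounding the ROI used for local background."""
        bw = self.background_band_width
        if self.is_linear:
            t, u = self._axis_coords(shape)
            outer = ((t >= -bw) & (t <= self.length_px + bw)
                     & (np.abs(u) <= self.width / 2 + bw))
            return outer & ~self.mask(shape)
        m = self.mask(shape)
        dilated = ndimage.binary_dilation(m, iterations=int(round(bw)))
        return dilated & ~m

    def check_inside(self, shape) -> None:
        if self.is_linear:
            xs = [self.p0[0], self.p1[0]]
            ys = [self.p0[1], self.p1[1]]
        else:
            xs = self.polygon[:, 0]
            ys = self.polygon[:, 1]
        if (min(xs) < 0 or min(ys) < 0
                or max(xs) > shape[1] - 1 or max(ys) > shape[0] - 1):
            raise InvalidParameterError("ROI extends outside the image")


@dataclass(frozen=True)
class MassCalibration:
    """Conversion from detector units to mass, anchored on the TMV rods."""

    k_cal_da_per_unit: float
    n_standards: int
    sd_k: float = 0.0
    tmv_reference_mpl_mda_nm: float = TMV_MPL_MDA_PER_NM

    def __post_init__(self) -> None:
        if self.k_cal_da_per_unit <= 0:
            raise CalibrationError("calibration factor must be > 0")


@dataclass(frozen=True)
class NetSignal:
    """Background-subtracted integrated signal of one ROI."""

    net_counts: float            # detector units above local background
    per_unit: float              # units/nm (linear) or units/nm^2 (patch)
    normalization: str           # "per_nm" | "per_nm2"
    extent_nm: float             # ROI length in nm, or area in nm^2
    valid: bool                  # False for negative net signal


@dataclass
class MassHistogram:
    """Population of mass-density values with an optional Gaussian fit."""

    values: np.ndarray
    unit: str                    # "MDa/nm" | "kDa/nm^2"
    bin_edges: np.ndarray | None = None
    gauss_mu: float | None = None
    gauss_sigma: float | None = None
    fit_r2: float | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def net_signal(image: DarkFieldImage, roi: SegmentROI,
               other_rois: tuple[SegmentROI, ...] = ()) -> NetSignal:
    """Integrated ROI signal above the local background.

    The background is the median per-pixel intensity of a band surrounding
    the ROI; pixels of the band that overlap other annotated ROIs are
    excluded (with a warning). Linear ROIs are normalized per nm of axis
    length, patches per nm^2 of area.
    """
    roi.check_inside(image.intensity.shape)
    shape = image.intensity.shape
    fg = roi.mask(shape)
    band = roi.background_mask(shape)
    for other in other_rois:
        if other is roi:
            continue
        overlap = band & other.mask(shape)
        if overlap.any():
            warnings.warn(
                "background band overlaps another ROI; overlapping pixels "
                "excluded", stacklevel=2)
            band &= ~overlap
    if not band.any():
        raise InvalidParameterError("background band is empty")

    bg_per_px = float(np.median(image.intensity[band]))
    net = float(image.intensity[fg].sum() - bg_per_px * fg.sum())

    if roi.is_linear:
        extent = roi.length_px * image.pixel_size
        norm = "per_nm"
    else:
        extent = fg.sum() * image.pixel_size**2
        norm = "per_nm2"
    return NetSignal(net_counts=net, per_unit=net / extent,
                     normalization=norm, extent_nm=extent,
                     valid=net >= 0)


def calibrate_with_tmv(image: DarkFieldImage,
                       tmv_rois: list[SegmentROI],
                       all_rois: tuple[SegmentROI, ...] = ()) -> MassCalibration:
    """Da-per-detector-unit factor from the co-deposited TMV rods."""
    rods = [r for r in tmv_rois if r.kind == "tmv_rod"]
    if not rods:
        raise CalibrationError("need at least one TMV rod ROI")
    per_nm = np.array([net_signal(image, r, all_rois).per_unit for r in rods])
    if np.any(per_nm <= 0):
        raise CalibrationError("non-positive TMV signal; calibration failed")
    mean_sig = float(per_nm.mean())
    k = TMV_MPL_MDA_PER_NM * 1e6 / mean_sig            # Da per detector unit
    if len(per_nm) > 1:
        sd_k = k * float(np.std(per_nm, ddof=1)) / mean_sig
    else:
        sd_k = 0.0
    return MassCalibration(k_cal_da_per_unit=k, n_standards=len(per_nm),
                           sd_k=sd_k)


def _measure(image, rois, cal, kinds, scale, unit, n_bins, all_rois):
    values = []
    for roi in rois:
        if roi.kind not in kinds:
            raise InvalidParameterError(
                f"expected ROI kinds {kinds}, got {roi.kind!r}")
        sig = net_signal(image, roi, all_rois)
        if not sig.valid:
            warnings.warn("negative net signal; measurement flagged invalid",
                          stacklevel=3)
        values.append(sig.per_unit * cal.k_cal_da_per_unit * scale)
    values = np.asarray(values)
    hist = MassHistogram(values=values, unit=unit)
    if len(values) >= 3 and np.ptp(values) > 0:
        edges = (np.histogram_bin_edges(values, bins=n_bins)
                 if n_bins else np.histogram_bin_edges(values, bins="fd"))
        hist.bin_edges = edges
        try:
            mu, sigma, r2 = fit_gaussian_histogram(values, edges)
            hist.gauss_mu, hist.gauss_sigma, hist.fit_r2 = mu, sigma, r2
        except (RuntimeError, ValueError):
            pass    # population too small/irregular for a stable fit
    return hist


def mass_per_length(image: DarkFieldImage, segment_rois: list[SegmentROI],
                    cal: MassCalibration, n_bins: int | None = None,
                    all_rois: tuple[SegmentROI, ...] = ()) -> MassHistogram:
    """Calibrated mass per unit length (MDa/nm) of straight tube segments
    or rods, as a population histogram with Gaussian fit."""
    return _measure(image, segment_rois, cal, ("tube_segment", "tmv_rod"),
                    1e-6, "MDa/nm", n_bins, all_rois)


def mass_per_area(image: DarkFieldImage, patch_rois: list[SegmentROI],
                  cal: MassCalibration, n_bins: int | None = None,
                  all_rois: tuple[SegmentROI, ...] = ()) -> MassHistogram:
    """Calibrated mass per unit area (kDa/nm^2) of flat membrane patches."""
    return _measure(image, patch_rois, cal, ("vesicle_patch",),
                    1e-3, "kDa/nm^2", n_bins, all_rois)


def fit_gaussian_histogram(values, bins=None) -> tuple[float, float, float]:
    """Least-squares Gaussian fit to the histogram of ``values``.

    Returns (mu, sigma, r^2) where r^2 is computed against the bin counts.
    Degenerate (all-identical) samples return sigma = 0 with no fit.
    """
    values = np.asarray(values, float)
    if len(np.unique(values)) < 3:
        # degenerate population: report sample moments, skip the fit
        return float(np.mean(values)), float(np.std(values)), float("nan")
    if bins is None:
        bins = np.histogram_bin_edges(values, bins="fd")
    elif np.isscalar(bins):
        bins = np.histogram_bin_edges(values, bins=int(bins))
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(centers) < 4:
        # too few bins to constrain a 3-parameter fit: report moments
        return (float(values.mean()), float(values.std(ddof=1)),
                float("nan"))

    def gauss(x, a, mu, sigma):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    p0 = (counts.max(), float(values.mean()), float(values.std(ddof=1)))
    popt, _ = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    a, mu, sigma = popt
    pred = gauss(centers, *popt)
    ss_res = float(np.sum((counts - pred) ** 2))
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(mu), abs(float(sigma)), r2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_darkfield_tiff(path, pixel_size: float) -> DarkFieldImage:
    """Load a 16-bit grayscale TIFF as a dark-field image."""
    return DarkFieldImage(intensity=tifffile.imread(path).astype(float),
                          pixel_size=pixel_size,
                          metadata={"source": str(path)})


def write_darkfield_tiff(image: DarkFieldImage, path) -> None:
    data = np.clip(image.intensity, 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, data.astype(np.uint16))


def save_rois_json(rois: list[SegmentROI], path) -> None:
    """ROI annotations as JSON (pixel units, 0-based, y-down)."""
    items = []
    for r in rois:
        d = {"kind": r.kind, "background_band_width": r.background_band_width}
        if r.is_linear:
            d.update(p0=list(r.p0), p1=list(r.p1), width=r.width)
        else:
            d["polygon"] = np.asarray(r.polygon).tolist()
        items.append(d)
    with open(path, "w") as fh:
        json.dump(items, fh, indent=2)


def load_rois_json(path) -> list[SegmentROI]:
    with open(path) as fh:
        items = json.load(fh)
    rois = []
    for d in items:
        if "polygon" in d:
            rois.append(SegmentROI(
                kind=d["kind"], polygon=np.asarray(d["polygon"], float),
                background_band_width=d.get("background_band_width", 5.0)))
        else:
            rois.append(SegmentROI(
                kind=d["kind"], p0=tuple(d["p0"]), p1=tuple(d["p1"]),
                width=d["width"],
                background_band_width=d.get("background_band_width", 5.0)))
    return rois


def write_mass_csv(hist: MassHistogram, path) -> None:
    pd.DataFrame({"mass": hist.values, "unit": hist.unit}).to_csv(
        path, index=False)


def write_fit_json(hist: MassHistogram, path) -> None:
    with open(path, "w") as fh:
        json.dump({"unit": hist.unit, "n": int(len(hist.values)),
                   "mean": hist.mean, "sd": hist.sd,
                   "gauss_mu": hist.gauss_mu, "gauss_sigma": hist.gauss_sigma,
                   "fit_r2": hist.fit_r2}, fh, indent=2)
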