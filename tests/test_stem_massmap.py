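import numpy as np
import pytest

from spiromass import (
    CalibrationError,
    DarkFieldImage,
    SegmentROI,
    calibrate_with_tmv,
    fit_gaussian_histogram,
    mass_per_area,
    mass_per_length,
    net_signal,
)
from spiromass.stem_massmap import (
    load_rois_json,
    read_darkfield_tiff,
    save_rois_json,
    write_darkfield_tiff,
)


def flat_image(value=10.0, size=64, pixel=1.0):
    return DarkFieldImage(np.full((size, size), float(value)), pixel)


def rod_image(signal_per_px=5.0, background=2.0, size=64, x0=10, x1=50,
              y=32, width=5):
    """A horizontal rod of uniform excess intensity on a flat background."""
    img = np.full((size, size), float(background))
    half = width // 2
    img[y - half:y + half + 1, x0:x1] += signal_per_px
    roi = SegmentROI(kind="tube_segment", p0=(x0, y), p1=(x1, y),
                     width=float(width))
    return DarkFieldImage(img, 1.0), roi


def test_net_signal_zero_on_uniform_image():
    img = flat_image()
    roi = SegmentROI(kind="tube_segment", p0=(10, 32), p1=(50, 32), width=5)
    assert net_signal(img, roi).net_counts == pytest.approx(0.0)


def test_net_signal_integrates_known_rod():
    img, roi = rod_image(signal_per_px=5.0, background=0.0)
    sig = net_signal(img, roi)
    # 5 painted rows x 40 columns x 5 units, per 40 nm of axis
    assert sig.net_counts == pytest.approx(5.0 * 5 * 40)
    assert sig.per_unit == pytest.approx(5.0 * 5 * 40 / 40.0)
    assert sig.normalization == "per_nm"


def test_net_signal_background_invariance():
    img0, roi = rod_image(background=0.0)
    imgb, _ = rod_image(background=7.0)
    assert net_signal(img0, roi).net_counts == pytest.approx(
        net_signal(imgb, roi).net_counts)


def test_net_signal_excludes_overlapping_rois():
    img, roi = rod_image()
    neighbor = SegmentROI(kind="tube_segment", p0=(10, 38), p1=(50, 38),
                          width=5)
    with pytest.warns(UserWarning):
        sig = net_signal(img, roi, (neighbor,))
    assert sig.net_counts == pytest.approx(5.0 * 5 * 40)


def test_negative_net_signal_flagged_invalid():
    img = np.full((64, 64), 10.0)
    img[30:35, 10:50] = 1.0    # darker than background
    dark = DarkFieldImage(img, 1.0)
    roi = SegmentROI(kind="tube_segment", p0=(10, 32), p1=(50, 32), width=5)
    assert not net_signal(dark, roi).valid


def test_tmv_calibration_from_known_signal():
    # rod with 1000 units/nm of net signal -> 0.131 MDa per 1000 units
    img, roi = rod_image(signal_per_px=200.0, background=3.0)
    roi = SegmentROI(kind="tmv_rod", p0=roi.p0, p1=roi.p1, width=roi.width)
    cal = calibrate_with_tmv(img, [roi])
    per_nm = 200.0 * 5        # 5 painted rows
    assert cal.k_cal_da_per_unit == pytest.approx(0.131e6 / per_nm)
    assert cal.sd_k == 0.0
    assert cal.n_standards == 1


def test_tmv_calibration_identical_rods_zero_scatter():
    img = np.zeros((64, 64))
    rois = []
    for y in (16, 48):
        img[y - 2:y + 3, 10:50] = 100.0
        rois.append(SegmentROI(kind="tmv_rod", p0=(10, y), p1=(50, y),
                               width=5))
    cal = calibrate_with_tmv(DarkFieldImage(img, 1.0), rois)
    assert cal.n_standards == 2
    assert cal.sd_k == pytest.approx(0.0, abs=1e-12)


def test_tmv_calibration_fails_on_empty_rod():
    img = flat_image(5.0)
    roi = SegmentROI(kind="tmv_rod", p0=(10, 32), p1=(50, 32), width=5)
    with pytest.raises(CalibrationError):
        calibrate_with_tmv(img, [roi])


def test_gain_invariance_of_calibrated_masses():
    """Scaling the whole image leaves calibrated masses unchanged exactly:
    the internal standard cancels the detector gain."""
    img = np.zeros((96, 96))
    img[14:19, 10:80] = 100.0          # TMV rod
    img[46:51, 10:80] = 250.0          # cell segment
    tmv = SegmentROI(kind="tmv_rod", p0=(10, 16), p1=(80, 16), width=5)
    seg = SegmentROI(kind="tube_segment", p0=(10, 48), p1=(80, 48), width=5)
    masses = []
    for gain in (1.0, 2.0, 13.7):
        image = DarkFieldImage(gain * img, 1.0)
        cal = calibrate_with_tmv(image, [tmv])
        masses.append(mass_per_length(image, [seg], cal).values[0])
    assert masses[0] == pytest.approx(masses[1], rel=1e-12)
    assert masses[0] == pytest.approx(masses[2], rel=1e-12)


def test_patch_additivity():
    """Integrated mass of a patch equals the sum over a partition of it."""
    img = np.zeros((96, 96))
    img[30:60, 20:80] = 40.0
    image = DarkFieldImage(img, 1.0)

    def patch(x0, x1):
        poly = np.array([[x0, 30], [x1, 30], [x1, 59], [x0, 59]], float)
        return SegmentROI(kind="vesicle_patch", polygon=poly)

    whole = net_signal(image, patch(20, 79))
    left = net_signal(image, patch(20, 49))
    right = net_signal(image, patch(49, 79))
    # integrated (not per-area) masses add; shared-edge pixels counted once
    assert left.net_counts + right.net_counts == pytest.approx(
        whole.net_counts + 40.0 * 30, rel=1e-9)


def test_zero_mass_patch_measures_zero():
    image = flat_image(6.0, size=96)
    poly = np.array([[20, 30], [70, 30], [70, 60], [20, 60]], float)
    roi = SegmentROI(kind="vesicle_patch", polygon=poly)
    img2 = DarkFieldImage(image.intensity, 1.0)
    rod = SegmentROI(kind="tmv_rod", p0=(10, 80), p1=(60, 80), width=5)
    img2.intensity[78:83, 10:60] += 50.0
    cal = calibrate_with_tmv(img2, [rod])
    hist = mass_per_area(img2, [roi], cal)
    assert hist.values[0] == pytest.approx(0.0, abs=1e-9)


def test_gaussian_histogram_fit_recovers_moments():
    rng = np.random.default_rng(42)
    values = rng.normal(189.0, 70.0, 10_000)
    mu, sigma, r2 = fit_gaussian_histogram(values)
    assert mu == pytest.approx(189.0, rel=0.05)
    assert sigma == pytest.approx(70.0, rel=0.05)
    assert r2 > 0.95


def test_gaussian_histogram_degenerate_cases():
    mu, sigma, r2 = fit_gaussian_histogram([5.0, 5.0, 5.0])
    assert mu == 5.0 and sigma == 0.0 and np.isnan(r2)
    mu, _, _ = fit_gaussian_histogram([2.0, 8.0])
    assert mu == pytest.approx(5.0)


def test_tiff_and_roi_json_roundtrip(tmp_path):
    img = flat_image(123.0, size=32)
    write_darkfield_tiff(img, tmp_path / "img.tif")
    back = read_darkfield_tiff(tmp_path / "img.tif", pixel_size=1.0)
    assert np.allclose(back.intensity, img.intensity)

    rois = [
        SegmentROI(kind="tmv_rod", p0=(1.0, 2.0), p1=(20.0, 2.0), width=4.0),
        SegmentROI(kind="vesicle_patch",
                   polygon=np.array([[0, 0], [10, 0], [10, 10]], float)),
    ]
    save_rois_json(rois, tmp_path / "rois.json")
    loaded = load_rois_json(tmp_path / "rois.json")
    assert loaded[0].kind == "tmv_rod" and loaded[0].p0 == (1.0, 2.0)
    assert np.allclose(loaded[1].polygon, rois[1].polygon)
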