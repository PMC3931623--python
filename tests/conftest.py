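import pytest

from spiromass import GeneratorConfig, HelicalCellParams, cell_geometry


@pytest.fixture(scope="session")
def reference_helix() -> HelicalCellParams:
    """Measured helix parameters of the average cell."""
    return HelicalCellParams(
        pitch_P=889.0, coil_centerline_diameter_Dcoil=382.0,
        tube_diameter_d=188.0, n_turns=4.0,
        sd_P=118.0, sd_Dcoil=69.0, sd_d=19.0, sd_n=0.4)


@pytest.fixture(scope="session")
def reference_geometry(reference_helix):
    return cell_geometry(reference_helix)


@pytest.fixture
def imaging_config() -> GeneratorConfig:
    """Small field of view for fast image-based tests (4 nm pixels)."""
    return GeneratorConfig(seed=0, image_size_px=384, pixel_size_nm=4.0)
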