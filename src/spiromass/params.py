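"""Reference measurement set for Spiroplasma melliferum BC3.

These are the measured population means and SDs of the study this package
models: the helix geometry of an average cell, the STEM mass densities,
the hydrodynamic coefficients, the stereological ribosome counts and the
bulk-chemistry composition table. They serve three purposes: default
arguments for the analysis chain, ground truth for the synthetic-data
generators, and the worked example of the README.
"""

from __future__ import annotations

import pandas as pd

# ------------------------------------------------------- helix geometry (nm)
HELIX_PITCH_NM = (889.0, 118.0)            # (mean, SD)
HELIX_COIL_DIAMETER_NM = (382.0, 69.0)     # centerline coil diameter D
HELIX_TUBE_DIAMETER_NM = (188.0, 19.0)     # tube diameter d
HELIX_N_TURNS = (4.0, 0.4)

# ------------------------------------------------------ STEM mass densities
CELL_MASS_PER_LENGTH_MDA_NM = (3.74, 0.68)      # whole-cell m_cell
MEMBRANE_MASS_PER_AREA_KDA_NM2 = (4.67, 0.70)   # collapsed vesicles, mu_memb
RIBBON_MASS_PER_LENGTH_KDA_NM = (189.0, 70.0)   # cytoskeletal ribbon m_R
RIBBON_LENGTH_PER_CELL_NM = 4368.0              # per-cell averaged L_R

# ------------------------------------------------------------ hydrodynamics
SEDIMENTATION_S = 9930.0            # Svedberg, viscosity-corrected peak
DIFFUSION_CM2_S = 6.1e-9            # DLS average translational D_t
TEMPERATURE_K = 293.0
BUFFER_DENSITY_G_CM3 = 1.00741
DLS_VISCOSITY_MPAS = 1.0183         # DLS solvent viscosity
AUC_VISCOSITY_MPAS = 1.157          # sedimentation solvent viscosity
ROTOR_RPM = 3000.0
DLS_ANGLE_DEG = 90.0
DLS_WAVELENGTH_NM = 633.0
REFRACTIVE_INDEX = 1.331            # PBS at 633 nm

# --------------------------------------------------------------- stereology
RIBOSOMES_PER_AREA_UM2 = (962.0, 102.0)
SECTION_THICKNESS_MEASURED_NM = 45.0   # post-irradiation, from folds
SECTION_SHRINKAGE_FACTOR = 2.0         # beam-induced thickness shrinkage

# -------------------------------------------- STEM imaging / generator dose
ELECTRON_DOSE_PER_NM2 = 1e3
IMAGE_PIXEL_NM = 1.0
IMAGE_SIZE_PX = 1024

# ------------------------------------------- bulk chemistry (per 1,022 ug)
TOTAL_DRY_MASS_UG = 1022.0
EXPRESSED_PROTEIN_SPOTS = 600      # reported 2D-gel spot count (not computed)
LITERATURE_GENOME_BP = 1.46e6      # pulsed-field estimate, reference only

_COMPOSITION_ROWS = [
    # analyte, class, is_subtype, weight_ug, sd_ug
    ("total_protein", "protein", False, 728.94, 2.11),
    ("lipoprotein", "protein", True, 285.35, 6.31),
    ("glycoprotein", "protein", True, 216.50, 3.99),
    ("total_lipid", "lipid", False, 80.46, 0.65),
    ("fatty_acid", "lipid", True, 16.92, 0.82),
    ("phospholipid", "lipid", True, 3.66, 0.37),
    ("cholesterol", "lipid", True, 22.84, 1.01),
    ("glycolipids", "lipid", True, 7.31, 0.26),
    ("total_carbohydrate", "carbohydrate", False, 82.61, 0.49),
    ("free_carbohydrate", "carbohydrate", True, 12.98, 0.99),
    ("total_DNA", "DNA", False, 41.06, 0.06),
    ("total_RNA", "RNA", False, 88.21, 0.85),
]


def composition_table() -> pd.DataFrame:
    """Measured bulk-chemistry table (weights in ug within 1,022 ug dry mass)."""
    return pd.DataFrame(
        _COMPOSITION_ROWS,
        columns=["analyte", "class", "is_subtype", "weight_ug", "sd_ug"],
    )


def dry_mass_fractions() -> dict[str, float]:
    """Class totals as fractions of the total dry mass."""
    df = composition_table()
    classes = df[~df.is_subtype].set_index("class").weight_ug
    return (classes / TOTAL_DRY_MASS_UG).to_dict()
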