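"""Physical constants and unit conversions used throughout the package.

All lengths are carried in nm internally; masses in Da (with MDa/kDa/GDa at
reporting boundaries); hydrodynamic quantities in CGS units (cm, g, s, erg),
the customary system for analytical ultracentrifugation.
"""

# ---------------------------------------------------------------- constants
K_B_ERG_PER_K = 1.380649e-16     # Boltzmann constant, erg/K
N_AVOGADRO = 6.02214076e23       # 1/mol; also Da per gram
SVEDBERG_S = 1e-13               # 1 Svedberg in seconds

# ------------------------------------------------------------- conversions
G_PER_DA = 1.0 / N_AVOGADRO
CM3_PER_NM3 = 1e-21
# 1 Da/nm^3 expressed in g/cm^3
G_PER_CM3_PER_DA_PER_NM3 = G_PER_DA / CM3_PER_NM3   # ~1.6605e-3
NM_PER_CM = 1e7
POISE_PER_MPAS = 1e-2            # 1 mPa*s = 0.01 g/(cm*s)

# --------------------------------------------- internal mass standard (TMV)
# Tobacco mosaic virus: rigid 18 nm x 300 nm rods of known total mass,
# co-deposited with the specimen to convert dark-field signal to mass.
TMV_MASS_MDA = 39.3
TMV_LENGTH_NM = 300.0
TMV_DIAMETER_NM = 18.0
TMV_MPL_MDA_PER_NM = 0.131       # 39.3 MDa / 300 nm

# ------------------------------------------------------ molecular constants
DA_PER_BP_DNA = 660.0            # average mass of one DNA base pair
DA_PER_NT_RNA = 330.0            # average mass of one RNA nucleotide
RIBOSOME_MASS_MDA = 2.7          # prokaryotic 70S ribosome
RIBOSOME_DIAMETER_NM = 20.0
RIBOSOME_RNA_MASS_FRACTION = 0.5  # roughly half of ribosomal mass is rRNA

# ------------------------------------------------- cytoskeletal (Fib) ribbon
FIB_MONOMER_KDA = 59.0           # dominant cytoskeletal protein monomer
FIBRILS_PER_RIBBON = 7
FIB_PER_TETRAMER = 4
TETRAMER_REPEAT_NM = 9.0         # axial repeat per tetramer along a fibril
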