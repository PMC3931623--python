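# Methods

This note documents the models, parameter defaults, numerical choices and
limitations behind each stage of the pipeline. It is written for a reader
who wants to know *why* the code computes what it computes.

## 1. Helical cell geometry

The cell is an open tube (no end-caps) of diameter *d* whose centerline is
a helix of pitch *P*, coil centerline diameter *D* and *n* turns. All
derived quantities follow analytically from one helical repeat:
L_C = √((πD)² + P²), V_C = π(d/2)²·L_C, S_C = πd·L_C, and the inner
(shortest) helical line l_R = √((π(D−d))² + P²), the track of the
cytoskeletal ribbon. The axial ratio is nP/(D+d), the length of the coiled
cell over its outer envelope diameter — this is the form consistent with
the measured values (3,556/570 = 6.24).

Default parameters (population means ± SD): P = 889 ± 118 nm,
D = 382 ± 69 nm, d = 188 ± 19 nm, n = 4 ± 0.4. Whole-cell values are
computed from the mean parameters rather than averaged per cell (individual
cell data are not available), which shifts nonlinear quantities slightly —
e.g. L_C on mean parameters is 1,493.5 nm versus a per-cell average of
1,490 nm, and l_R is 1,078 vs 1,092 nm. Tests and tolerances allow 2% for
this. For the ribbon budget the per-cell averaged L_R = 4,368 nm is kept as
the default, since the ribbon mass M_R is defined against it.

Uncertainties propagate to first order. Products and ratios use the
relative-quadrature rule sd(XY) = |XY|·√((sd_X/X)² + (sd_Y/Y)²) (with an
absolute-form fallback at zero means); the helix arc lengths use their
analytic partial derivatives. Inputs are treated as independent.

Membrane thickness is estimated by differential staining: membrane-stained
cross-sections project a larger diameter than cytoplasm-delimited ones, and
t_memb = Δd/2. With the measured diameters (503–511 px stained, 403 px
unstained, 0.39 nm/px) this gives ≈ 20 nm.

## 2. Dark-field mass mapping

The annular dark-field signal is modelled as linear in projected dry mass.
The Z^3/2 dependence of scattering on composition is not modelled: the
elemental ratios of cellular components vary little, bounding the error at
a few percent, and it is absorbed into the measurement scatter. A ROI's net
signal is its integrated intensity minus (median per-pixel intensity of a
surrounding band) × (ROI pixel count). The median band (default width
5 px) is robust against nearby bright objects; its estimator makes net
signals exactly invariant to constant background offsets, and the
internal-standard calibration makes calibrated masses exactly invariant to
detector gain. Background-band pixels overlapping other annotated ROIs are
excluded with a warning; negative net signals are flagged invalid.

Calibration divides the accepted TMV mass-per-length (39.3 MDa/300 nm =
0.131 MDa/nm) by the mean net per-length signal of the co-deposited rods;
between-rod scatter gives the calibration SD. Straight tube segments yield
MDa/nm, flat collapsed-vesicle patches kDa/nm². The measured 4.67 kDa/nm²
is treated as the per-cell-surface value (the downstream membrane fraction
of ~75% is only consistent with that reading). Population histograms get a
least-squares Gaussian fit with Freedman–Diaconis binning by default
(reference bin widths are unstated); degenerate or under-binned samples
fall back to sample moments with the fit skipped.

## 3. Hydrodynamics and hydration

Whole cells sediment at ~10⁴ S while diffusing negligibly over the
experiment, so boundaries are modelled as Lamm solutions for non-diffusing
species: a step at r_b(t) = r_m·exp(sω²t) with plateau c₀·exp(−2sω²t)
(radial dilution in a sector cell). The ls-g*(s) fit solves a non-negative
least-squares superposition of such boundaries over a log-spaced s-grid
(default 100 points, 500–30,000 S), optionally with unconstrained
time-invariant radial offsets and radius-invariant per-scan offsets — a
simplified two-term version of full systematic-noise decomposition — and
optional Tikhonov regularization (default 0; raised automatically with a
logged note if the design is rank-deficient). Full diffusion-broadened Lamm
solutions and concentration-dependent non-ideality are out of scope.

A conservation subtlety: the solution-column integral ∫c·r dr is *not*
constant under this model, because the plateau dilutes while material
pellets at the base from t = 0 at rate c_p·sω²·b². The conserved quantity,
verified in tests to 0.1%, is the column integral plus the accumulated
pellet mass c₀b²(1−e^(−2sω²t))/2, valid until the boundary itself reaches
the base.

DLS traces are fitted as g₂−1 = A·exp(−2Dq²τ) with q = 4πn·sin(θ/2)/λ
(defaults: 90°, 633 nm, refractive index 1.331 for PBS). The fit is
parametrized on the decay rate Γ = 2Dq² (order 10² s⁻¹) rather than D
(~10⁻⁹) for numerical conditioning. The solvent viscosities are taken as
1.0183 mPa·s (DLS) and 1.157 mPa·s (sedimentation) — centipoise-scale
values for a water-like buffer; Stokes–Einstein with 1.0183 mPa·s maps
D = 6.1×10⁻⁹ cm²/s onto a ~691 nm sphere, matching the reported ~700 nm.

The Svedberg equation m_b = s·k_B·T/D (identical frictional coefficients
for sedimentation and diffusion; cells starved and non-motile) gives the
buoyant mass; with the independently known cell volume, hydrated mass =
m_b + V_cell·ρ_buffer (ρ_buffer = 1.00741 g/cm³), the dry fraction is the
STEM dry mass over the hydrated mass, and the dry density divides dry mass
by the volume not occupied by water, taking intracellular water at buffer
density. Constants: k_B = 1.380649×10⁻¹⁶ erg/K, N_A = 6.02214076×10²³,
1 S = 10⁻¹³ s; CGS units throughout this stage.

## 4. Stereology

Section thickness measured from folds (45 nm) is doubled to the
pre-irradiation value (90 nm): beam damage shrinks Spurr's-resin sections
by a factor ≈ 2 perpendicular to the section plane only. The Holmes
correction uses the effective thickness (T_corrected + d): a sphere is
counted whenever it intersects the slab, so ν = n_A/(T + d) with
d_ribosome = 20 nm. Partial-profile visibility thresholds (lost caps) are
not modelled. Defaults: m_ribosome = 2.7 MDa, rRNA = half the ribosomal
mass, 330 Da per RNA nucleotide. The chemical cross-check converts the
bulk RNA fraction into ribosome equivalents with the same constants; the
structural (≈1,444) and chemical (≈1,414) counts agree within 2%.

## 5. Composition and genome size

The analyte table partitions 1,022 µg of dry cell mass into protein, lipid,
carbohydrate, DNA and RNA classes with conjugate subtypes. Unconjugated
protein and free lipid are derived by subtracting subtypes from class
totals; recomputed values (227.09, 29.73 µg) differ from the printed ones
(226.91, 29.72 µg) by <0.1% — the printed values evidently derive from
unrounded inputs — and a 0.1% tolerance accepts both. Percentages use the
stated 1,022 µg total as denominator (the class-sum alternative differs
by <0.1%). Genome size is M_cell·f_DNA/660 Da·bp⁻¹ ≈ 1.35 Mbp; ongoing
replication can inflate DNA per cell by up to 50%, so an optional
correction factor in [1, 1.5] reports a lower bound (~0.90 Mbp). The
literature genome size (1.46 Mbp) is carried as a reference constant only.

## 6. Inventory and closure

Component masses are measured independently: membrane (µ_memb·S_cell),
cytoskeleton (m_R·L_R), ribosomes (stereology), DNA (chemistry). Their
fractions of M_cell need not sum to 1; the closure residual is reported,
not forced to zero, and is ≈ 1% on the default inputs (membrane 0.74,
ribosomes 0.175, cytoskeleton 0.037, DNA 0.040). The reference table's
printed membrane mass of 1.66 GDa is inconsistent with its own inputs
(4.67 kDa/nm² × 3.54×10⁶ nm² = 16.5 GDa) and with the ~75% membrane
fraction; the package computes from the inputs and treats the printed cell
as a decimal typo. Similarly the reported 19% ribosome fraction is not
reproducible from the reported N and m_ribosome (which give 17.5%); the
recomputed value is reported. Fib copy numbers come from two routes —
M_R/59 kDa and 7 fibrils × 4 per tetramer × L_R/9 nm — which agree within
3% and serve as mutual validation.

## 7. Synthetic data: what it does and does not emulate

Generators draw population parameters as truncated normals (the measured
histograms are well fit by Gaussians). The dark-field generator renders
straight tube segments, TMV rods and flat patches with mass spread
uniformly over each ROI footprint and per-pixel Poisson counts at the
nominal dose of 10³ electrons/nm² (default 1024×1024 px at 1 nm/px, the
probe size); detector MTF, Z-contrast and beam-induced mass loss are not
simulated, and no coil-crossing geometry is rendered (only straight
segments are measured in practice). The sedimentation generator superposes
non-diffusing boundaries (default monodisperse 9,930 S; satellite species
configurable) with Gaussian fringe noise — no diffusional broadening. The
stereology generator places Poisson sphere centers in a box and counts
slab intersections, which realizes the (T+d) expectation exactly. The
composition generator draws weights around the measured table with the
stated replicate SDs.

Passing recovery tests therefore demonstrates estimator correctness under
the assumed statistical model — linear mass contrast, ideal non-diffusing
boundaries, single-exponential DLS decay, fully visible spheres — not
robustness to real-instrument systematics (drift, non-uniform films,
stain variability, beam damage).

## 8. Problem sizes and numerical choices

Tests run the ls-g*(s) round trip on 8 scans × 120 radii with an 80-point
grid (50 random species), image recovery on 448 px fields at 4 nm/px over
100 seeds (3 segments each, 3-SE criterion with the population SE), and the
stereology oracle on 6 sections × 10 µm² over 100 seeds — sizes chosen so
the whole suite completes in well under a minute while keeping counting
statistics meaningful. Exact invariants (gain/background invariance,
additivity, unit-change invariance, Svedberg consistency) are asserted at
1e-9 to 1e-12 relative; statistical recoveries at 3 standard errors with a
≥95% pass rate over seeds. Degenerate inputs (zero signal, flat DLS traces,
over-packed cells, subtype sums exceeding class totals) raise typed errors
rather than returning silently wrong numbers.
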