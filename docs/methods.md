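# Methods

## Model

The package solves steady-state CO₂ transport over an explicit 2-D leaf
cross-section coupled to FvCB photosynthesis kinetics.  One vein-to-vein
segment is modelled with impermeable lateral boundaries; ambient CO₂ is a
Dirichlet condition on the outer edges of both epidermes (wheat is
amphistomatous; a single-surface flag exists).  Within each phase CO₂
obeys Fickian diffusion with the phase diffusivity; at every gas–liquid
interface the two concentrations are in Henry equilibrium
(C_liq = H·C_gas, H = 0.83 at 25 °C); every membrane (plasmalemma,
tonoplast, chloroplast envelope) is a flux resistance φ = P_m ΔC_liq,
the envelope at half permeability because it is a double membrane.  An
HCO₃⁻ field diffuses inside each aqueous compartment, crosses neither
membranes nor gas interfaces, and exchanges with CO₂ through the
uncatalysed hydration/dehydration pair (no carbonic anhydrase); at the
default pH 7 its equilibrium pool is ≈ 4.2× the dissolved CO₂.

Photosynthesis acts as a volumetric sink A_G/(d·f_c) in the chloroplast
layer, where d is the leaf thickness and f_c the chloroplast areal
fraction measured on the mesh (so that the area integral reproduces the
leaf-area rate exactly).  A_G is the minimum of the Rubisco-, electron-
transport- and TPU-limited rates; below the compensation point the
(negative) Rubisco-limited value applies and is flagged.  Γ* scales
linearly with the O₂ level, anchored at the published 34 µbar at 21 % O₂;
day respiration uses the photorespiratory estimate at 21 % O₂ and the
non-photorespiratory one below 100 mbar.  Respiration is released in the
mesophyll cytosol by default (matching the volumetric normalisation
R_d/(d·f_m)); a `respiration="distributed"` switch spreads it over
epidermis, cytosol and phloem in proportion to area.  The two choices
differ measurably only near the light/CO₂ compensation regions, where the
cytosolic release inflates C̄ₘ; the cytosolic default reproduces the
characteristic decline of ḡₘ with ambient CO₂, which the distributed
variant flattens.

Electron transport J is an input per condition — measured directly, or
derived from fluorescence as J = s·I·Φ₂ — because intra-leaf light
propagation is out of scope (irradiance is assumed uniform).

## Discretisation and solver

Cell-centred finite volumes on a labelled structured raster (pixel pitch
h).  The solver's unknown is the gas-equivalent potential u (= C_gas in
gas phases, C_liq/H in aqueous ones): u is continuous across Henry
interfaces, so the diffusion operator keeps divergence form with
conductivity D (gas) or H·D (aqueous), and face conductances are harmonic
means; membrane faces add a series resistance 1/(P_m·H) (counted once per
physically crossed membrane — a face lookup table covers the degenerate
pairs a raster can produce).  This construction is conservative by
design: at convergence the boundary influx equals the volume-integrated
reactions to linear-solver precision, which the resistance analysis and
mass-balance tests rely on.

The FvCB nonlinearity is handled by Picard iteration with limb selection:
at each outer step the active limb and its denominator are frozen at the
current iterate, making the sink affine in u, and the fully linear system
(including the implicit CO₂–HCO₃⁻ coupling — no splitting error) is
solved sparsely.  The sparse LU factorisation from the first iteration is
reused as a GMRES preconditioner in later iterations, since only the
chloroplast diagonal changes; the solver refactorises on demand.  Damping
is adaptive: the update is relaxed after a residual increase and driven
back toward 1 while the residual falls (a fixed 0.5 damping reaches the
same fixed point but costs ~20 extra iterations).  Convergence requires a
relative update below 10⁻⁶ *and* a stable limb assignment; afterwards the
active limb equals the minimising limb in ≥ 99 % of chloroplast elements
or the field is flagged.  Non-convergence and negative concentrations
raise errors carrying the residual history.

Default resolution is h = 0.5 µm — one cell across the 0.5 µm wall, the
coarsest pitch at which the nested wall/chloroplast/vacuole rings are
provably closed under pixel-centre sampling; halving h changes whole-leaf
assimilation by < 1 %.  Whole-leaf assimilation is the Dirichlet-face
flux sum per projected leaf width; C̄ᵢ averages the pore, C̄ₘ the aqueous
mesophyll-cell phases excluding the wall (gas-equivalent), and
ḡₘ = Ā_N/(C̄ᵢ−C̄ₘ).  The serial resistance analysis defines compartment
drops as differences of successive boundary-layer averages (elements
adjacent to the relevant interface; membrane drops from the jump across
membrane faces), so the seven drops telescope exactly to the
ambient-to-stroma difference and the percentage shares sum to 100 by
construction — the substantive checks are the telescoping identity,
positivity, and the 1-D layered-leaf oracle.

## Synthetic microstructure

The generator emulates a compact wheat mesophyll.  Lloyd-relaxed Voronoi
cells fill the band between two 20 µm epidermis strips (the thickness is
not printed in the source anatomy; 20 µm per side leaves a mid-range pore
fraction ≈ 0.21).  Two pinned seeds guarantee a vascular bundle whose
xylem faces the adaxial epidermis.  Each cell–cell face is a sealed
contact with probability 0.65→0.85 (default 0.85) — compact tissue with
cells touching — or a 1 µm gas channel; the remaining porosity is carved
as circular lacunae at cell-junction vertices, the radius solved so the
total mesophyll-cell area equals f_c·W·d / (chloroplast share).  Inside
each cell: 0.5 µm wall (inward mitre offset), chloroplast layer 0.5 µm
inside the plasmalemma with thickness solved for a 20 % share of cell
area, and a vacuole whose share is derived from the cytosol-fraction
target f_m (≈ 0.40; the printed per-cell shares 20 % chloroplast + 60 %
vacuole are mutually inconsistent with f_c = 0.104 and f_m = 0.169 in one
section, and the generator prioritises the three quantities that are
checked: f_c, f_m and the chloroplast share).  The chloroplast ring is
closed, so CO₂ reaches the vacuole only through the envelope (twice) and
tonoplast.  Contact sealing and cell count (~Ø20 µm cells) were fixed so
the realised resistance profile matches the published wheat section —
intercellular-space share ≈ 25–30 % of the total — rather than the ~3 %
an every-contact-open tessellation gives.  Helox multiplies the
diffusivity of both gas-basis phases (pore *and* the epidermal effective
medium, which lumps the gas-filled stomata).

What the generator does **not** emulate: lobed cell outlines (surface
enlargement is set by cell size only), 3-D pore connectivity (a 2-D
section understates connectivity), chlorophyll depth gradients (the
capacity profile varies only through anatomy), and instrument artifacts.
Passing tests therefore show the machinery is correct and the emergent
trends are robust to tessellation seeds — not that any particular real
leaf is reproduced.

## Synthetic gas exchange and calibration

The dataset generator reproduces the measurement protocol structure:
CO₂ series 50…1500 µmol mol⁻¹ at I = 1000, irradiance series 0…2000 at
C_a = 350 (21 % O₂) or 1000 (2 % O₂), with records (Â_N, Ĉᵢ, Φ₂, ĝ_s)
made mutually consistent (Φ₂ back-computed so J = s·I·Φ₂ is exactly the J
used).  The lumped two-resistance mode intersects FvCB demand with
C_i = C_a − A/g_s, C_c = C_i − A/g_m (g_m = 0.40 mol m⁻² s⁻¹ by default),
so the variable-J estimators invert it exactly at electron-transport-
limited points — the estimator-consistency oracle.  Stomata follow
g_s(I) = 0.05 + 0.40·I/(I+300) mol m⁻² s⁻¹ and PSII efficiency
Φ₂(I) = 0.78/(1+I/1300) (at I = 1000 these give g_s ≈ 0.36 and
J ≈ 168 µmol e⁻ m⁻² s⁻¹, typical of wheat flag leaves).  Noise is
multiplicative Gaussian on Â_N and Ĉᵢ, seeded.

Calibration fits log₁₀(D_epi, D_w) by Nelder–Mead (positivity by
construction, each objective evaluation a full PDE solve warm-started
from the previous field) on the squared C̄ᵢ and C̄ₘ residuals at the
reference condition, then one D_epi per irradiance by bracketed root
finding at fixed D_w.  D_w is identifiable through the apoplastic
pathway (the wall network wraps and bridges all cells), shifting C̄ₘ by
≈ ±8 µmol mol⁻¹ per octave.  The variable-J Ĉ_c is biased low whenever
part of the chloroplast field is Rubisco-limited (≈ −13 µmol mol⁻¹ at
the mixed-limb reference condition — the same estimator limitation that
shows up as model–measurement discrepancies in the field), so recovery
tests target the model's own C̄ₘ via the `cc_hat` argument; the Harley
estimator itself is validated against the lumped generator where it is
exact.  Near the compensation point (|Â_N| < 0.5 µmol m⁻² s⁻¹) the
per-irradiance fit is flagged ill-conditioned since Ĉᵢ ≈ C_a carries no
information on D_epi.

## Problem sizes

The shipped configurations are sized for a single CPU: the default
section is 120 µm wide (≈ 34 mesophyll cells, 88 k elements at
h = 0.5 µm, a few seconds per steady solve); the test suite uses a 60 µm
section for response curves and calibration.  Larger domains and finer
meshes only change run time.

## Known limitations

Steady state only; 2-D; uniform irradiance; no carbonic anhydrase; no
temperature dependence of the FvCB parameters (25 °C throughout); the
epidermis lumps stomata, so no stomatal-patchiness effects; ḡₘ near the
CO₂/light compensation point is dominated by the respiration offset in
C̄ₘ and is reported but flagged unreliable below C_a = 100 µmol mol⁻¹.
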