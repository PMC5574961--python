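# Methods

## Mechanistic model of intercalating-dye uptake

A cell is modelled as two well-mixed compartments, cytosol and nucleus,
with volumes normalized to 1 (the true volume ratio is absorbed into the
exchange rate and the site densities). The state is

    C_cyt, B_cyt : free / bound dye in the cytosol   (µM)
    C_nuc, B_nuc : free / bound dye in the nucleus   (µM)
    Q            : cumulative photobleached bound dye (µM)

and evolves as

    dC_cyt/dt = P(t)·(C_ext − C_cyt) − r_cyt − k_cn·(C_cyt − C_nuc)
    dB_cyt/dt = r_cyt − k_pb·B_cyt
    dC_nuc/dt = k_cn·(C_cyt − C_nuc) − r_nuc
    dB_nuc/dt = r_nuc − k_pb·B_nuc
    dQ/dt     = k_pb·(B_cyt + B_nuc)

with bimolecular binding `r_x = k_on·C_x·(S_x − B_x) − k_off·B_x`. Membrane
influx is Fick-like, `P(t)·(C_ext − C_cyt)`: a sonoporation pore reseals
exponentially, `P(t) = P0·exp(−(t − onset)/τ_pore)` (τ_pore within the
seconds-to-a-minute window reported for pore resealing), while detergent
permeabilization leaves a constant `P_chem`. Photobleaching acts on bound
dye only, at `k_pb(DC) = k_dark + k_laser·DC` — a linear duty-cycle model
anchored exactly at the packaged pulsed (3.3 %) and continuous (100 %)
calibration rates (0.41 and 2.63 ×10⁻³ s⁻¹).

The observed intensity is

    I(t) = b_free·(C_cyt + C_nuc) + b_bound·(B_cyt + B_nuc) / (1 + C_ext/Q50)

with a divisive self-quenching factor on bound-dye brightness (`Q50` = 8 µM
for SYTOX Green, infinite for PI). Quenching rescales amplitudes only and
never the fitted rate constants; the 8 µM default is what makes the
simulated 20 µM chemically-permeabilized maximum fall below the 10 µM
maximum, the non-monotonicity attributed to self-quenching in well-plate
data.

Mass conservation — cumulative membrane influx equals total intracellular
dye (free + bound + bleached) — is tracked as an integrated state and held
to ≲10⁻⁸ relative by the integrator (LSODA, rtol 1e−10, atol 1e−13, output
on the acquisition grid, segments split at the permeabilization onset).
Negative excursions below 10⁻⁹ µM are integrator noise and are clipped;
anything larger raises an error.

## Condition presets and calibration

Apparent fluorescence rate constants `k_f` (from two-compartment fits)
follow packaged concentration-response lines:

* `usmb_fadu` : k_f = 0.2×10⁻³ s⁻¹ µM⁻¹ · C (zero intercept),
* `usmb_c6`   : 2.4 × the FaDu line,
* `chem_fadu` : k_f = 0.544×10⁻³ + 0.056×10⁻³·C s⁻¹ for C ≤ 10 µM, and a
  quench-regime line through k_f(20 µM) = 2.2×10⁻³ s⁻¹ above that. The
  intercept is forced by the two anchors k_f(1 µM) = 0.6×10⁻³ s⁻¹ and the
  printed slope.

Each preset is a full mechanistic parameterization whose simulated traces,
fitted with the 2CM, reproduce these lines to well under 5 %:

* **Chemical preset.** A high constant permeability (P_chem = 0.5 s⁻¹ —
  detergent-treated monolayers are effectively open) and fast
  cytosol–nucleus exchange (k_cn = 0.5 s⁻¹) clamp the free intracellular
  concentration at C_ext, so the bound pool relaxes mono-exponentially at
  exactly `k_on·C_ext + k_off`. The preset therefore uses
  k_on = 0.056×10⁻³ µM⁻¹ s⁻¹ and k_off = 0.544×10⁻³ s⁻¹ analytically; above
  10 µM the effective k_on is re-anchored so the fitted rate passes through
  2.2×10⁻³ s⁻¹ at 20 µM (self-quenching and site competition reduce the
  effective per-µM association at high concentration).
* **Sonoporation presets.** After the pore reseals (P0 = 0.6 s⁻¹,
  τ_pore = 5 s, so ~95 % of C_ext is internalized), the cell holds a fixed
  free-dye load A ≈ 0.95·C_ext. The presets run in the *dye-excess* regime:
  binding-site totals (S_nuc = 0.01, S_cyt = 2×10⁻⁵ µM-equivalent) are small
  against A, so the free pool is nearly constant and the bound pool rises
  mono-exponentially at a rate proportional to C_ext — the only way a
  mass-conserving, fully resealing model yields the observed linear,
  zero-intercept concentration response. The price is nominal site
  densities far below physiological nucleic-acid concentrations; they are
  effective parameters of a reduced-order observation model, not estimates
  of chromatin content. The single free scale, the effective k_on, is
  calibrated by a deterministic two-step fixed point (simulate the 2 µM
  trace, fit, rescale) against the target line; the C6 preset multiplies
  the calibrated rate by 2.4.

Condition-specific effective k_on values (0.27×10⁻³ µM⁻¹ s⁻¹ for
sonoporation vs 0.056×10⁻³ for chemical permeabilization) are deliberate:
the two experimental systems (live cells under FCFM vs detergent-extracted
monolayers in a plate reader) differ in chromatin accessibility,
temperature and readout, and their empirical concentration responses cannot
arise from one shared parameter set.

FCFM trace sampling starts 30 s after the ultrasound onset (61 frames would
otherwise place the first frame inside the exposure/transfer window); the
spectrofluorometer protocol reads every 2 min for 180 min from t = 0.

## Synthetic imaging

**Population mode (FCFM).** 593×593 µm field at 1.4 µm/px (424×424; the
pixel size is a preset choice, not a claim about the instrument), 61 frames.
Cells are random non-overlapping ellipses (axes 15–25 µm, concentric
nucleus at 40 % area, ≥2-px gaps so neighbours remain resolvable); the
probe does not resolve compartments, so each cell carries its whole-cell
mean intensity. Cell-to-cell kinetic variability is a median-one lognormal
multiplier on the binding rate (log-sd 0.5). Noise is multiplicative
Gaussian (σ = signal/SNR) plus additive read noise, clipped at zero. Focal
drift — in reality an axial effect — is surrogated by its observable
consequence at this resolution, a slowly accumulating integer-pixel lateral
translation; ground-truth masks and centers shift with the image.

**Single-cell mode (swept-field).** One cell on a 1 µm grid, 9 min at 1-s
frames. Free dye enters at a single boundary pore pixel at a rate scaled by
the resealing permeability, diffuses (D_cyt = 40 µm² s⁻¹, a small-molecule
cytosolic value), crosses a nuclear envelope modelled as edge-attenuated
diffusion (factor 5×10⁻⁴ — nuclear pore transport is slow relative to free
diffusion), and binds locally (k_on = 0.5 µM⁻¹ s⁻¹, sites 0.05 µM in the
cytosol vs 50 µM in the nucleus). These defaults produce the qualitative
single-cell pattern: pore-side asymmetry in the first seconds, a cytosolic
plateau (≥95 % of maximum by 30 s, from fast saturation of scarce cytosolic
sites plus the free-dye load), and monotone nuclear accumulation still
rising at 9 min, ending well above the cytosol. Integration is explicit
Euler in flux form (exactly mass-conserving on the closed mask) with
automatic sub-stepping below the diffusion CFL limit and the influx/binding
relaxation rates.

What the generator does *not* emulate: optical PSF and out-of-focus light,
microbubbles, 3-D geometry, cell motility beyond rigid drift, mitosis,
endocytotic uptake as a separate pathway, and detector nonlinearity.
Passing tests therefore demonstrate correct recovery under the stated
observation model, not robustness to every artifact of real recordings.

## Estimation

Fits are bounded nonlinear least squares (trust-region reflective;
xtol = ftol = gtol = 1e−12, ≤500 function evaluations per start) over
baseline (free), amplitude (≥0) and one rate (≥0), with a half-time-based
initial rate and a 3-point multistart (k₀ × {0.3, 1, 3}; best SSE wins).
The 3CM never co-fits `k_pb` — with rise data alone the pair (k_f, k_pb) is
poorly identified — but fixes it to the stained-fixed-cell calibration at
the matching duty cycle. Non-convergence is flagged, not raised, and
flagged traces are excluded from population summaries. On noiseless
model-generated data all three models recover their parameters to better
than 10⁻⁶ relative; under 5 % multiplicative noise the median k_f bias
stays below 5 %.

Segmentation is median-background subtraction, a global threshold (Otsu by
default — scale-invariant — or fixed), radius-1 opening, connected
components and an area filter (≥50 µm²). Cells are nearly dark before
uptake, so tracks are built greedily (nearest centroid, 10 µm/frame gate;
jumps beyond the gate terminate a track rather than swap identities), short
tracks (<10 detections) are dropped, and each track's earliest mask is
back-propagated to pre-detection frames, translated by the global drift
estimated from matched centroid displacements — recovering the dim early
rise that carries most of the information about k_f. Border-touching cells
are excluded from population summaries. Traces are mask means per frame;
empty-mask frames are interpolated and flagged.

## Synthetic study design

The cell-line comparison runs the full pipeline (render → drift → noise →
segment → track → extract → fit → summarize) for FaDu and C6 at 2 µM,
100 cells per line at SNR 20. The two lines share the placement, kinetic-
variability and noise random streams (common random numbers), so the
contrast is paired — mirroring matched experimental batches — and the
median-k_f ratio estimates the 2.4-fold kinetic difference rather than
sampling noise of two independent 100-cell draws. Problem sizes (100
cells/line, 61 frames, 4-concentration grids, 200-replicate noise studies)
were chosen so every preset runs in seconds to a few tens of seconds on one
CPU while leaving percentile summaries well determined.

## Known limitations

* The dye-excess regime ties the sonoporation presets' amplitude scale to
  the (small) nominal site densities; absolute intensities are arbitrary
  units and only rate constants and ratios should be interpreted.
* The apparent-rate lines are empirical calibrations per condition; the
  model does not explain *why* the sonoporation and chemical responses
  differ, it reproduces both.
* Greedy nearest-neighbour linking has no merge/split handling and no gap
  bridging; it is adequate for sparse, slowly drifting monolayers.
* The 2CM/3CM observation models assume a single dominant rate; traces with
  strong early free-dye transients are handled by the free baseline and the
  acquisition starting 30 s after onset, not by an explicit lag parameter.
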