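# Methods

This note documents the models, numerical choices and known limitations of
`bcri`, in the spirit of a methods appendix a maintainer can audit.

## Observation-volume calibration

The confocal detection volume is modelled as a 3D Gaussian with beam waist
`w0` (1/e² radius, µm) and axial half-length `z0 = AR·w0`. `w0` is obtained
from the fitted diffusion time of a freely diffusing standard dye via
`w0 = sqrt(4·D_t·τ_D,st)`; the built-in standards are ATTO488-COOH
(400 µm²/s), Alexa568-COOH (370 µm²/s), ATTO655-COOH (426 µm²/s) and
rhodamine B (450 µm²/s), all quoted at 25 °C. Because laser heating raises
the focal temperature a few degrees, reference coefficients are rescaled by
Stokes–Einstein, `D(T₂) = D(T₁)·(T₂/T₁)_K·(η(T₁)/η(T₂))`, using a built-in
water-viscosity table (15–40 °C, standard reference values, linear
interpolation, <0.1% interpolation error). The scaling is exactly the
identity at the reference temperature. Derived quantities:
`V_eff = π^{3/2} w0² z0` (concentrations, `c = N/(N_A V_eff)`) and
`A_eff = π w0 z0` (membrane surface densities). Internally all lengths are
µm, times s, concentrations mol/L; converters live at the I/O boundary.

## Correlation models and fitting

The membrane model combines a triplet factor with two diffusing species:

    G(τ) = (1/N) · G_T(τ) · [ f_3D·g_3D(τ) + (1−f_3D)·g_2D(τ) ]
    G_T  = 1 + f_T e^{−τ/τ_T}/(1−f_T)
    g_3D = (1+τ/τ_3D)^{−1} (1+τ/(AR²τ_3D))^{−1/2}
    g_2D = (1+τ/τ_2D)^{−1}

The two diffusion terms are combined **additively** so that G(0) = 1/N holds
for any species split — the property the brightness definition CPP = F/N
rests on. A multiplicative combination of the two terms (whose zero-lag
amplitude would be f_3D·(1−f_3D)/N, i.e. vanish for a single species) is
available behind `product_form=True` for comparison only.

Fitting is bounded trust-region least squares (`scipy.optimize.least_squares`)
with N and the time constants log-scaled. Membrane bounds: τ_T ∈ [1, 100] µs,
τ_3D ∈ [100 µs, 3 ms], τ_2D ∈ [3, 300] ms, AR fixed to 6. The solution
(free-dye) model relaxes the τ_3D bound to [1 µs, 1 s], since calibration
dyes diffuse in tens of µs — the tight window describes the supernatant
component of membrane measurements, not free dyes. Initialisation is
deterministic (amplitude from the first lag, geometric bound midpoints for
time constants), so fits are reproducible without a seed. Non-convergence and
parameters pinned at a bound are reported as flags/warnings, never silently.
Residuals are unweighted by default.

Run curation drops a run when its fitted linear intensity drift exceeds 10%
of the mean or any bin exceeds mean + 5 SD; datasets with fewer than two
surviving runs per channel are marked unusable. Both thresholds are explicit
configuration values (the underlying acquisition rule is qualitative).

## FCCS corrections and the relative amplitude

Zero-lag amplitudes are taken from 2D-model fits of the two autocorrelations
and the cross-correlation. Corrections, in order:

1. **Background.** Uncorrelated background B dilutes the mean intensity
   without correlating, so each autocorrelation amplitude is multiplied by
   (F/(F−B))², the cross amplitude by the product of the two channel
   factors, and intensities are reduced to F−B. Identity at B = 0.
2. **Spectral cross-talk.** With measured red signal r' = r + κ·g
   (κ = 0.01 by default), the corrected quantities follow from substituting
   r' into the correlation definitions:
   `⟨δgδr⟩ = G_x'·F_g·F_r' − κ·G_g·F_g²`, `F_r = F_r' − κ·F_g`,
   `⟨δr²⟩ = G_r'·F_r'² − 2κ⟨δgδr⟩ − κ²·G_g·F_g²`. These reconstructions are
   validated against the particle simulator, where truth is known.

**Denominator choice.** With amplitudes G_g = 1/N_g, G_r = 1/N_r and
G_x = N_gr/(N_g N_r), the ratio G_x/G_r equals N_gr/N_g — the fraction of
the green (receptor) pool carrying a red label, which is what a click- or
occupancy-style readout measures. G_x/G_g instead equals N_gr/N_r, ≈ 1
whenever every red species sits on a receptor. The default denominator is
therefore the **red** autocorrelation; `denominator="green"` is available.

## Image quantification

Segmentation: optional light Gaussian smoothing (σ = 1 px) stabilises Otsu's
threshold on Poisson counts; the largest 8-connected component is the
membrane mask; boundary pixels are included. One mask, derived from the
reference (eGFP) channel, is shared by all channels; optional integer-pixel
registration maximises mask overlap within ±2 px but defaults to no shift
unless the overlap gain exceeds a tie tolerance (chromatic displacement on a
calibrated instrument is sub-pixel).

Conversion chain per channel: F = mean(counts in mask)/dwell (kHz),
N_raw = F/CPP, N = N_raw/(1−p_nf) with p_nf = 0.20 (eGFP, immature
fluorescent protein) and 0.32 (partially labeled ligand). Then
CE = N_click/N_ref, occupancy = N_ligand/N_ref, density = N_ref/A_eff.

**Interior erosion.** Mean rates are computed after eroding the shared mask
by 1 px (configurable, 0 disables): pixels at the mask boundary are dimmed
by the point-spread function, which biases absolute particle numbers and
densities downward by 10–20% for a ~0.5 µm membrane profile; ratios between
channels are unaffected either way. With erosion the simulated round trip
recovers densities to within 5% across 50–2000 receptors/µm².

Saturation QC flags pixels whose instantaneous rate exceeds 1 MHz; flagged
cells are reported, not dropped. Occupied-state click efficiencies measured
under partial ligand binding are un-mixed linearly:
CE_occ = (CE'_occ − (1−F_occ)·CE_free)/F_occ.

## Binding statistics

The Monte-Carlo Hill fit perturbs **both axes** of every titration point with
zero-mean Gaussians of width σ_c and σ_θ and refits 10,000 times (default),
reporting resample means ± SDs; c0 is fitted in log space, and perturbed
concentrations are floored at 1% of their unperturbed value to stay in the
model's domain. `fix_n=1` (the 1:1 binding model) is the default; the Hill
coefficient can be freed. A single zero-noise resample reproduces the plain
least-squares fit exactly.

Labeling kinetics: CE(t) = A_f(1−e^{−k_f t}) + A_s(1−e^{−k_s t}) fitted by
multi-start (20 log-spaced rate initialisations) bounded least squares; rate
separation below 3× flags weak identifiability. The concentration dependence
uses a two-hyperbola saturation CE(c) = B1·c/(K1+c) + B2·c/(K2+c) — a
deliberate functional choice for the "fast surface compartment + bulk-fed
compartment" picture; alternatives can be substituted, and boundary solutions
are flagged.

Occupancy mixtures: 1- vs 2-component Gaussian mixtures by EM (10 restarts,
fixed seed, component-variance floor at (1% of data range)²), selected by
small-sample-corrected AIC. If the 2-component EM lands below the nested
1-component likelihood (a local optimum), it is re-seeded from the duplicated
1-component solution, which EM can only improve — guaranteeing L₂ ≥ L₁.

Welch's t-test uses `scipy.stats.ttest_ind(equal_var=False)`, with the
Welch–Satterthwaite degrees of freedom reported. Monte-Carlo Pearson
correlations perturb both coordinates with their σ and report plain r/p plus
resample mean ± SD (10,000 resamples by default). Differential click
efficiency is ΔCE = CE_occ − CE_free with SEM_Δ = sqrt(SEM²_occ + SEM²_free)
(independence assumed); a secondary-axis scaling factor equates the SD across
sites of |ΔCE| and of an RMSD profile for joint display.

## Trajectory post-processing

**Average structures** are computed by superposing every frame (least squares
over all atoms, proper rotations only) onto the running mean, iterated three
times from the raw arithmetic mean. Starting from the raw mean — rather than
from frame 0 — makes the result independent of frame order and avoids the
constant misalignment floor a noisy single-frame reference would imprint.

**B-factors.** Frames are superposed onto the average structure; for each
residue the mean-square fluctuation of its peptide-bond atoms (N, CA, C, O;
the BCN pseudo-residue renames these to N, C2, C3, O3) is converted by the
crystallographic convention B = (8π²/3)·MSF. Raw RMSF is reported alongside.
For isotropic per-axis jitter σ this reproduces 8π²σ², up to the well-known
rigid-body absorption of order 6/(3·N_atoms), negligible for real systems.

**Catchbox.** A 13.5 × 4.5 × 3.5 Å cuboid is centred on the C14–C15
triple-bond midpoint each frame. Only the local x-axis (along C14→C15) is
fixed by the geometry; the y-axis is chosen as the component of the vector
from the ring-carbon centroid to the bond midpoint orthogonal to x — a
deterministic, chemically meaningful in-plane direction — and z = x × y.
Membership is |ξᵢ| ≤ dimᵢ/2 in local coordinates, verified against a
brute-force six-half-space oracle. Hit distances are measured from the BCNK
residue's Cα (C2) anchor, an explicit convention.

**Ring orientation.** n = normalize((C15−C11) × (C14−C18)) per frame, after
superposing frames onto the average structure (so the angles live in a
consistent molecular frame; the lab frame is available via
`superpose=False`). Polar = arccos(n_z), azimuth = atan2(n_y, n_x); at the
poles the azimuth is fixed to 0 by convention; near-collinear vector pairs
(|cross| < 1e−9) are excluded and reported. Angle maps use a Gaussian KDE
with the bandwidth chosen by leave-one-out cross-validated grid search over
100 log-spaced values in [0.1, 10]°; angles are treated as Euclidean (no
periodic wrap, matching the estimator used for the original maps — a wrapped
variant would be a straightforward extension); contour levels are 8
log-spaced values floored at 10^−6.5.

**Domain-wise RMSD profiles.** Chains are paired by global sequence alignment
(BLOSUM62, gap open/extend −10/−1), superposed on the Cα pairs inside the
requested domain (D1 ≈ residues 2–96, D2 ≈ 98–196, or a global 2–196 range
for linker sites) with iterative outlier rejection (5 cycles, rejecting pairs
beyond 2.0× the current RMSD, mirroring the molecular-graphics `align`
behaviour; `outlier_cycles=0` gives pure one-shot superposition). The frozen
transform is then applied once and RMSD_0..3 computed per anchor (anchor Cα
alone, then ±1/2/3 sequence neighbours) **without refitting**. Residue
numbering: construct numbering is mature + 6 (N-terminal His-tag); site
labels use mature numbering with explicit converters.

Solvation-free-energy tables are consumed, not computed: per-site means ± SEM
over sub-trajectory values after discarding values beyond 3 SD of the site
mean (note this criterion cannot mathematically trigger for fewer than ~10
values, since max |z| = (n−1)/√n).

## Synthetic-data generators

Defaults are the study conditions: click efficiency 20% (the standard-
condition readout), double-labeled fraction 38% (the clicked-receptor FCCS
readout), p_nf 0.20/0.32, membrane diffusion 0.2 µm²/s, w0 = 0.2 µm, AR = 6,
1% cross-talk, 0.2 kHz background per channel, Hill truth A = 1, A0 = 0,
n = 1 with c0 = 34 nM, and surface densities spanning 50–2000 µm⁻².

*Fluctuation traces:* 100 particles diffuse in a periodic square box of edge
10·w0 (large enough to avoid depletion) with time step ≤ w0²/(100·D)
(enforced); detection is a centred 2D Gaussian exp(−2r²/w0²); photons are
Poisson per 1 ms bin; a double-labeled subset emits in both channels;
cross-talk adds κ× the green molecular rate to red. Triplet blinking is an
optional two-state telegraph (off by default — its µs timescale is far below
the 1 ms binning of the membrane-scale simulations). The correlator computes
G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩² by FFT on a quasi-logarithmic lag grid (16 per
decade, max lag = trace/4).

*Cell images:* an annulus (radius 4 µm, thickness 0.5 µm) represents the
equatorial membrane section; membrane-pixel rates follow the imaging
convention rate = ρ·A_eff·fraction·(1−p_nf)·CPP, scaled per cell by a common
auto-exposure factor that puts the reference channel at 200 kHz (mimicking
per-image laser attenuation below detector saturation; effective CPPs are
recorded in the truth record); Gaussian PSF of σ = 0.55 px; Poisson sampling.
Not emulated: intracellular signal, membrane ruffling, bleaching, detector
afterpulsing, vignetting — so passing round trips demonstrate calibration
correctness, not robustness to those real-data features.

*Titrations:* per point, 30 single-cell bound fractions (SD 0.05) are
averaged; the free-ligand concentration is the mean of 18 simulated FCS runs
with 10% relative noise each, reported with the run-to-run SD — mirroring how
titration error bars are quoted (SD across cells/runs on each axis).

*Trajectories:* reference + zero-mean Gaussian jitter (scalar or per-atom σ),
optional random rigid tumbling per frame that superposing analyses must undo.

All generators are bit-reproducible from (config, seed).

## Problem sizes and tolerances

The test suite and the acceptance script use scaled problem sizes chosen for
quick, statistically sufficient closed loops: 60 s particle traces at 1 ms
binning (5 seed pairs for the co-diffusion loop), 30 cells for the imaging
loop, 10 repetitions × 2,000 resamples for the Hill-recovery calibration
(the acceptance script itself uses the full 10,000 resamples), 2,000 frames
for the B-factor law, 10⁴ atom-frame pairs for the catchbox oracle. Noiseless
round trips are asserted at 1e−6 relative; stochastic loops at their sampling
error (e.g. ±5 points for the co-diffusion fraction, ±2 points for mean CE).

## Known limitations

- The 3BPN/3BPO crystal-structure comparison requires those PDB entries as
  local files; they are not redistributed with the package.
- No raw photon-stream (TTTR) correlation, afterpulsing correction, 3D image
  stacks, deconvolution, or bleaching correction.
- The KDE for angle maps is non-periodic by design (see above); densities
  near ±180° azimuth are split across the seam.
- The background/cross-talk corrections are reconstructions of the cited
  correction scheme validated against the particle simulator, not against
  instrument data.
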