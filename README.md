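# bcri — brightness-calibrated ratiometric imaging

`bcri` quantifies **absolute molecule numbers and label ratios at the plasma
membrane of living cells** from confocal photon-counting images. The central
idea is to calibrate pixel intensities with the *molecular brightness* (counts
per particle, CPP) of each fluorophore measured by fluorescence correlation
spectroscopy (FCS), so that ordinary confocal images become quantitative:
receptor surface densities, the fraction of receptors carrying a
bioorthogonally "clicked" dye (click efficiency, CE), and the fraction bound
by fluorescent ligand (occupancy) are read off per cell.

It is aimed at quantitative fluorescence microscopists and chemical
biologists characterising genetic-code-expansion labeling (e.g. BCNK/tetrazine
iEDDA chemistry on an interleukin receptor), and at computational users
post-processing the matching MD trajectories.

## What it computes

**Calibration** (`bcri.calibration`). The confocal observation volume is a 3D
Gaussian with beam waist `w0 = sqrt(4·D_t·τ_D,st)` from a standard dye's
diffusion time, effective volume `V_eff = π^{3/2}·w0²·z0` and equatorial
cross-section `A_eff = π·w0·z0`; excitation power density `P_0 = 2·P_tot/(π·w0²)`;
degree of labeling from absorbance,
`DOL = A_dye,max·ε_prot,280 / ((A_dye,280 − A_dye,max·CF_280)·ε_dye,max)`.

**Correlation analysis** (`bcri.correlation`). Autocorrelation models
`G(τ) = (1/N)·G_T(τ)·[G_3D(τ) + G_2D(τ)]` (triplet, free 3D species, membrane
2D species; axis ratio fixed to 6; the standard bound set τ_T ∈ [1, 100] µs,
τ_3D ∈ [100 µs, 3 ms], τ_2D ∈ [3, 300] ms), bounded least-squares fitting,
CPP = F/N, run curation (drift/spike rejection), and dual-color FCCS
amplitude ratios corrected for uncorrelated background and 1% green→red
spectral cross-talk.

**Image quantification** (`bcri.imaging`). Otsu segmentation of the membrane
(largest connected component on the eGFP channel), then per channel
`N = mean(counts)/dwell / CPP / (1 − p_nf)`, with `p_nf` the non-fluorescent
label fraction (0.20 for eGFP, 0.32 for the partially labeled ligand);
CE = N_click/N_ref, occupancy = N_ligand/N_ref, density = N_ref/A_eff,
`c = N/(N_A·V_eff)`.

**Binding & kinetics** (`bcri.binding`). Monte-Carlo Hill fits
`θ = A/(1+(c0/c)^n) + A0` with Gaussian perturbation of both axes (10,000
resamples), double-exponential and two-state-saturation labeling kinetics,
Gaussian-mixture decomposition of occupancy distributions, Welch's t-test,
Monte-Carlo Pearson correlations.

**Structure analysis** (`bcri.structure`). MD post-processing around the
BCNK incorporation site: iterated-mean average structures, peptide-bond
B-factors `(8π²/3)·MSF`, the 13.5 × 4.5 × 3.5 Å "catchbox" census along the
ring's triple-bond axis, ring-normal orientation maps with LOO-cross-validated
kernel density estimates, and domain-wise Cα superposition with anchor RMSD
profiles (RMSD_0..3).

**Synthetic data** (`bcri.simulate`). Ground-truth generators for everything
above: Brownian particles through a Gaussian focus (dual-color, Poisson
photons, cross-talk), a multi-tau-style FFT correlator, three-channel annulus
cell images, Hill titrations, and jittered coordinate ensembles.

## Worked example

Simulate one cell under standard click-labeling conditions (true CE 20%,
surface density 500 receptors/µm²) and quantify it:

```python
from bcri.calibration import effective_volume
from bcri.imaging import quantify_cell
from bcri.simulate import SimulationConfig, simulate_cell_image

sim = simulate_cell_image(SimulationConfig(seed=6))
cal = {"egfp": effective_volume(0.2, 6.0, laser_line=488.0)}
cell = quantify_cell(sim["channels"], cal,
                     cpp=sim["truth"]["cpp"], p_nf=sim["truth"]["p_nf"])
print(f"CE = {cell.CE:.3f}, occupancy = {cell.occupancy:.3f}, "
      f"density = {cell.density:.0f} /um^2")
```

prints

```
CE = 0.189, occupancy = 0.962, density = 508 /um^2
```

i.e. the pipeline recovers the simulated truth within shot noise: 18.9% of
the receptors carry the clicked dye (truth 20%), essentially all receptors
are ligand-bound (truth 100%), and the surface density is 508/µm² (truth
500). The same
pipeline is exposed on the command line (`bcri simulate image`,
`bcri quantify`, `bcri titrate`, `bcri structure rmsd`, ...); run
`bcri --help` for the full set.

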