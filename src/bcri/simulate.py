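"""Synthetic-data generators with known ground truth.

Every analysis stage in this package has a matching generator here: Brownian
particles crossing a Gaussian observation volume feed the correlator and the
FCS/FCCS fits, annulus-shaped photon-count images feed the BCRI pipeline,
Hill-model titrations feed the Monte-Carlo binding fit, and jittered
coordinate ensembles feed the trajectory analyses. Generators are
deterministic given (config, seed) and return their ground truth alongside
the data, so closed-loop parameter-recovery tests are the module's reason to
exist.

Default parameter values emulate the study conditions of the click-labeling
experiments: K97B standard-condition click efficiency 20%, non-fluorescent
fractions 0.20 (eGFP) and 0.32 (labeled ligand), membrane diffusion around
0.2 µm²/s, beam waist 0.2 µm with axis ratio 6, 1% green→red spectral
cross-talk, and surface densities between 50 and 2000 receptors/µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .binding import TitrationDataset, hill_equation
from .correlation import AcfModelParams, CorrelationCurve, model_membrane_acf, \
    model_solution_acf
from .imaging import ChannelImage
from .structure import TrajectoryEnsemble

__all__ = [
    "SimulationConfig",
    "simulate_fluctuation_traces",
    "correlate",
    "cross_correlate",
    "synthetic_acf_curve",
    "simulate_cell_image",
    "simulate_titration",
    "simulate_trajectory",
]


@dataclass
class SimulationConfig:
    """Ground-truth parameters shared by the generators.

    Units: lengths µm, times s, diffusion µm²/s, brightness kHz,
    concentrations mol/L, densities µm⁻².
    """

    seed: int

    # particle / FCS simulation
    n_particles: int = 100
    frac_double: float = 0.38  # double-labeled fraction (K97B-Cy5 readout)
    diffusion: float = 0.2  # membrane diffusion coefficient
    w0: float = 0.2
    AR: float = 6.0
    box_factor: float = 10.0  # box edge in units of w0
    dt: float = 1e-3  # s per bin
    duration: float = 60.0  # s
    cpp_green: float = 20.0  # kHz at focus center
    cpp_red: float = 20.0
    background_green: float = 0.2  # kHz
    background_red: float = 0.2
    crosstalk: float = 0.01  # green → red
    f_T: float = 0.0
    tau_T: float = 5e-6

    # imaging
    image_size: int = 128
    pixel_size: float = 0.1  # µm
    dwell_time: float = 25e-6  # s
    annulus_radius: float = 4.0  # µm
    annulus_thickness: float = 0.5  # µm
    psf_sigma_factor: float = 0.55  # PSF sigma in units of pixel size
    target_ref_rate_khz: float = 200.0  # auto-exposure target, reference channel
    density: float = 500.0  # receptors/µm²
    true_ce: float = 0.20
    true_occupancy: float = 1.0
    p_nf_ref: float = 0.20
    p_nf_ligand: float = 0.32
    cpp_ref: float = 3.0  # kHz (eGFP)
    cpp_click: float = 20.0
    cpp_ligand: float = 15.0
    background_counts: float = 0.0  # constant offset, counts/px

    # titration
    hill_A: float = 1.0
    hill_A0: float = 0.0
    hill_c0: float = 34e-9  # mol/L
    hill_n: float = 1.0
    cells_per_point: int = 30
    theta_cell_sd: float = 0.05
    conc_rel_noise: float = 0.10
    conc_runs: int = 18  # FCS runs averaged per supernatant concentration

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_particles", "diffusion", "w0", "dt", "duration",
                     "image_size", "pixel_size", "dwell_time", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Brownian-particle fluctuation traces


def simulate_fluctuation_traces(cfg: SimulationConfig) -> dict:
    """Dual-channel intensity traces from 2D Brownian motion through a focus.

    ``n_particles`` diffuse in a periodic square box (edge ``box_factor``·w0)
    past a centred 2D-Gaussian detection profile exp(−2r²/w0²). A fraction
    ``frac_double`` of particles carries both labels; the rest carry only the
    green one. Photon counts per bin are Poisson with mean (CPP·profile +
    background)·dt, and a fraction ``crosstalk`` of the green molecular
    signal bleeds into the red channel. Optional triplet blinking is a
    two-state telegraph with dark fraction f_T and relaxation time tau_T.

    Returns ``{"green", "red", "dt", "truth"}`` with counts per bin.
    """
    if cfg.dt > cfg.w0**2 / (100.0 * cfg.diffusion):
        raise ValueError(
            "time step too coarse for the diffusion coefficient: "
            f"dt must be <= w0^2/(100 D) = {cfg.w0**2 / (100 * cfg.diffusion):.2e} s"
        )
    rng = np.random.default_rng(cfg.seed)
    n_bins = int(round(cfg.duration / cfg.dt))
    box = cfg.box_factor * cfg.w0
    n = cfg.n_particles
    n_double = int(round(cfg.frac_double * n))
    is_double = np.zeros(n, dtype=bool)
    is_double[:n_double] = True

    pos = rng.uniform(-box / 2, box / 2, size=(n, 2))
    step_sd = np.sqrt(2.0 * cfg.diffusion * cfg.dt)
    use_triplet = cfg.f_T > 0

    rate_g = np.empty(n_bins)
    rate_r = np.empty(n_bins)
    chunk = 4096
    dark = np.zeros(n, dtype=bool)
    for start in range(0, n_bins, chunk):
        m = min(chunk, n_bins - start)
        steps = rng.normal(0.0, step_sd, size=(m, n, 2))
        path = pos[None] + np.cumsum(steps, axis=0)
        pos = path[-1]
        wrapped = (path + box / 2) % box - box / 2
        w = np.exp(-2.0 * np.sum(wrapped**2, axis=2) / cfg.w0**2)  # (m, n)
        if use_triplet:
            p_dark = cfg.f_T / cfg.tau_T * cfg.dt
            p_bright = (1 - cfg.f_T) / cfg.tau_T * cfg.dt
            flips = rng.random((m, n))
            for k in range(m):
                dark = np.where(dark, flips[k] >= p_bright, flips[k] < p_dark)
                w[k, dark] = 0.0
        rate_g[start : start + m] = cfg.cpp_green * w.sum(axis=1)
        rate_r[start : start + m] = cfg.cpp_red * w[:, is_double].sum(axis=1)
    # kHz → counts/s, add crosstalk and background, then Poisson sampling
    lam_g = (rate_g + cfg.background_green) * 1e3 * cfg.dt
    lam_r = (rate_r + cfg.crosstalk * rate_g + cfg.background_red) * 1e3 * cfg.dt
    green = rng.poisson(lam_g)
    red = rng.poisson(lam_r)
    return {
        "green": green,
        "red": red,
        "dt": cfg.dt,
        "truth": {
            "frac_double": n_double / n,
            "n_particles": n,
            "tau_2D": cfg.w0**2 / (4.0 * cfg.diffusion),
            "background_green": cfg.background_green,
            "background_red": cfg.background_red,
            "crosstalk": cfg.crosstalk,
        },
    }


def _log_lag_indices(n_bins: int, n_per_decade: int = 16) -> np.ndarray:
    max_lag = n_bins // 4
    raw = np.logspace(0, np.log10(max_lag), int(np.log10(max_lag) * n_per_decade))
    return np.unique(raw.astype(int))


def _fft_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Unnormalised cross-covariance ⟨δa(t)δb(t+τ)⟩ for all non-negative lags."""
    n = a.size
    da = a - a.mean()
    db = b - b.mean()
    size = 1 << int(np.ceil(np.log2(2 * n)))
    fa = np.fft.rfft(da, size)
    fb = np.fft.rfft(db, size)
    corr = np.fft.irfft(np.conj(fa) * fb, size)[:n]
    counts = n - np.arange(n)
    return corr / counts


def correlate(
    trace: np.ndarray,
    dt: float,
    channel: str = "green",
    n_per_decade: int = 16,
    max_lag_fraction: float = 0.25,
) -> CorrelationCurve:
    """Normalised fluctuation autocorrelation on a quasi-logarithmic lag grid.

    G(τ) = ⟨δF(t)δF(t+τ)⟩/⟨F⟩², evaluated by FFT and subsampled to
    ``n_per_decade`` lags per decade up to a quarter of the trace length.
    """
    return cross_correlate(trace, trace, dt, channel=channel,
                           n_per_decade=n_per_decade,
                           max_lag_fraction=max_lag_fraction)


def cross_correlate(
    a: np.ndarray,
    b: np.ndarray,
    dt: float,
    channel: str = "cross",
    n_per_decade: int = 16,
    max_lag_fraction: float = 0.25,
) -> CorrelationCurve:
    """Normalised cross-correlation G(τ) = ⟨δa(t)δb(t+τ)⟩/(⟨a⟩⟨b⟩)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("traces must have equal length")
    lag_idx = _log_lag_indices(a.size, n_per_decade)
    lag_idx = lag_idx[lag_idx <= int(a.size * max_lag_fraction)]
    if a.size < 8 or lag_idx.size < 4:
        raise ValueError("trace too short to correlate")
    denom = a.mean() * b.mean()
    if denom == 0:
        raise ValueError("zero-mean trace cannot be normalised")
    corr = _fft_correlation(a, b)
    g = corr[lag_idx] / denom
    mean_khz = 0.5 * (a.mean() + b.mean()) / dt / 1e3
    return CorrelationCurve(
        lags=lag_idx * dt, G=g, channel=channel,
        mean_intensity=mean_khz, duration=a.size * dt,
    )


def synthetic_acf_curve(
    params: AcfModelParams,
    model: str = "membrane",
    lags: np.ndarray | None = None,
    mean_intensity: float | None = None,
) -> CorrelationCurve:
    """Noiseless model correlation curve (fit oracle input).

    ``mean_intensity`` defaults to 10 kHz per particle, so CPP round-trips to
    10 kHz exactly.
    """
    if lags is None:
        lags = np.logspace(-6, 1, 160)
    if model == "membrane":
        g = model_membrane_acf(lags, params)
    elif model == "solution":
        g = model_solution_acf(lags, params.N, params.tau_3D, params.AR)
    else:
        raise ValueError(f"unknown model '{model}'")
    f = mean_intensity if mean_intensity is not None else 10.0 * params.N
    return CorrelationCurve(lags=lags, G=g, channel="synthetic", mean_intensity=f)


# ---------------------------------------------------------------------------
# Confocal cell images


def simulate_cell_image(cfg: SimulationConfig) -> dict:
    """Three-channel photon-count images of an annulus-shaped membrane section.

    The equatorial cross-section of the plasma membrane is an annulus of
    radius ``annulus_radius`` and thickness ``annulus_thickness``. On
    membrane pixels the expected count rate of a channel follows the imaging
    calibration convention — the focal spot sees the receptors inside the
    elliptical cross-section A_eff = π·w0·z0:

        rate = ρ · A_eff · fraction · (1 − p_nf) · CPP

    with fraction the channel's labeled share (1 for the reference, CE for
    the click channel, occupancy for the ligand channel). Mimicking
    acquisition practice, the excitation of every channel is scaled by a
    common per-cell exposure factor that puts the reference-channel membrane
    rate at ``target_ref_rate_khz`` (laser attenuation is chosen per cell to
    stay below detector saturation); the effective CPPs after this scaling
    are reported in the truth record, as they would be read off the
    brightness-versus-power calibration. The rate map is blurred with an
    isotropic Gaussian PSF and Poisson-sampled.

    Returns ``{"channels": {name: ChannelImage}, "truth": {...}}``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size
    extent = n * cfg.pixel_size
    if cfg.annulus_radius + cfg.annulus_thickness > extent / 2:
        raise ValueError("annulus does not fit inside the frame")
    yy, xx = np.mgrid[0:n, 0:n]
    r = np.hypot((xx - n / 2) * cfg.pixel_size, (yy - n / 2) * cfg.pixel_size)
    membrane = (
        (r >= cfg.annulus_radius - cfg.annulus_thickness / 2)
        & (r <= cfg.annulus_radius + cfg.annulus_thickness / 2)
    ).astype(float)

    a_eff = np.pi * cfg.w0 * (cfg.AR * cfg.w0)  # µm²
    n_focus = cfg.density * a_eff  # receptors in the focal cross-section
    specs = {
        "egfp": (1.0, cfg.p_nf_ref, cfg.cpp_ref),
        "click": (cfg.true_ce, 0.0, cfg.cpp_click),
        "ligand": (cfg.true_occupancy, cfg.p_nf_ligand, cfg.cpp_ligand),
    }
    ref_rate = n_focus * (1.0 - cfg.p_nf_ref) * cfg.cpp_ref  # kHz
    exposure = cfg.target_ref_rate_khz / ref_rate
    lines = {"egfp": 488.0, "click": 561.0, "ligand": 633.0}
    channels = {}
    for name, (fraction, p_nf, cpp) in specs.items():
        rate = n_focus * fraction * (1.0 - p_nf) * cpp * exposure  # kHz
        expected = membrane * rate * 1e3 * cfg.dwell_time
        expected = gaussian_filter(expected, cfg.psf_sigma_factor)
        expected += cfg.background_counts
        counts = rng.poisson(expected).astype(np.uint16)
        channels[name] = ChannelImage(
            pixels=counts,
            dwell_time=cfg.dwell_time,
            pixel_size=cfg.pixel_size,
            channel=name,
            laser_line=lines[name],
        )
    return {
        "channels": channels,
        "truth": {
            "ce": cfg.true_ce,
            "occupancy": cfg.true_occupancy,
            "density": cfg.density,
            "membrane_mask": membrane.astype(bool),
            "exposure": exposure,
            "cpp": {"egfp": cfg.cpp_ref * exposure,
                    "click": cfg.cpp_click * exposure,
                    "ligand": cfg.cpp_ligand * exposure},
            "p_nf": {"egfp": cfg.p_nf_ref, "click": 0.0,
                     "ligand": cfg.p_nf_ligand},
        },
    }


# ---------------------------------------------------------------------------
# Titrations


def simulate_titration(cfg: SimulationConfig, c_grid: np.ndarray) -> TitrationDataset:
    """Synthetic titration from the Hill-model ground truth.

    Per concentration, ``cells_per_point`` single-cell bound fractions are
    drawn around the Hill curve with SD ``theta_cell_sd`` and aggregated to
    mean ± SD. The free-ligand concentration is measured as the mean of
    ``conc_runs`` FCS readouts of the supernatant, each carrying
    multiplicative Gaussian noise of relative width ``conc_rel_noise``; the
    reported σ_c is the run-to-run SD, matching how titration error bars are
    quoted (mean ± SD of runs/cells on each axis).
    """
    rng = np.random.default_rng(cfg.seed)
    c_grid = np.asarray(c_grid, dtype=float)
    if np.any(c_grid <= 0):
        raise ValueError("concentrations must be positive")
    c_meas, sigma_c, theta, sigma_theta, n_cells = [], [], [], [], []
    for c in c_grid:
        th_true = hill_equation(c, cfg.hill_A, cfg.hill_A0, cfg.hill_c0, cfg.hill_n)
        cells = rng.normal(th_true, cfg.theta_cell_sd, size=cfg.cells_per_point)
        runs = c * np.maximum(
            1.0 + rng.normal(0.0, cfg.conc_rel_noise, size=cfg.conc_runs), 0.05
        )
        c_meas.append(runs.mean())
        sigma_c.append(runs.std(ddof=1))
        theta.append(cells.mean())
        sigma_theta.append(cells.std(ddof=1))
        n_cells.append(cfg.cells_per_point)
    return TitrationDataset(
        c=np.array(c_meas), sigma_c=np.array(sigma_c),
        theta=np.array(theta), sigma_theta=np.array(sigma_theta),
        n_cells=np.array(n_cells),
    )


# ---------------------------------------------------------------------------
# Coordinate ensembles


def simulate_trajectory(
    reference: TrajectoryEnsemble | np.ndarray,
    jitter: float | np.ndarray,
    n_frames: int,
    seed: int,
    tumbling: bool = False,
) -> TrajectoryEnsemble:
    """Jittered coordinate ensemble around a reference structure.

    Frames are the reference plus zero-mean isotropic Gaussian displacements
    (``jitter`` in Å, scalar or per-atom). ``tumbling`` applies an additional
    random rigid rotation/translation per frame, which a superposing analysis
    must undo.
    """
    rng = np.random.default_rng(seed)
    if isinstance(reference, TrajectoryEnsemble):
        base = reference.coords[0]
        meta = reference
    else:
        base = np.asarray(reference, dtype=float)
        n_atoms = base.shape[0]
        meta = TrajectoryEnsemble(
            atom_names=np.array(["CA"] * n_atoms),
            res_names=np.array(["ALA"] * n_atoms),
            res_ids=np.arange(1, n_atoms + 1),
            chains=np.array(["A"] * n_atoms),
            coords=base[None],
        )
    sigma = np.asarray(jitter, dtype=float)
    if sigma.ndim == 1:
        sigma = sigma[:, None]
    frames = base[None] + rng.normal(0.0, 1.0, size=(n_frames,) + base.shape) * sigma
    if tumbling:
        from scipy.spatial.transform import Rotation

        for i in range(n_frames):
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.normal(0.0, 5.0, size=3)
            frames[i] = frames[i] @ rot.T + shift
    return TrajectoryEnsemble(
        atom_names=meta.atom_names, res_names=meta.res_names,
        res_ids=meta.res_ids, chains=meta.chains, coords=frames,
    )
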