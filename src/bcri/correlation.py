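"""FCS/FCCS model functions, curve fitting, run curation and amplitude corrections.

The autocorrelation models cover two regimes measured at the plasma membrane
of living cells: a fast freely diffusing 3D species (unbound ligand in the
supernatant), a slow membrane-bound 2D species, and fast triplet/blinking
kinetics. Fitting follows bounded nonlinear least squares with the standard
constraint set (axis ratio fixed to 6; triplet time 1–100 µs; 3D diffusion
time 100 µs–3 ms; 2D diffusion time 3–300 ms). The molecular brightness is
CPP = F/N from the fitted particle number and the mean count rate.

Dual-color cross-correlation amplitudes are corrected for uncorrelated
background and spectral cross-talk from the green into the red detection
channel (1% by default) before forming the relative cross-correlation
amplitude that reads out co-diffusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CorrelationCurve",
    "AcfModelParams",
    "AcfFitResult",
    "FccsResult",
    "DEFAULT_BOUNDS",
    "model_membrane_acf",
    "model_solution_acf",
    "model_2d_acf",
    "curate_runs",
    "fit_acf",
    "fit_2d_amplitude",
    "fccs_relative_amplitude",
]


@dataclass(frozen=True)
class CorrelationCurve:
    """A correlation curve G(τ) with its acquisition metadata.

    ``mean_intensity`` is the average count rate F of the run in kHz; it is
    what converts a fitted particle number into a molecular brightness.
    """

    lags: np.ndarray  # s, strictly increasing
    G: np.ndarray
    channel: str = "green"
    mean_intensity: float = 0.0  # kHz
    duration: float = 0.0  # s
    run_id: int = 0

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", g)
        if lags.ndim != 1 or lags.size == 0:
            raise ValueError("lags must be a non-empty 1D array")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if g.shape != lags.shape:
            raise ValueError("G must match lags in shape")
        if not np.all(np.isfinite(g)):
            raise ValueError("G must be finite")
        if self.mean_intensity < 0:
            raise ValueError("mean intensity must be non-negative")


@dataclass(frozen=True)
class AcfModelParams:
    """Parameters of the triplet + 3D + 2D membrane autocorrelation model."""

    N: float
    f_T: float = 0.0
    tau_T: float = 5e-6  # s
    f_3D: float = 1.0
    tau_3D: float = 3e-4  # s
    tau_2D: float = 3e-2  # s
    AR: float = 6.0

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if not (0 <= self.f_T < 1):
            raise ValueError("f_T must be in [0, 1)")
        if not (0 <= self.f_3D <= 1):
            raise ValueError("f_3D must be in [0, 1]")
        if min(self.tau_T, self.tau_3D, self.tau_2D, self.AR) <= 0:
            raise ValueError("time constants and AR must be positive")


#: Fit bounds used for membrane measurements: triplet time 1–100 µs,
#: 3D diffusion time 100 µs – 3 ms, 2D diffusion time 3–300 ms.
DEFAULT_BOUNDS = {
    "N": (1e-3, 1e6),
    "f_T": (0.0, 0.999),
    "tau_T": (1e-6, 1e-4),
    "f_3D": (0.0, 1.0),
    "tau_3D": (1e-4, 3e-3),
    "tau_2D": (3e-3, 3e-1),
}


def _triplet_term(tau: np.ndarray, f_T: float, tau_T: float) -> np.ndarray:
    if f_T == 0:
        return np.ones_like(tau)
    return 1.0 + f_T * np.exp(-tau / tau_T) / (1.0 - f_T)


def _g3d_shape(tau: np.ndarray, tau_3D: float, AR: float) -> np.ndarray:
    return (1.0 + tau / tau_3D) ** -1 * (1.0 + tau / (AR**2 * tau_3D)) ** -0.5


def model_membrane_acf(
    tau: np.ndarray | float, p: AcfModelParams, product_form: bool = False
) -> np.ndarray | float:
    """Membrane autocorrelation: triplet × (3D + 2D diffusion).

    G(τ) = (1/N)·G_T(τ)·[f_3D·g_3D(τ) + (1−f_3D)·g_2D(τ)] so that
    G(0) = 1/N for any species split, which is what CPP = F/N requires.

    ``product_form=True`` multiplies the two diffusion terms instead of
    summing them (kept for comparison with the literature transcription of
    the model; its zero-lag amplitude is f_3D·(1−f_3D)/N).
    """
    t = np.asarray(tau, dtype=float)
    g_t = _triplet_term(t, p.f_T, p.tau_T)
    g3 = p.f_3D * _g3d_shape(t, p.tau_3D, p.AR)
    g2 = (1.0 - p.f_3D) / (1.0 + t / p.tau_2D)
    if product_form:
        g = g_t * g3 * g2 / p.N
    else:
        g = g_t * (g3 + g2) / p.N
    return float(g) if np.isscalar(tau) else g


def model_solution_acf(
    tau: np.ndarray | float, N: float, tau_3D: float, AR: float = 6.0
) -> np.ndarray | float:
    """Single-species free 3D diffusion: G = (1/N)·(1+τ/τ_3D)⁻¹(1+τ/(AR²τ_3D))^(−1/2)."""
    if N <= 0 or tau_3D <= 0 or AR <= 0:
        raise ValueError("N, tau_3D and AR must be positive")
    t = np.asarray(tau, dtype=float)
    g = _g3d_shape(t, tau_3D, AR) / N
    return float(g) if np.isscalar(tau) else g


def model_2d_acf(
    tau: np.ndarray | float, N: float, tau_2D: float
) -> np.ndarray | float:
    """Single-species 2D membrane diffusion: G = (1/N)/(1+τ/τ_2D)."""
    if N <= 0 or tau_2D <= 0:
        raise ValueError("N and tau_2D must be positive")
    t = np.asarray(tau, dtype=float)
    g = 1.0 / (N * (1.0 + t / tau_2D))
    return float(g) if np.isscalar(tau) else g


def curate_runs(
    runs: list[CorrelationCurve],
    intensity_traces: list[np.ndarray],
    drift_threshold: float = 0.10,
    spike_sd: float = 5.0,
    min_runs: int = 2,
) -> dict:
    """Discard runs with slow intensity drifts or intensity spikes.

    A run is dropped when the fitted linear drift over the run exceeds
    ``drift_threshold`` (fraction of the mean intensity) or any intensity bin
    exceeds mean + ``spike_sd``·SD. Downstream correlation analysis requires
    at least ``min_runs`` surviving runs per channel.

    Returns ``{"kept": [...], "flags": {run_id: reason}, "usable": bool}``.
    """
    if len(runs) == 0:
        raise ValueError("no runs provided")
    if len(runs) != len(intensity_traces):
        raise ValueError("one intensity trace per run is required")
    kept: list[CorrelationCurve] = []
    flags: dict[int, str] = {}
    for run, trace in zip(runs, intensity_traces):
        tr = np.asarray(trace, dtype=float)
        mean = tr.mean()
        if mean <= 0:
            flags[run.run_id] = "empty trace"
            continue
        x = np.arange(tr.size)
        slope = np.polyfit(x, tr, 1)[0]
        drift = abs(slope * (tr.size - 1)) / mean
        sd = tr.std()
        has_spike = sd > 0 and np.any(tr > mean + spike_sd * sd)
        if drift > drift_threshold:
            flags[run.run_id] = f"drift {drift:.2f} > {drift_threshold:.2f}"
        elif has_spike:
            flags[run.run_id] = "intensity spike"
        else:
            kept.append(run)
    if not kept:
        raise ValueError("no usable runs after curation")
    channels = {r.channel for r in kept}
    usable = all(
        sum(r.channel == ch for r in kept) >= min_runs for ch in channels
    )
    return {"kept": kept, "flags": flags, "usable": usable}


@dataclass
class AcfFitResult:
    """Result of a bounded least-squares autocorrelation fit."""

    params: AcfModelParams
    cpp: float  # kHz, = F/N
    residual_norm: float
    converged: bool
    at_bounds: list[str] = field(default_factory=list)
    model: str = "membrane"

    @property
    def amplitude(self) -> float:
        """Zero-lag amplitude G(0) = 1/N."""
        return 1.0 / self.params.N


_MEMBRANE_FREE = ["N", "f_T", "tau_T", "f_3D", "tau_3D", "tau_2D"]
_SOLUTION_FREE = ["N", "tau_3D"]
_2D_FREE = ["N", "tau_2D"]


def fit_acf(
    curve: CorrelationCurve,
    model: str = "membrane",
    init: AcfModelParams | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    AR: float = 6.0,
) -> AcfFitResult:
    """Fit an autocorrelation curve with the membrane, solution, or 2D model.

    Free parameters are log-scaled internally for the time constants. The
    starting point is the geometric midpoint of each bound interval unless
    ``init`` is supplied, making the fit deterministic. Non-convergence and
    parameters pinned at a bound are flagged, never silently ignored.
    """
    if model not in ("membrane", "solution", "2d"):
        raise ValueError(f"unknown model '{model}'")
    b = dict(DEFAULT_BOUNDS)
    if model == "solution":
        # free-dye diffusion times (tens of µs) lie outside the membrane
        # constraint; the stated 100 µs – 3 ms window applies to the
        # supernatant component of membrane measurements only
        b["tau_3D"] = (1e-6, 1.0)
    if bounds:
        b.update(bounds)
    free = {"membrane": _MEMBRANE_FREE, "solution": _SOLUTION_FREE, "2d": _2D_FREE}[
        model
    ]
    log_scaled = {"N", "tau_T", "tau_3D", "tau_2D"}

    if init is None:
        g0 = max(curve.G[0], 1e-6)
        start = {
            "N": min(max(1.0 / g0, b["N"][0] * 1.01), b["N"][1] * 0.99),
            "f_T": 0.1,
            "tau_T": np.sqrt(b["tau_T"][0] * b["tau_T"][1]),
            "f_3D": 0.5,
            "tau_3D": np.sqrt(b["tau_3D"][0] * b["tau_3D"][1]),
            "tau_2D": np.sqrt(b["tau_2D"][0] * b["tau_2D"][1]),
        }
    else:
        start = {k: getattr(init, k) for k in _MEMBRANE_FREE}

    def pack(vals: dict) -> np.ndarray:
        return np.array(
            [np.log(vals[k]) if k in log_scaled else vals[k] for k in free]
        )

    def unpack(x: np.ndarray) -> dict:
        out = dict(start)
        for k, v in zip(free, x):
            out[k] = float(np.exp(v)) if k in log_scaled else float(v)
        return out

    lo = np.array(
        [np.log(b[k][0]) if k in log_scaled else b[k][0] for k in free]
    )
    hi = np.array(
        [np.log(b[k][1]) if k in log_scaled else b[k][1] for k in free]
    )
    x0 = np.clip(pack(start), lo + 1e-12, hi - 1e-12)

    def residuals(x: np.ndarray) -> np.ndarray:
        v = unpack(x)
        if model == "membrane":
            p = AcfModelParams(
                N=v["N"], f_T=min(v["f_T"], 0.999), tau_T=v["tau_T"],
                f_3D=v["f_3D"], tau_3D=v["tau_3D"], tau_2D=v["tau_2D"], AR=AR,
            )
            g = model_membrane_acf(curve.lags, p)
        elif model == "solution":
            g = model_solution_acf(curve.lags, v["N"], v["tau_3D"], AR)
        else:
            g = model_2d_acf(curve.lags, v["N"], v["tau_2D"])
        return g - curve.G

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    v = unpack(sol.x)
    fitted = AcfModelParams(
        N=v["N"], f_T=min(v["f_T"], 0.999), tau_T=v["tau_T"],
        f_3D=v["f_3D"] if model == "membrane" else 1.0,
        tau_3D=v["tau_3D"], tau_2D=v["tau_2D"], AR=AR,
    )
    at_bounds = [
        k
        for k, xv, l_, h_ in zip(free, sol.x, lo, hi)
        if xv - l_ < 1e-8 * max(abs(l_), 1) or h_ - xv < 1e-8 * max(abs(h_), 1)
    ]
    if at_bounds:
        warnings.warn(f"fit parameters at bounds: {at_bounds}", stacklevel=2)
    cpp = curve.mean_intensity / fitted.N
    return AcfFitResult(
        params=fitted,
        cpp=float(cpp),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=bool(sol.success),
        at_bounds=at_bounds,
        model=model,
    )


def fit_2d_amplitude(curve: CorrelationCurve) -> float:
    """Zero-lag amplitude of a curve fitted with the 2D diffusion model."""
    res = fit_acf(curve, model="2d")
    return res.amplitude


@dataclass
class FccsResult:
    """Corrected relative cross-correlation amplitude of a dual-color measurement."""

    rel_cc: float
    corrected: bool
    background_rates: dict[str, float]
    crosstalk_gr: float
    amplitudes: dict[str, float] = field(default_factory=dict)


def fccs_relative_amplitude(
    green: CorrelationCurve,
    red: CorrelationCurve,
    cross: CorrelationCurve,
    backgrounds: dict[str, float] | None = None,
    crosstalk_gr: float = 0.01,
    denominator: str = "red",
) -> FccsResult:
    """Background- and cross-talk-corrected relative cross-correlation amplitude.

    All three curves are fitted with the 2D membrane diffusion model; the
    zero-lag amplitudes are then corrected in two steps.

    Background: uncorrelated detector/room background B dilutes the mean
    intensity without correlating, so each autocorrelation amplitude is
    multiplied by (F/(F−B))² and the cross amplitude by the product of the two
    single-channel factors.

    Cross-talk: a fraction κ of the green fluorescence bleeds into the red
    channel. Writing the measured red signal as r' = r + κ·g, the spurious
    contribution is removed via

        G_x = (G_x'·F_g·F_r' − κ·G_g·F_g²) / (F_g·(F_r' − κ·F_g))
        G_r = (G_r'·F_r'² − 2κ·⟨δgδr⟩ − κ²·G_g·F_g²) / (F_r' − κ·F_g)²

    with ⟨δgδr⟩ the already-corrected covariance. These forms follow from
    substituting r' into the correlation definitions; they are validated
    against the particle-based simulator.

    ``denominator`` selects the autocorrelation the corrected cross amplitude
    is divided by. The default ``"red"`` makes rel_cc = N_gr/N_g, the fraction
    of the green (receptor) pool carrying a red label — the quantity that a
    click-efficiency or occupancy readout needs; ``"green"`` gives N_gr/N_r,
    the fraction of red particles co-diffusing with green.
    """
    if denominator not in ("red", "green"):
        raise ValueError("denominator must be 'red' or 'green'")
    bg = {"green": 0.0, "red": 0.0}
    if backgrounds:
        bg.update(backgrounds)
    f_g, f_r = green.mean_intensity, red.mean_intensity
    for ch, f in (("green", f_g), ("red", f_r)):
        if bg[ch] >= f:
            raise ValueError(f"background exceeds signal in {ch} channel")

    g_g = fit_2d_amplitude(green)
    g_r = fit_2d_amplitude(red)
    g_x = fit_acf(cross, model="2d").amplitude if np.any(cross.G > 0) else 0.0

    # background correction: amplitudes up, intensities down
    cf_g = f_g / (f_g - bg["green"])
    cf_r = f_r / (f_r - bg["red"])
    g_g *= cf_g**2
    g_r *= cf_r**2
    g_x *= cf_g * cf_r
    f_g -= bg["green"]
    f_r -= bg["red"]

    # cross-talk correction (green → red), on background-corrected quantities
    k = crosstalk_gr
    if k > 0:
        if f_r <= k * f_g:
            raise ValueError("red signal is entirely cross-talk")
        cov_gr = g_x * f_g * f_r - k * g_g * f_g**2  # ⟨δg δr⟩, true red
        f_r_true = f_r - k * f_g
        g_x = cov_gr / (f_g * f_r_true)
        var_r = g_r * f_r**2 - 2 * k * cov_gr - k**2 * g_g * f_g**2
        g_r = var_r / f_r_true**2
        f_r = f_r_true

    denom = g_r if denominator == "red" else g_g
    rel_cc = g_x / denom
    return FccsResult(
        rel_cc=float(rel_cc),
        corrected=True,
        background_rates=bg,
        crosstalk_gr=crosstalk_gr,
        amplitudes={"green": float(g_g), "red": float(g_r), "cross": float(g_x)},
    )
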