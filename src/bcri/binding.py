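"""Statistical models fitted to BCRI outputs.

Covers the Monte-Carlo Hill fit for titration curves (uncertainty on both the
free-ligand concentration and the bound fraction), labeling kinetics
(rising double exponential in time, two-state saturation in concentration),
Gaussian-mixture decomposition of single-cell occupancy distributions,
Welch's t-test, Monte-Carlo Pearson correlations, and differential click
efficiency with independent-error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares
from sklearn.mixture import GaussianMixture

__all__ = [
    "TitrationDataset",
    "HillFit",
    "KineticsFit",
    "MixtureFit",
    "CePattern",
    "hill_equation",
    "hill_fit_mc",
    "fit_double_exponential",
    "fit_two_state_saturation",
    "fit_occupancy_mixture",
    "welch_test",
    "pearson_mc",
    "differential_ce",
]


@dataclass(frozen=True)
class TitrationDataset:
    """Per-concentration binding points: (c ± σ_c, θ ± σ_θ, n_cells).

    Concentrations in mol/L; θ is the bound receptor fraction from BCRI.
    """

    c: np.ndarray
    sigma_c: np.ndarray
    theta: np.ndarray
    sigma_theta: np.ndarray
    n_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        sc = np.asarray(self.sigma_c, dtype=float)
        th = np.asarray(self.theta, dtype=float)
        st = np.asarray(self.sigma_theta, dtype=float)
        for name, arr in (("c", c), ("sigma_c", sc), ("theta", th), ("sigma_theta", st)):
            object.__setattr__(self, name, arr)
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(sc < 0) or np.any(st < 0):
            raise ValueError("uncertainties must be non-negative")
        if not (c.shape == sc.shape == th.shape == st.shape):
            raise ValueError("all point arrays must share a shape")
        if not np.all(np.isfinite(th)):
            raise ValueError("theta must be finite")

    def __len__(self) -> int:
        return self.c.size


@dataclass
class HillFit:
    """Monte-Carlo Hill fit result: per-parameter resample mean ± SD."""

    A: float
    A0: float
    c0: float  # mol/L
    n: float
    A_sd: float
    A0_sd: float
    c0_sd: float
    n_sd: float
    n_resamples: int
    n_failed: int
    flagged: bool
    base: dict = field(default_factory=dict)


def hill_equation(
    c: np.ndarray | float, A: float, A0: float, c0: float, n: float
) -> np.ndarray | float:
    """Hill binding isotherm θ(c) = A/(1+(c0/c)^n) + A0."""
    return A / (1.0 + (c0 / c) ** n) + A0


def _hill_base_fit(
    c: np.ndarray,
    theta: np.ndarray,
    fix_n: float | None,
    p0: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares Hill fit with c0 in log space; returns (A, A0, log_c0[, n])."""
    c0_init = float(np.exp(np.interp(0.5 * (theta.min() + theta.max()),
                                     np.sort(theta), np.log(np.sort(c)))))
    if p0 is None:
        p0 = np.array([theta.max() - theta.min(), max(theta.min(), 0.0),
                       np.log(c0_init)] + ([] if fix_n is not None else [1.0]))

    def resid(p: np.ndarray) -> np.ndarray:
        a, a0, log_c0 = p[0], p[1], p[2]
        n = fix_n if fix_n is not None else p[3]
        return hill_equation(c, a, a0, np.exp(log_c0), n) - theta

    lo = [-np.inf, -np.inf, np.log(c.min()) - 10]
    hi = [np.inf, np.inf, np.log(c.max()) + 10]
    if fix_n is None:
        lo.append(0.1)
        hi.append(10.0)
    sol = least_squares(resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    if not sol.success:
        raise RuntimeError("Hill base fit did not converge")
    return sol.x


def hill_fit_mc(
    data: TitrationDataset,
    fix_n: float | None = 1.0,
    n_resamples: int = 10_000,
    seed: int | None = None,
    perturb: str = "both",
) -> HillFit:
    """Monte-Carlo Hill fit with uncertainties on both axes.

    The base fit is a nonlinear least-squares fit of the Hill equation with
    the dissociation constant in log space. The fit is then repeated
    ``n_resamples`` times; each time zero-mean Gaussian perturbations of
    width σ_c and σ_θ are added to every point before refitting
    (``perturb``: "both" | "x" | "y"). Reported parameters are the mean ± SD
    over converged resamples. Perturbed concentrations are clipped at 1% of
    their unperturbed value to stay in the Hill equation's domain.

    ``fix_n=1.0`` (default) fits the 1:1 binding model; pass ``fix_n=None``
    to free the Hill coefficient (requires ≥4 points spanning c0).

    More than 20% failed resamples flags the result.
    """
    min_pts = 4 if fix_n is None else 3
    if len(data) < min_pts:
        raise ValueError(f"need at least {min_pts} titration points")
    if seed is None:
        raise ValueError("seed is required for the Monte-Carlo fit")
    rng = np.random.default_rng(seed)

    base = _hill_base_fit(data.c, data.theta, fix_n)
    draws = []
    failed = 0
    for _ in range(n_resamples):
        dc = rng.normal(0.0, data.sigma_c) if perturb in ("both", "x") else 0.0
        dth = rng.normal(0.0, data.sigma_theta) if perturb in ("both", "y") else 0.0
        c_p = np.maximum(data.c + dc, 0.01 * data.c)
        th_p = data.theta + dth
        try:
            draws.append(_hill_base_fit(c_p, th_p, fix_n, p0=base.copy()))
        except RuntimeError:
            failed += 1
    if not draws:
        raise RuntimeError("all Monte-Carlo resamples failed")
    arr = np.array(draws)
    mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=0)
    # back-transform log c0: report mean/SD of the resampled c0 values
    c0_draws = np.exp(arr[:, 2])
    n_val = fix_n if fix_n is not None else float(mean[3])
    n_sd = 0.0 if fix_n is not None else float(sd[3])
    flagged = failed > 0.2 * n_resamples
    if flagged:
        warnings.warn(f"{failed}/{n_resamples} Monte-Carlo resamples failed",
                      stacklevel=2)
    return HillFit(
        A=float(mean[0]), A0=float(mean[1]),
        c0=float(c0_draws.mean()), n=float(n_val),
        A_sd=float(sd[0]), A0_sd=float(sd[1]),
        c0_sd=float(c0_draws.std(ddof=0)), n_sd=n_sd,
        n_resamples=n_resamples, n_failed=failed, flagged=flagged,
        base={"A": float(base[0]), "A0": float(base[1]),
              "c0": float(np.exp(base[2])),
              "n": float(base[3]) if fix_n is None else float(fix_n)},
    )


@dataclass
class KineticsFit:
    """Parameters of a labeling-kinetics fit (time or concentration domain)."""

    params: dict
    residual_norm: float
    converged: bool
    flagged: bool = False
    flag_reason: str = ""


def _double_exp(t: np.ndarray, a1: float, k1: float, a2: float, k2: float) -> np.ndarray:
    return a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def fit_double_exponential(
    t: np.ndarray, ce: np.ndarray, seed: int = 0, n_starts: int = 20
) -> KineticsFit:
    """Rising double exponential CE(t) = A_f(1−e^{−k_f t}) + A_s(1−e^{−k_s t}).

    ``t`` in minutes, rates in min⁻¹. Multi-start bounded least squares with
    log-spaced rate initialisations; the faster rate is reported as k_fast.
    A rate separation k_fast/k_slow < 3 flags the fit as weakly identifiable.
    """
    t = np.asarray(t, dtype=float)
    ce = np.asarray(ce, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 time points")
    rng = np.random.default_rng(seed)
    span = ce.max() - ce.min()
    t_pos = t[t > 0]
    k_lo, k_hi = 0.01 / t_pos.max(), 100.0 / t_pos.min()
    best = None
    for i in range(n_starts):
        k1 = np.exp(rng.uniform(np.log(k_lo), np.log(k_hi)))
        k2 = np.exp(rng.uniform(np.log(k_lo), np.log(k_hi)))
        p0 = [max(span, 1e-6) * 0.7, max(k1, k2), max(span, 1e-6) * 0.3, min(k1, k2)]
        try:
            popt, _ = curve_fit(
                _double_exp, t, ce, p0=p0,
                bounds=([0, k_lo / 10, 0, k_lo / 10], [np.inf, k_hi * 10, np.inf, k_hi * 10]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rn = float(np.linalg.norm(_double_exp(t, *popt) - ce))
        if best is None or rn < best[1]:
            best = (popt, rn)
    if best is None:
        return KineticsFit(params={}, residual_norm=np.inf, converged=False,
                           flagged=True, flag_reason="no start converged")
    popt, rn = best
    a1, k1, a2, k2 = popt
    if k1 < k2:  # enforce k_fast ≥ k_slow
        a1, k1, a2, k2 = a2, k2, a1, k1
    flagged = k2 > 0 and k1 / k2 < 3
    return KineticsFit(
        params={"A_fast": float(a1), "k_fast": float(k1),
                "A_slow": float(a2), "k_slow": float(k2)},
        residual_norm=rn, converged=True, flagged=flagged,
        flag_reason="rate separation < 3×" if flagged else "",
    )


def _two_state(c: np.ndarray, b1: float, k1: float, b2: float, k2: float) -> np.ndarray:
    return b1 * c / (k1 + c) + b2 * c / (k2 + c)


def fit_two_state_saturation(c: np.ndarray, ce: np.ndarray, seed: int = 0,
                             n_starts: int = 20) -> KineticsFit:
    """Sublinear two-state saturation CE(c) = B1·c/(K1+c) + B2·c/(K2+c).

    Models click yield against tetrazine concentration where a fast-reacting
    surface-proximal compartment saturates before the bulk-fed one.
    """
    c = np.asarray(c, dtype=float)
    ce = np.asarray(ce, dtype=float)
    if c.size < 5:
        raise ValueError("need at least 5 concentrations")
    rng = np.random.default_rng(seed)
    k_lo, k_hi = c.min() / 100, c.max() * 100
    best = None
    for _ in range(n_starts):
        p0 = [ce.max() * 0.6, np.exp(rng.uniform(np.log(k_lo), np.log(k_hi))),
              ce.max() * 0.6, np.exp(rng.uniform(np.log(k_lo), np.log(k_hi)))]
        try:
            popt, _ = curve_fit(
                _two_state, c, ce, p0=p0,
                bounds=([0, k_lo / 10, 0, k_lo / 10],
                        [np.inf, k_hi * 10, np.inf, k_hi * 10]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        rn = float(np.linalg.norm(_two_state(c, *popt) - ce))
        if best is None or rn < best[1]:
            best = (popt, rn)
    if best is None:
        return KineticsFit(params={}, residual_norm=np.inf, converged=False,
                           flagged=True, flag_reason="no start converged")
    popt, rn = best
    b1, k1, b2, k2 = popt
    if k1 > k2:  # order by half-saturation constant
        b1, k1, b2, k2 = b2, k2, b1, k1
    at_bound = k2 >= k_hi * 9 or k1 <= k_lo / 9
    return KineticsFit(
        params={"B1": float(b1), "K1": float(k1), "B2": float(b2), "K2": float(k2)},
        residual_norm=rn, converged=True, flagged=at_bound,
        flag_reason="boundary solution" if at_bound else "",
    )


@dataclass
class MixtureFit:
    """Gaussian-mixture decomposition of a single-cell occupancy distribution."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    scores: dict  # AICc per candidate model
    log_likelihoods: dict


def _aicc(log_lik: float, k: int, n: int) -> float:
    aic = 2 * k - 2 * log_lik
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_occupancy_mixture(
    values: np.ndarray, k_max: int = 2, seed: int = 0, n_restarts: int = 10
) -> MixtureFit:
    """Fit 1- and 2-component Gaussian mixtures to per-cell occupancies.

    Bimodal occupancy distributions indicate two co-existing receptor states
    with different ligand affinity. Model choice is by small-sample-corrected
    AIC; the selected model and both scores are returned. Component SDs are
    floored at 1% of the data range to avoid collapse.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size < 20:
        raise ValueError("need at least 20 cells for a mixture decomposition")
    floor = (1e-2 * (x.max() - x.min())) ** 2
    scores, liks, fits = {}, {}, {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full",
            reg_covar=max(floor, 1e-10),
            n_init=n_restarts, random_state=seed,
        ).fit(x)
        if k > 1 and (k - 1) in liks and float(gm.score(x) * x.size) < liks[k - 1]:
            # EM stuck in a local optimum below the nested simpler model:
            # restart from the (k−1)-solution duplicated, which EM can only improve
            prev = fits[k - 1]
            seeded = GaussianMixture(
                n_components=k, covariance_type="full",
                reg_covar=max(floor, 1e-10),
                weights_init=np.full(k, 1.0 / k),
                means_init=np.repeat(prev.means_[:1], k, axis=0)
                + np.linspace(-1e-6, 1e-6, k)[:, None],
                precisions_init=np.repeat(prev.precisions_[:1], k, axis=0),
                random_state=seed,
            ).fit(x)
            if seeded.score(x) > gm.score(x):
                gm = seeded
        ll = float(gm.score(x) * x.size)
        n_params = 3 * k - 1
        scores[k] = _aicc(ll, n_params, x.size)
        liks[k] = ll
        fits[k] = gm
    best_k = min(scores, key=scores.get)
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    return MixtureFit(
        n_components=best_k,
        weights=gm.weights_[order],
        means=gm.means_.ravel()[order],
        sds=np.sqrt(gm.covariances_.reshape(-1)[order]),
        scores=scores,
        log_likelihoods=liks,
    )


def welch_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided Welch's t-test (unequal variances and sample sizes).

    Returns t, the Welch–Satterthwaite degrees of freedom, and the two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    dof = (se2a + se2b) ** 2 / (
        se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1)
    )
    return {"t": float(res.statistic), "dof": float(dof), "p": float(res.pvalue)}


def pearson_mc(
    x: np.ndarray,
    y: np.ndarray,
    sigma_x: np.ndarray | float = 0.0,
    sigma_y: np.ndarray | float = 0.0,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Pearson correlation with Monte-Carlo propagation of point uncertainties.

    Computes plain r and two-tailed p on the unperturbed data, then repeats
    the calculation ``n_resamples`` times with zero-mean Gaussian noise of
    width σ_x/σ_y added to each point, reporting the resample mean ± SD of
    both r and p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if seed is None:
        raise ValueError("seed is required for the Monte-Carlo resampling")
    rng = np.random.default_rng(seed)
    sx = np.broadcast_to(np.asarray(sigma_x, dtype=float), x.shape)
    sy = np.broadcast_to(np.asarray(sigma_y, dtype=float), y.shape)
    r0, p0 = stats.pearsonr(x, y)
    rs = np.empty(n_resamples)
    ps = np.empty(n_resamples)
    for i in range(n_resamples):
        xi = x + rng.normal(0.0, sx)
        yi = y + rng.normal(0.0, sy)
        if np.ptp(xi) == 0 or np.ptp(yi) == 0:
            rs[i], ps[i] = 0.0, 1.0
            continue
        rs[i], ps[i] = stats.pearsonr(xi, yi)
    return {
        "r": float(r0), "p": float(p0),
        "r_mc": float(rs.mean()), "r_mc_sd": float(rs.std(ddof=0)),
        "p_mc": float(ps.mean()), "p_mc_sd": float(ps.std(ddof=0)),
        "n_resamples": n_resamples,
    }


@dataclass(frozen=True)
class CePattern:
    """Per-site click efficiencies under the free and ligand-occupied state.

    ``sites[label] = {"free": (mean, sem, n), "occupied": (mean, sem, n)}``.
    """

    sites: dict


def differential_ce(pattern: CePattern, rmsd: dict | None = None) -> dict:
    """Per-site differential click efficiency ΔCE = CE_occ − CE_free.

    SEMs propagate assuming independence: SEM_Δ = sqrt(SEM_occ² + SEM_free²).
    Sites missing either condition are skipped with a warning. When an RMSD
    profile is supplied, the secondary-axis scaling factor that equates the
    average spread (SD across sites) of |ΔCE| and RMSD is returned too.
    """
    out = {}
    for site, conds in pattern.sites.items():
        if "free" not in conds or "occupied" not in conds:
            warnings.warn(f"site {site}: missing condition, skipped", stacklevel=2)
            continue
        m_occ, s_occ = conds["occupied"][0], conds["occupied"][1]
        m_free, s_free = conds["free"][0], conds["free"][1]
        d = m_occ - m_free
        out[site] = {
            "delta_ce": d,
            "sem": float(np.hypot(s_occ, s_free)),
            "abs_delta_ce": abs(d),
        }
    result = {"sites": out}
    if rmsd is not None:
        common = sorted(set(out) & set(rmsd))
        if len(common) >= 2:
            dce = np.array([out[s]["abs_delta_ce"] for s in common])
            rm = np.array([rmsd[s] for s in common])
            result["axis_scale"] = float(dce.std(ddof=0) / rm.std(ddof=0)) \
                if rm.std(ddof=0) > 0 else np.nan
    return result
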