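"""Thioflavin-T competition binding model: equilibria and titration fits.

Thioflavin T (ThT) fluoresces weakly free in solution and strongly when bound
to amyloid fibrils, so displacement of fibril-bound ThT by a nonfluorescent
competitor L reads out the competitor's affinity. The model distinguishes two
site classes on the fibril: S1 binds both ThT and L, S2 binds only ThT, and
ThT is assumed to bind both with the same dissociation constant Kd(ThT).

Species obey mass action and mass balance:

    [ThT.Sn] = [ThT][Sn] / Kd(ThT)          (n = 1, 2)
    [L.S1]   = [L][S1] / Kd(L)
    [ThT]tot = [ThT] + [ThT.S1] + [ThT.S2]
    [L]tot   = [L] + [L.S1]
    S1tot    = [S1] + [ThT.S1] + [L.S1]
    S2tot    = [S2] + [ThT.S2]

and the fluorescence intensity is

    I = eps_f*phi_f*[ThT] + eps_b*phi_b*([ThT.S1] + [ThT.S2]).

The coupled system reduces analytically to a single monotone scalar equation
in free ThT: given [ThT], the L balance is a quadratic in [L] with one
nonnegative root, and the remaining ThT balance brackets a sign change on
[0, [ThT]tot], solved here by Brent's method at machine precision. Because
ThT binds S1 and S2 with a shared Kd, a direct titration (no competitor)
collapses exactly to a one-site isotherm in the *total* site concentration
S1tot + S2tot; the S1/S2 split is identified only by the competition phase
(the depth of the displacement plateau), which is why the direct-phase fit
takes the split as a parameter and the competition fit can optionally float
it.

A three-phase experiment is supported: (i) a ThT dilution series without
fibrils fixes the free-ThT response eps_f*phi_f; (ii) a direct ThT titration
into fibrils fits eps_b*phi_b, Kd(ThT) and the total site concentration;
(iii) a competitor titration at fixed ThT fits Kd(L). Kd values are fitted
in log10 space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Relative residual tolerance required of a solved equilibrium state.
SOLVER_RTOL = 1e-12

#: Default excitation/emission wavelengths recorded as titration metadata (nm).
DEFAULT_WAVELENGTHS = {"lambda_ex_nm": 440.0, "lambda_em_nm": 483.0}

TITRATION_COLUMNS = ("phase", "tht_tot_M", "l_tot_M", "fibril_conc_M",
                     "intensity_au", "replicate_id")


class EquilibriumError(RuntimeError):
    """Solver failed to meet the residual tolerance; carries diagnostics."""

    def __init__(self, msg, residuals=None, inputs=None):
        super().__init__(msg)
        self.residuals = residuals
        self.inputs = inputs


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the two-site ThT/competitor model (all concentrations molar).

    eps_f_phi_f / eps_b_phi_b are fluorescence responses (intensity per molar)
    of free and fibril-bound ThT; kd_tht is shared by sites S1 and S2; kd_l
    applies to the competitor at S1 only.
    """

    eps_f_phi_f: float
    eps_b_phi_b: float
    kd_tht: float
    kd_l: float
    s1_tot: float
    s2_tot: float

    def __post_init__(self):
        for name in ("eps_f_phi_f", "eps_b_phi_b", "s1_tot", "s2_tot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("kd_tht", "kd_l"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound species concentrations (molar) satisfying the model."""

    tht_free: float
    l_free: float
    s1_free: float
    s2_free: float
    tht_s1: float
    tht_s2: float
    l_s1: float
    residuals: dict = field(default_factory=dict, compare=False)

    @property
    def tht_bound(self) -> float:
        return self.tht_s1 + self.tht_s2


def one_site_bound(total_ligand: float, total_sites: float, kd: float) -> float:
    """Closed-form bound concentration for a single 1:1 equilibrium.

    Root of b**2 - b*(T + S + K) + T*S = 0 in [0, min(T, S)], evaluated in the
    numerically stable form 2TS / (q + sqrt(q^2 - 4TS)), q = T + S + K.
    """
    t, s, k = float(total_ligand), float(total_sites), float(kd)
    if t == 0.0 or s == 0.0:
        return 0.0
    q = t + s + k
    disc = q * q - 4.0 * t * s
    return 2.0 * t * s / (q + math.sqrt(max(disc, 0.0)))


def _free_l_given_free_tht(tht_free: float, l_tot: float, p: BindingParams) -> float:
    """Closed-form free [L] from the L and S1 balances at fixed free [ThT].

    Eliminating [S1] gives L^2 + L*(s1_tot + Kl*a - l_tot) - Kl*a*l_tot = 0
    with a = 1 + [ThT]/Kd(ThT); the nonnegative root is returned.
    """
    if l_tot == 0.0:
        return 0.0
    a = 1.0 + tht_free / p.kd_tht
    b = p.s1_tot + p.kd_l * a - l_tot
    disc = b * b + 4.0 * p.kd_l * a * l_tot
    sq = math.sqrt(disc)
    if b >= 0.0:
        return 2.0 * p.kd_l * a * l_tot / (b + sq)
    return 0.5 * (-b + sq)


def _state_from_free_tht(tht_free: float, l_tot: float, p: BindingParams,
                         tht_tot: float) -> EquilibriumState:
    a = 1.0 + tht_free / p.kd_tht
    l_free = _free_l_given_free_tht(tht_free, l_tot, p)
    s1_free = p.s1_tot / (a + l_free / p.kd_l)
    s2_free = p.s2_tot / a
    tht_s1 = tht_free * s1_free / p.kd_tht
    tht_s2 = tht_free * s2_free / p.kd_tht
    l_s1 = l_free * s1_free / p.kd_l
    tiny = 1e-300
    residuals = {
        "tht": abs(tht_tot - (tht_free + tht_s1 + tht_s2)) / max(tht_tot, tiny),
        "l": abs(l_tot - (l_free + l_s1)) / max(l_tot, tiny),
        "s1": abs(p.s1_tot - (s1_free + tht_s1 + l_s1)) / max(p.s1_tot, tiny),
        "s2": abs(p.s2_tot - (s2_free + tht_s2)) / max(p.s2_tot, tiny),
    }
    return EquilibriumState(tht_free=tht_free, l_free=l_free, s1_free=s1_free,
                            s2_free=s2_free, tht_s1=tht_s1, tht_s2=tht_s2,
                            l_s1=l_s1, residuals=residuals)


def solve_equilibrium(tht_tot: float, l_tot: float, params: BindingParams,
                      rtol: float = SOLVER_RTOL) -> EquilibriumState:
    """Solve the coupled two-site equilibria for given totals.

    The ThT balance as a function of free ThT changes sign on [0, tht_tot], so
    Brent's method is guaranteed a bracket; the inner L balance is closed-form.
    Raises :class:`EquilibriumError` if residuals exceed ``rtol``.
    """
    if tht_tot < 0 or l_tot < 0:
        raise ValueError("total concentrations must be nonnegative")
    if tht_tot == 0.0:
        state = _state_from_free_tht(0.0, l_tot, params, tht_tot)
    else:
        def f(t):
            a = 1.0 + t / params.kd_tht
            l_free = _free_l_given_free_tht(t, l_tot, params)
            s1f = params.s1_tot / (a + l_free / params.kd_l)
            s2f = params.s2_tot / a
            return t * (1.0 + s1f / params.kd_tht + s2f / params.kd_tht) - tht_tot

        t_root = optimize.brentq(f, 0.0, tht_tot, xtol=tht_tot * 1e-18 + 1e-300,
                                 rtol=8.881784197001252e-16, maxiter=300)
        state = _state_from_free_tht(t_root, l_tot, params, tht_tot)
    worst = max(state.residuals.values())
    if worst > rtol:
        raise EquilibriumError(
            f"equilibrium residual {worst:.3e} exceeds tolerance {rtol:.1e}",
            residuals=state.residuals,
            inputs={"tht_tot": tht_tot, "l_tot": l_tot, "params": params})
    return state


def predict_intensity(state: EquilibriumState, params: BindingParams) -> float:
    """Fluorescence intensity of a solved state: free + bound ThT responses."""
    return (params.eps_f_phi_f * state.tht_free
            + params.eps_b_phi_b * (state.tht_s1 + state.tht_s2))


def simulate_intensities(tht_tot: np.ndarray, l_tot: np.ndarray,
                         params: BindingParams) -> np.ndarray:
    """Vector convenience: intensity at each (tht_tot, l_tot) pair."""
    return np.array([predict_intensity(solve_equilibrium(t, l, params), params)
                     for t, l in zip(np.atleast_1d(tht_tot), np.atleast_1d(l_tot))])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a titration fit.

    ``stderr``/``ci95`` hold per-parameter uncertainties: across-replicate
    dispersion when ≥3 replicate curves were fitted, otherwise the asymptotic
    (covariance-based) estimate, labelled by ``uncertainty_kind``.
    """

    params: BindingParams
    fitted: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    residual_norm: float = math.nan
    converged: bool = False
    flags: list[str] = field(default_factory=list)
    uncertainty_kind: str = "asymptotic"
    replicate_fits: list["FitResult"] = field(default_factory=list)


def fit_dilution(points: pd.DataFrame) -> float:
    """Slope of intensity vs total ThT through the origin (free-ThT response).

    Uses dilution-phase rows (no fibrils). Least squares with zero intercept.
    """
    pts = points[points["phase"] == "dilution"] if "phase" in points else points
    t = pts["tht_tot_M"].to_numpy(dtype=float)
    i = pts["intensity_au"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("dilution fit needs at least 2 points")
    denom = float(np.dot(t, t))
    if denom == 0.0:
        raise ValueError("singular dilution design: all ThT totals are zero")
    return float(np.dot(t, i) / denom)


def _direct_model(tht_tot: np.ndarray, eps_f: float, eps_b: float,
                  kd_tht: float, s_tot: float) -> np.ndarray:
    """Direct-phase intensity; exact one-site closed form in S1tot + S2tot."""
    bound = np.array([one_site_bound(t, s_tot, kd_tht) for t in tht_tot])
    return eps_f * (tht_tot - bound) + eps_b * bound


def fit_direct_titration(points: pd.DataFrame, eps_f_phi_f: float,
                         site1_fraction: float = 0.5,
                         kd_l_placeholder: float = 1e-7) -> FitResult:
    """Fit eps_b*phi_b, Kd(ThT) and total site concentration to a direct
    ThT-into-fibrils titration.

    The shared-Kd assumption makes the direct phase exactly a one-site
    isotherm in S1tot + S2tot; the fitted total is split according to
    ``site1_fraction`` (refine with :func:`fit_competition_titration` with
    ``float_split=True`` if the split is of interest). Multi-start nonlinear
    least squares over log-spaced Kd(ThT) initializations; parameters are
    fitted in log10 space.
    """
    pts = points[points["phase"] == "direct"] if "phase" in points else points
    t = pts["tht_tot_M"].to_numpy(dtype=float)
    i = pts["intensity_au"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("direct-titration fit needs at least 3 points")
    scale = float(np.max(np.abs(i)))
    if scale == 0.0 or np.max(i) <= eps_f_phi_f * np.max(t) * 1.001:
        flags = ["degenerate: no bound-state signal"]
        params = BindingParams(eps_f_phi_f, 0.0, 1e-6, kd_l_placeholder, 0.0, 0.0)
        return FitResult(params=params, fitted={"eps_b_phi_b": 0.0},
                         residual_norm=float(np.linalg.norm(i - eps_f_phi_f * t)),
                         converged=True, flags=flags)

    tmax = float(np.max(t[t > 0])) if np.any(t > 0) else 1e-6

    def resid(theta):
        eps_b, kd, s = 10.0 ** np.clip(theta, -150.0, 150.0)
        return (_direct_model(t, eps_f_phi_f, eps_b, kd, s) - i) / scale

    eps_b0 = max((np.max(i) - eps_f_phi_f * tmax) / (0.25 * tmax), eps_f_phi_f)
    best = None
    for lk0, ls0 in product((-7.5, -6.5, -5.5, -4.5),
                            (math.log10(0.1 * tmax), math.log10(0.5 * tmax))):
        theta0 = np.array([math.log10(eps_b0), lk0, ls0])
        try:
            sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-14,
                                         ftol=1e-14, max_nfev=4000)
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("direct-titration fit failed from every start")
    eps_b, kd_tht, s_tot = 10.0 ** best.x
    params = BindingParams(eps_f_phi_f=eps_f_phi_f, eps_b_phi_b=eps_b,
                           kd_tht=kd_tht, kd_l=kd_l_placeholder,
                           s1_tot=site1_fraction * s_tot,
                           s2_tot=(1.0 - site1_fraction) * s_tot)
    stderr = _asymptotic_stderr(best)
    names = ["log10_eps_b_phi_b", "log10_kd_tht", "log10_s_tot"]
    return FitResult(
        params=params,
        fitted={"eps_b_phi_b": eps_b, "log10_kd_tht": math.log10(kd_tht),
                "s_tot": s_tot, "s1_tot": params.s1_tot, "s2_tot": params.s2_tot},
        stderr=dict(zip(names, stderr)),
        residual_norm=float(np.linalg.norm(best.fun * scale)),
        converged=bool(best.success), uncertainty_kind="asymptotic")


def _asymptotic_stderr(sol) -> np.ndarray:
    """Covariance-based parameter SDs from a least_squares solution."""
    m, n = sol.jac.shape
    if m <= n:
        return np.full(n, np.nan)
    dof = m - n
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def fit_competition_titration(points: pd.DataFrame, phase1: BindingParams,
                              float_split: bool = False) -> FitResult:
    """Fit Kd(L) to a competitor titration at fixed total ThT.

    All phase-1 parameters (responses, Kd(ThT), site totals) stay fixed; the
    search is one-dimensional over log10 Kd(L). With ``float_split=True`` the
    S1 share of the (fixed) total site concentration is fitted jointly with
    Kd(L) — the depth of the displacement plateau identifies it. A flat
    response (no displacement) is flagged as unidentifiable.
    """
    pts = points[points["phase"] == "competition"] if "phase" in points else points
    lt = pts["l_tot_M"].to_numpy(dtype=float)
    tt = pts["tht_tot_M"].to_numpy(dtype=float)
    i = pts["intensity_au"].to_numpy(dtype=float)
    if len(lt) < 2:
        raise ValueError("competition fit needs at least 2 points")
    scale = float(np.max(np.abs(i))) or 1.0
    s_tot = phase1.s1_tot + phase1.s2_tot

    def model(log_kd_l, split):
        p = replace(phase1, kd_l=10.0 ** float(log_kd_l),
                    s1_tot=split * s_tot, s2_tot=(1.0 - split) * s_tot)
        return simulate_intensities(tt, lt, p)

    split0 = phase1.s1_tot / s_tot if s_tot > 0 else 0.5

    if float_split:
        def resid(theta):
            split = 1.0 / (1.0 + math.exp(-theta[1]))  # logistic keeps (0,1)
            return (model(theta[0], split) - i) / scale

        best = None
        for lk0 in (-9.0, -7.5, -6.0):
            sol = optimize.least_squares(resid, np.array([lk0, 0.0]),
                                         xtol=1e-13, ftol=1e-13, max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        log_kd_l = float(best.x[0])
        split = 1.0 / (1.0 + math.exp(-best.x[1]))
        resid_norm = float(np.linalg.norm(best.fun * scale))
        converged = bool(best.success)
        stderr = dict(zip(["log10_kd_l", "logit_split"], _asymptotic_stderr(best)))
    else:
        def sse(log_kd_l):
            return float(np.sum((model(log_kd_l, split0) - i) ** 2)) / scale ** 2

        res = optimize.minimize_scalar(sse, bounds=(-12.0, -3.0),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        log_kd_l = float(res.x)
        split = split0
        resid_norm = math.sqrt(res.fun) * scale
        converged = bool(res.success)
        # curvature-based asymptotic SD for the 1-D fit
        h = 1e-4
        curv = (sse(log_kd_l + h) - 2 * res.fun + sse(log_kd_l - h)) / h ** 2
        dof = max(len(i) - 1, 1)
        s2 = res.fun / dof
        stderr = {"log10_kd_l": math.sqrt(2 * s2 / curv) if curv > 0 else math.nan}

    flags = []
    pred = model(log_kd_l, split)
    dyn = float(np.max(pred) - np.min(pred))
    if dyn < 0.01 * scale:
        flags.append("unidentifiable: flat response (no measurable displacement)")
    params = replace(phase1, kd_l=10.0 ** log_kd_l,
                     s1_tot=split * s_tot, s2_tot=(1.0 - split) * s_tot)
    return FitResult(params=params,
                     fitted={"log10_kd_l": log_kd_l, "site1_fraction": split},
                     stderr=stderr, residual_norm=resid_norm,
                     converged=converged, flags=flags,
                     uncertainty_kind="asymptotic")


def fit_two_phase(points: pd.DataFrame, site1_fraction: float = 0.5,
                  float_split: bool = False) -> FitResult:
    """Convenience pipeline over a three-phase table: dilution → direct →
    competition. Returns the competition-phase result (its ``params`` carry
    all fitted quantities)."""
    eps_f = max(fit_dilution(points), 0.0)  # response is physically nonnegative
    direct = fit_direct_titration(points, eps_f, site1_fraction=site1_fraction)
    if "degenerate: no bound-state signal" in direct.flags:
        return direct
    comp = fit_competition_titration(points, direct.params, float_split=float_split)
    comp.fitted.update({k: v for k, v in direct.fitted.items() if k not in comp.fitted})
    comp.fitted["eps_f_phi_f"] = eps_f
    return comp


def fit_replicates(points: pd.DataFrame, site1_fraction: float = 0.5,
                   float_split: bool = False) -> FitResult:
    """Fit each replicate curve independently and report the mean with a 95%
    confidence interval from the across-replicate dispersion (t-based). With
    fewer than 3 replicates the single-fit asymptotic uncertainty is kept."""
    groups = [g for _, g in points.groupby("replicate_id")] if "replicate_id" in points else [points]
    fits = [fit_two_phase(g, site1_fraction=site1_fraction, float_split=float_split)
            for g in groups]
    if len(fits) < 3:
        result = fits[0]
        result.replicate_fits = fits
        return result
    vals = np.array([f.fitted["log10_kd_l"] for f in fits])
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    sem = sd / math.sqrt(len(vals))
    tcrit = stats.t.ppf(0.975, len(vals) - 1)
    result = FitResult(
        params=replace(fits[0].params, kd_l=10.0 ** mean),
        fitted={"log10_kd_l": mean},
        stderr={"log10_kd_l": sem},
        ci95={"log10_kd_l": (mean - tcrit * sem, mean + tcrit * sem)},
        residual_norm=float(np.mean([f.residual_norm for f in fits])),
        converged=all(f.converged for f in fits),
        flags=sorted({fl for f in fits for fl in f.flags}),
        uncertainty_kind="replicate-dispersion",
        replicate_fits=fits)
    return result


def fit_global(points: pd.DataFrame, site1_fraction: float = 0.5) -> FitResult:
    """Joint fit of the direct and competition phases.

    The two phases share eps_b*phi_b, Kd(ThT) and the site totals, so fitting
    them together propagates no phase-1 point estimate into the Kd(L)
    estimate; uncertainty in the shared parameters is absorbed jointly. The
    sequential two-step protocol (:func:`fit_direct_titration` then
    :func:`fit_competition_titration`) is kept as the classical analysis
    path and seeds this fit's initialization.

    Free parameters (all in log10): eps_b*phi_b, Kd(ThT), total sites, Kd(L);
    eps_f*phi_f comes from the dilution phase and the S1 share of sites is
    fixed at ``site1_fraction``.
    """
    eps_f = max(fit_dilution(points), 0.0)
    d = points[points["phase"] == "direct"]
    c = points[points["phase"] == "competition"]
    td, i_d = d["tht_tot_M"].to_numpy(float), d["intensity_au"].to_numpy(float)
    tc = c["tht_tot_M"].to_numpy(float)
    lc = c["l_tot_M"].to_numpy(float)
    i_c = c["intensity_au"].to_numpy(float)
    scale = float(np.max(np.abs(np.concatenate([i_d, i_c])))) or 1.0

    def resid(theta):
        eps_b, kt, s, kl = 10.0 ** np.clip(theta, -150.0, 150.0)
        p = BindingParams(eps_f, eps_b, kt, kl,
                          site1_fraction * s, (1.0 - site1_fraction) * s)
        r1 = _direct_model(td, eps_f, eps_b, kt, s) - i_d
        r2 = simulate_intensities(tc, lc, p) - i_c
        return np.concatenate([r1, r2]) / scale

    seq = fit_two_phase(points, site1_fraction=site1_fraction)
    if "degenerate: no bound-state signal" in seq.flags:
        return seq
    theta0 = np.array([
        math.log10(max(seq.params.eps_b_phi_b, 1e-30)),
        math.log10(seq.params.kd_tht),
        math.log10(max(seq.params.s1_tot + seq.params.s2_tot, 1e-30)),
        math.log10(seq.params.kd_l),
    ])
    sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-14,
                                 ftol=1e-14, max_nfev=5000)
    eps_b, kd_tht, s_tot, kd_l = 10.0 ** sol.x
    params = BindingParams(eps_f, eps_b, kd_tht, kd_l,
                           site1_fraction * s_tot, (1.0 - site1_fraction) * s_tot)
    names = ["log10_eps_b_phi_b", "log10_kd_tht", "log10_s_tot", "log10_kd_l"]
    return FitResult(
        params=params,
        fitted={"eps_f_phi_f": eps_f, "eps_b_phi_b": eps_b,
                "log10_kd_tht": math.log10(kd_tht), "s_tot": s_tot,
                "log10_kd_l": math.log10(kd_l)},
        stderr=dict(zip(names, _asymptotic_stderr(sol))),
        residual_norm=float(np.linalg.norm(sol.fun * scale)),
        converged=bool(sol.success), flags=list(seq.flags),
        uncertainty_kind="asymptotic")


def displacement_fraction(params: BindingParams, tht_tot: float) -> float:
    """Fraction of fibril-bound ThT displaced by a saturating competitor.

    At [L] → ∞ site S1 is fully occupied by L, so bound ThT tends to the
    one-site isotherm in S2 alone (exact limit, no large-L solve needed).
    """
    base = solve_equilibrium(tht_tot, 0.0, params).tht_bound
    if base == 0.0:
        return 0.0
    limit = one_site_bound(tht_tot, params.s2_tot, params.kd_tht)
    return 1.0 - limit / base
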