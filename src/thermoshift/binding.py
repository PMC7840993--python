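"""Equilibrium binding analysis of dTm titrations.

The ligand-induced stabilization dTm as a function of total ligand
(dsDNA duplex) concentration [D] is described by the ligand-depletion
(quadratic) isotherm::

    dTm([D]) = ((dTmax + [D] + K_D) - sqrt((dTmax + [D] + K_D)^2
               - 4 * dTmax * [D])) / 2

with dTmax the saturating shift and K_D the apparent dissociation
constant.  The form mixes a temperature (dTmax, degC) with
concentrations, so the fitted K_D depends on the concentration unit:
this module fixes **micromolar** as the fitting unit.  With [D] and
K_D in uM the published NF-kB parameters reproduce the observed
1-3 degC shifts at 10 uM dsDNA; on a molar scale the same parameters
would predict ~1e-5 degC.  The unit convention is recorded on every
result.

``site_multiplicity`` rescales [D] for duplexes carrying more than one
equivalent binding site (a 2-site duplex at 10 uM is 20 uM of sites);
the default 1 fits on duplex concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from thermoshift.errors import DegenerateFitError, ValidationError

__all__ = [
    "BindingSeries",
    "BindingFitResult",
    "predict_delta_tm",
    "fit_binding",
    "bootstrap_ci",
    "bootstrap_group_ci",
]


@dataclass
class BindingSeries:
    """dTm observations across a ligand titration (concentrations in uM)."""

    ligand_concs: np.ndarray
    delta_tms: np.ndarray
    site_multiplicity: int = 1
    probe: str = ""
    ligand: str = ""

    def __post_init__(self) -> None:
        self.ligand_concs = np.asarray(self.ligand_concs, dtype=float)
        self.delta_tms = np.asarray(self.delta_tms, dtype=float)
        if self.ligand_concs.shape != self.delta_tms.shape:
            raise ValidationError("ligand_concs and delta_tms must have equal length")
        if self.ligand_concs.size < 3:
            raise ValidationError("need at least 3 titration points")
        if np.any(self.ligand_concs < 0):
            raise ValidationError("ligand concentrations must be >= 0")
        if np.unique(self.ligand_concs).size < 2:
            raise ValidationError("need at least two distinct ligand concentrations")
        if self.site_multiplicity < 1:
            raise ValidationError("site_multiplicity must be a positive integer")

    @property
    def effective_concs(self) -> np.ndarray:
        return self.ligand_concs * self.site_multiplicity


@dataclass
class BindingFitResult:
    delta_t_max: float
    kd: float
    sse: float
    converged: bool
    n_points: int
    conc_unit: str = "uM"
    site_multiplicity: int = 1
    ci_delta_t_max: tuple[float, float] | None = None
    ci_kd: tuple[float, float] | None = None
    message: str = ""
    residuals: np.ndarray | None = field(default=None, repr=False)


def predict_delta_tm(delta_t_max: float, kd: float, d) -> float | np.ndarray:
    """Evaluate the ligand-depletion equation at total ligand
    concentration ``d`` (same unit as ``kd``; uM by convention).

    Algebraically 0 <= dTm <= dTmax for all d >= 0: the radicand equals
    (d + K_D - dTmax)^2 + 4*K_D*dTmax and is never negative.
    """
    if delta_t_max <= 0:
        raise ValidationError("delta_t_max must be > 0")
    if kd < 0:
        raise ValidationError("kd must be >= 0")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValidationError("ligand concentration must be >= 0")
    s = delta_t_max + d_arr + kd
    radicand = s * s - 4.0 * delta_t_max * d_arr
    if np.any(radicand < -1e-9):
        raise FloatingPointError("negative radicand in ligand-depletion equation")
    value = 0.5 * (s - np.sqrt(np.maximum(radicand, 0.0)))
    return float(value) if np.isscalar(d) else value


def _default_init(series: BindingSeries) -> tuple[float, float]:
    dtm = series.delta_tms
    concs = series.effective_concs
    a0 = float(dtm.max())
    if a0 <= 0:
        a0 = 1e-3
    half = 0.5 * a0
    kd0 = float(concs[np.argmin(np.abs(dtm - half))])
    if kd0 <= 0:
        kd0 = float(np.median(concs[concs > 0])) if np.any(concs > 0) else 1.0
    return a0, kd0


def fit_binding(
    series: BindingSeries,
    init: tuple[float, float] | None = None,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> BindingFitResult:
    """Unweighted least-squares fit of (dTmax, K_D) to a titration.

    Default start values: dTmax = max(dTm), K_D = concentration nearest
    the half-maximal shift.  Both parameters are bounded positive.
    """
    concs = series.effective_concs
    dtm = series.delta_tms
    if np.allclose(dtm, 0.0):
        raise DegenerateFitError("all dTm values are zero; nothing to fit")
    p0 = init if init is not None else _default_init(series)
    lob, upb = bounds if bounds is not None else ((1e-9, 1e-9), (np.inf, np.inf))

    def model(d, a, k):
        return predict_delta_tm(a, k, d)

    try:
        popt, _ = curve_fit(model, concs, dtm, p0=p0, bounds=(lob, upb), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return BindingFitResult(
            delta_t_max=float(p0[0]),
            kd=float(p0[1]),
            sse=float(np.sum((dtm - model(concs, *p0)) ** 2)),
            converged=False,
            n_points=concs.size,
            site_multiplicity=series.site_multiplicity,
            message=f"fit did not converge: {exc}",
        )
    resid = dtm - model(concs, *popt)
    return BindingFitResult(
        delta_t_max=float(popt[0]),
        kd=float(popt[1]),
        sse=float(np.sum(resid**2)),
        converged=True,
        n_points=concs.size,
        site_multiplicity=series.site_multiplicity,
        residuals=resid,
    )


def _bca_interval(draws: np.ndarray, theta_hat: float, jackknife: np.ndarray,
                  alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected and accelerated (BCa) bootstrap interval.

    Plain percentile intervals undercover for small-n nonlinear fits
    with correlated parameters; BCa corrects both the median bias of
    the bootstrap distribution and its skew.
    """
    z0 = norm.ppf(np.clip(np.mean(draws < theta_hat), 1e-6, 1.0 - 1e-6))
    jm = jackknife.mean()
    num = np.sum((jm - jackknife) ** 3)
    den = 6.0 * np.sum((jm - jackknife) ** 2) ** 1.5
    accel = num / den if den > 0 else 0.0
    z = norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])
    adjusted = norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z)))
    lo, hi = np.percentile(draws, 100.0 * adjusted)
    return float(lo), float(hi)


def _refit(series: BindingSeries, values: np.ndarray, p0: tuple[float, float],
           concs: np.ndarray | None = None) -> tuple[float, float]:
    try:
        sub = BindingSeries(
            ligand_concs=concs if concs is not None else series.ligand_concs,
            delta_tms=values,
            site_multiplicity=series.site_multiplicity,
        )
        boot_fit = fit_binding(sub, init=p0)
        if boot_fit.converged:
            return boot_fit.delta_t_max, boot_fit.kd
    except (DegenerateFitError, ValidationError):
        pass
    return p0


def bootstrap_ci(
    series: BindingSeries,
    fit: BindingFitResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> BindingFitResult:
    """Residual-resampling bootstrap 95% BCa intervals for (dTmax, K_D).
    Deterministic given ``seed``.

    Nonlinear small-n fits have unreliable linearized standard errors,
    so the bootstrap is the default uncertainty here.  Residuals are
    rescaled by sqrt(n/(n-p)) before resampling (fitted residuals are
    variance-shrunk by the p=2 estimated parameters) and the intervals
    are bias-corrected and accelerated, with the acceleration estimated
    by jackknifing the titration points.
    """
    if not fit.converged:
        raise ValidationError("bootstrap requires a converged fit")
    if series.ligand_concs.size < 4:
        raise ValidationError("bootstrap needs at least 4 titration points")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    concs = series.effective_concs
    fitted = np.asarray(predict_delta_tm(fit.delta_t_max, fit.kd, concs))
    residuals = series.delta_tms - fitted
    n = residuals.size
    residuals = residuals * math.sqrt(n / max(n - 2, 1))
    rng = np.random.default_rng(seed)
    p0 = (fit.delta_t_max, fit.kd)
    draws = np.empty((n_boot, 2))
    for b in range(n_boot):
        resampled = fitted + rng.choice(residuals, size=n, replace=True)
        draws[b] = _refit(series, resampled, p0)
    jack = np.empty((n, 2))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        jack[i] = _refit(series, series.delta_tms[mask], p0, concs=series.ligand_concs[mask])
    ci_a = _bca_interval(draws[:, 0], fit.delta_t_max, jack[:, 0])
    ci_k = _bca_interval(draws[:, 1], fit.kd, jack[:, 1])
    return replace(fit, ci_delta_t_max=ci_a, ci_kd=ci_k)


def bootstrap_group_ci(
    series: BindingSeries,
    fit: BindingFitResult,
    pooled_sd: float,
    n_reference: int,
    n_per_point: Sequence[int],
    n_boot: int = 1000,
    seed: int = 0,
) -> BindingFitResult:
    """Design-aware parametric bootstrap for plate data.

    Every dTm point on a plate shares the same reference-well mean, so
    replicate noise induces a *correlated* error across the titration
    that residual resampling cannot see.  Here each bootstrap replicate
    draws one reference-mean perturbation (sd = pooled_sd/sqrt(n_ref))
    plus independent per-concentration perturbations
    (sd = pooled_sd/sqrt(n_c)) around the fitted curve and refits.
    ``pooled_sd`` is the pooled within-replicate-group Tm SD.
    """
    if not fit.converged:
        raise ValidationError("bootstrap requires a converged fit")
    if n_boot < 100:
        raise ValidationError("n_boot must be >= 100")
    n_per_point = np.asarray(n_per_point, dtype=float)
    if n_per_point.size != series.ligand_concs.size:
        raise ValidationError("n_per_point must match the titration length")
    concs = series.effective_concs
    pred = np.asarray(predict_delta_tm(fit.delta_t_max, fit.kd, concs))
    rng = np.random.default_rng(seed)
    p0 = (fit.delta_t_max, fit.kd)
    draws = np.empty((n_boot, 2))
    for b in range(n_boot):
        ref_err = rng.normal(0.0, pooled_sd / math.sqrt(n_reference))
        point_err = rng.normal(0.0, pooled_sd / np.sqrt(n_per_point))
        draws[b] = _refit(series, pred + point_err - ref_err, p0)
    lo_a, hi_a = np.percentile(draws[:, 0], [2.5, 97.5])
    lo_k, hi_k = np.percentile(draws[:, 1], [2.5, 97.5])
    return replace(fit, ci_delta_t_max=(float(lo_a), float(hi_a)), ci_kd=(float(lo_k), float(hi_k)))


def grid_search_sse(
    series: BindingSeries,
    a_grid: Sequence[float],
    kd_grid: Sequence[float],
) -> tuple[float, float, float]:
    """Brute-force SSE minimum over a (dTmax, K_D) grid.

    Exists as an independent oracle for :func:`fit_binding`; O(grid^2),
    use small grids.
    """
    concs = series.effective_concs
    best = (math.inf, math.nan, math.nan)
    for a in a_grid:
        for k in kd_grid:
            pred = predict_delta_tm(a, k, concs)
            sse = float(np.sum((series.delta_tms - pred) ** 2))
            if sse < best[0]:
                best = (sse, a, k)
    return best[1], best[2], best[0]
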