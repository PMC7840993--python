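"""Inhibitor dose-response analysis.

Two read-outs are kept separate because they probe different things:

* **destabilization** — Tm(probe + compound) - Tm(probe): a negative
  shift indicates direct binding/modification that loosens the fold;
* **suppression** — percent loss of the dsDNA-induced stabilization,
  100 * (1 - dTm(DNA, dose) / dTm(DNA, 0)): interference with DNA
  binding, the screening read-out.

Suppression is referenced against the contemporaneous no-inhibitor
dTm rather than a historical value, so plate-to-plate Tm drift cancels.
IC50s come from a four-parameter logistic (4PL) fitted on the linear
dose axis with IC50 as an explicit parameter.  Group comparisons use
the classic pooled-variance Student t test (Welch available behind a
flag) with the usual significance stars (0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from thermoshift.errors import DegenerateFitError, ValidationError
from thermoshift.melt import TmEstimate

__all__ = [
    "DoseSeries",
    "DoseResponseFit",
    "GroupComparison",
    "predict_4pl",
    "fit_4pl",
    "destabilization_profile",
    "stabilization_suppression",
    "compare_tm_groups",
]

_RESPONSE_KINDS = {"tm_shift", "stabilization_fraction"}


@dataclass
class DoseSeries:
    """Responses across an inhibitor dose series.

    ``response_kind`` is ``tm_shift`` (degC, negative = destabilization)
    or ``stabilization_fraction`` (% inhibition of the DNA-induced
    shift).
    """

    doses: np.ndarray
    responses: np.ndarray
    response_kind: str
    dose_unit: str = "uM"
    n_per_dose: np.ndarray | None = None
    sd_per_dose: np.ndarray | None = None
    compound: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.response_kind not in _RESPONSE_KINDS:
            raise ValidationError(f"unknown response_kind {self.response_kind!r}")
        if self.doses.shape != self.responses.shape:
            raise ValidationError("doses and responses must have equal length")
        if np.any(self.doses < 0):
            raise ValidationError("doses must be >= 0")
        for name in ("n_per_dose", "sd_per_dose"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.doses.shape:
                    raise ValidationError(f"{name} must match the dose vector length")
                setattr(self, name, arr)


@dataclass
class DoseResponseFit:
    ic50: float
    hill: float
    top: float
    bottom: float
    sse: float
    converged: bool
    n_points: int = 0
    dose_unit: str = "uM"
    message: str = ""


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_stat: float
    p_value: float
    stars: str


def predict_4pl(dose, ic50: float, hill: float, top: float, bottom: float):
    """4PL response = bottom + (top - bottom) / (1 + (ic50/dose)^hill).

    Monotone from ``bottom`` (dose -> 0) to ``top`` (dose -> inf) for
    ``hill > 0``; dose 0 maps to ``bottom`` exactly.
    """
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, ic50 / np.where(d > 0, d, 1.0), np.inf)
        value = bottom + (top - bottom) / (1.0 + ratio**hill)
    value = np.where(d == 0, bottom, value)
    return float(value) if np.isscalar(dose) else value


def fit_4pl(
    series: DoseSeries,
    init: Sequence[float] | None = None,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit.

    Default initialization: top/bottom from the response extremes, IC50
    from the dose nearest the half-maximal response, Hill slope 1.

    ``fix_top`` / ``fix_bottom`` pin the plateaus instead of fitting
    them.  For normalized suppression responses both anchors are defined
    by construction (0% at zero dose, 100% at complete suppression), so
    the suppression workflow fits with ``fix_bottom=0, fix_top=100``;
    raw Tm-shift responses are fitted with all four parameters free.
    """
    doses = series.doses
    resp = series.responses
    nonzero = doses[doses > 0]
    if np.unique(doses).size < 4:
        raise ValidationError("4PL fit needs at least 4 distinct doses")
    if np.unique(nonzero).size < 3:
        raise ValidationError("4PL fit needs at least 3 distinct nonzero doses")
    if init is None:
        bottom0 = fix_bottom if fix_bottom is not None else float(resp[np.argmin(doses)])
        top0 = fix_top if fix_top is not None else float(resp[np.argmax(doses)])
        half = 0.5 * (top0 + bottom0)
        ic50_0 = float(nonzero[np.argmin(np.abs(resp[doses > 0] - half))])
        init = (max(ic50_0, 1e-6), 1.0, top0, bottom0)

    free = [True, True, fix_top is None, fix_bottom is None]

    def model(d, *params):
        it = iter(params)
        full = [next(it) if f else None for f in free]
        ic50, hill = full[0], full[1]
        top = full[2] if free[2] else fix_top
        bottom = full[3] if free[3] else fix_bottom
        return predict_4pl(d, ic50, hill, top, bottom)

    lo_full = (1e-12, 1e-3, -np.inf, -np.inf)
    hi_full = (np.inf, 50.0, np.inf, np.inf)
    p0 = tuple(v for v, f in zip(init, free) if f)
    lo = tuple(v for v, f in zip(lo_full, free) if f)
    hi = tuple(v for v, f in zip(hi_full, free) if f)

    def expand(params):
        it = iter(params)
        full = [next(it) if f else fixed
                for f, fixed in zip(free, (None, None, fix_top, fix_bottom))]
        return tuple(full)

    try:
        popt, _ = curve_fit(model, doses, resp, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        ic50_0, hill0, top0, bottom0 = expand(p0)
        pred0 = predict_4pl(doses, ic50_0, hill0, top0, bottom0)
        return DoseResponseFit(
            ic50=float(ic50_0), hill=float(hill0), top=float(top0), bottom=float(bottom0),
            sse=float(np.sum((resp - pred0) ** 2)), converged=False, n_points=doses.size,
            dose_unit=series.dose_unit, message=f"fit did not converge: {exc}",
        )
    ic50, hill, top, bottom = expand(popt)
    sse = float(np.sum((resp - predict_4pl(doses, ic50, hill, top, bottom)) ** 2))
    return DoseResponseFit(
        ic50=float(ic50), hill=float(hill), top=float(top), bottom=float(bottom),
        sse=sse, converged=True, n_points=doses.size, dose_unit=series.dose_unit,
    )


def _group_stats(estimates: Sequence[TmEstimate]) -> tuple[float, float, int]:
    tms = np.array([e.tm for e in estimates if not math.isnan(e.tm)])
    if tms.size == 0:
        raise ValidationError("group has no usable Tm estimates")
    sd = float(np.std(tms, ddof=1)) if tms.size > 1 else 0.0
    return float(tms.mean()), sd, tms.size


def destabilization_profile(
    tm_by_dose: Mapping[float, Sequence[TmEstimate]],
    reference: Sequence[TmEstimate],
    dose_unit: str = "uM",
    compound: str = "",
) -> DoseSeries:
    """Tm shift of the probe alone under increasing compound dose,
    relative to the untreated probe (negative = destabilization)."""
    if not reference:
        raise ValidationError("empty reference group")
    ref_mean, ref_sd, ref_n = _group_stats(reference)
    doses = sorted(tm_by_dose)
    responses, sds, ns = [], [], []
    for dose in doses:
        mean, sd, n = _group_stats(tm_by_dose[dose])
        responses.append(mean - ref_mean)
        sds.append(math.sqrt(sd**2 / n + ref_sd**2 / ref_n))
        ns.append(n)
    return DoseSeries(
        doses=np.array(doses), responses=np.array(responses), response_kind="tm_shift",
        dose_unit=dose_unit, n_per_dose=np.array(ns, dtype=float),
        sd_per_dose=np.array(sds), compound=compound,
    )


def stabilization_suppression(
    tm_probe: Sequence[TmEstimate],
    tm_probe_dna: Sequence[TmEstimate],
    tm_probe_inh_by_dose: Mapping[float, Sequence[TmEstimate]],
    tm_probe_dna_inh_by_dose: Mapping[float, Sequence[TmEstimate]],
    dose_unit: str = "uM",
    compound: str = "",
    clamp_top: bool = True,
) -> DoseSeries:
    """Percent suppression of the DNA-induced stabilization per dose.

    The reference shift dTm(DNA, 0) = mean Tm(probe+DNA) - mean Tm(probe)
    must be positive.  At each dose the DNA shift is measured against the
    probe + inhibitor wells at the same dose, so direct destabilization
    by the compound does not masquerade as DNA-binding inhibition.
    Values above 100% (shift inverted) are clamped to 100 by default;
    negative values (shift enhanced) are kept raw.
    """
    base_mean, base_sd, base_n = _group_stats(tm_probe_dna)
    probe_mean, probe_sd, probe_n = _group_stats(tm_probe)
    base_shift = base_mean - probe_mean
    if base_shift <= 0:
        raise DegenerateFitError(
            f"reference DNA shift is {base_shift:.3g} degC; no stabilization to suppress"
        )
    doses = sorted(tm_probe_dna_inh_by_dose)
    responses, sds, ns = [], [], []
    for dose in doses:
        probe_at_dose = tm_probe_inh_by_dose.get(dose, tm_probe)
        p_mean, p_sd, p_n = _group_stats(probe_at_dose)
        d_mean, d_sd, d_n = _group_stats(tm_probe_dna_inh_by_dose[dose])
        shift = d_mean - p_mean
        frac = 100.0 * (1.0 - shift / base_shift)
        if clamp_top:
            frac = min(frac, 100.0)
        responses.append(frac)
        shift_sd = math.sqrt(d_sd**2 / d_n + p_sd**2 / p_n)
        sds.append(100.0 * shift_sd / base_shift)
        ns.append(d_n)
    return DoseSeries(
        doses=np.array(doses), responses=np.array(responses),
        response_kind="stabilization_fraction", dose_unit=dose_unit,
        n_per_dose=np.array(ns, dtype=float), sd_per_dose=np.array(sds), compound=compound,
    )


_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for threshold, symbol in _STAR_THRESHOLDS:
        if p < threshold:
            return symbol
    return "ns"


def compare_tm_groups(
    a: Sequence[float] | Sequence[TmEstimate],
    b: Sequence[float] | Sequence[TmEstimate],
    welch: bool = False,
) -> GroupComparison:
    """Two-sample two-tailed t test on Tm values (pooled variance by
    default).  Two zero-variance groups with equal means give t=0, p=1
    by convention."""
    a_vals = np.array([x.tm if isinstance(x, TmEstimate) else float(x) for x in a])
    b_vals = np.array([x.tm if isinstance(x, TmEstimate) else float(x) for x in b])
    if a_vals.size < 2 or b_vals.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if np.std(a_vals) == 0 and np.std(b_vals) == 0:
        if a_vals.mean() == b_vals.mean():
            t_stat, p_value = 0.0, 1.0
        else:
            t_stat = math.inf if a_vals.mean() > b_vals.mean() else -math.inf
            p_value = 0.0
    else:
        t_stat, p_value = stats.ttest_ind(a_vals, b_vals, equal_var=not welch)
        t_stat, p_value = float(t_stat), float(p_value)
    sd_a = float(np.std(a_vals, ddof=1))
    sd_b = float(np.std(b_vals, ddof=1))
    return GroupComparison(
        mean_a=float(a_vals.mean()), mean_b=float(b_vals.mean()),
        sd_a=sd_a, sd_b=sd_b, n_a=a_vals.size, n_b=b_vals.size,
        t_stat=t_stat, p_value=p_value, stars=_stars(p_value),
    )


def grid_search_4pl_sse(
    series: DoseSeries,
    ic50_grid: Sequence[float],
    hill_grid: Sequence[float],
    top_grid: Sequence[float],
    bottom_grid: Sequence[float],
) -> tuple[tuple[float, float, float, float], float]:
    """Brute-force SSE minimum over a 4PL parameter grid (independent
    oracle for :func:`fit_4pl`)."""
    best_sse = math.inf
    best = (math.nan,) * 4
    for ic50 in ic50_grid:
        for hill in hill_grid:
            for top in top_grid:
                for bottom in bottom_grid:
                    pred = predict_4pl(series.doses, ic50, hill, top, bottom)
                    sse = float(np.sum((series.responses - pred) ** 2))
                    if sse < best_sse:
                        best_sse = sse
                        best = (ic50, hill, top, bottom)
    return best, best_sse
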