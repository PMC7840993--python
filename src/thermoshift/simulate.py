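"""Seeded synthetic melt curves and whole assay plates.

The generator produces SYPRO-Orange-style melt curves from a two-state
van't Hoff unfolding model: the unfolded fraction at temperature T is

    f(T) = 1 / (1 + exp(dG / (R * T_K))),   dG = dH_vH * (1 - T_K / Tm_K)

with temperatures in Kelvin internally and the van't Hoff enthalpy
dH_vH in kJ/mol.  f(Tm) = 1/2 exactly; larger dH_vH sharpens the
transition.  The fluorescence trace is

    RFU(T) = [native(T) * (1 - f) + (unfolded(T) + amplitude) * f]
             * exp(-quench_rate * max(0, T - quench_onset))  + noise

i.e. sloped native/unfolded baselines, a dye-binding amplitude, an
exponential post-transition quench (dye release on aggregation), and
Gaussian replicate noise.

Plate-level generators inject ligand-induced stabilization through the
same quadratic ligand-depletion equation the fitter uses, and inhibitor
effects through a dose->shift map or 4PL truth, so full-pipeline
parameter recovery is well defined.  All randomness flows from a single
integer seed; per-well streams are derived deterministically from
(seed, well id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from thermoshift.binding import predict_delta_tm
from thermoshift.dose import predict_4pl
from thermoshift.errors import ValidationError
from thermoshift.plate_io import MeltPlate, WellCondition

__all__ = [
    "GAS_CONSTANT_KJ",
    "SimSpec",
    "PlateSimSpec",
    "two_state_fraction_unfolded",
    "simulate_melt_curve",
    "simulate_binding_experiment",
    "simulate_inhibition_experiment",
]

#: Gas constant in kJ / (mol K).
GAS_CONSTANT_KJ = 8.31446261815324e-3

_ZERO_C = 273.15


@dataclass(frozen=True)
class SimSpec:
    """Generative parameters for one two-state melt curve.

    Defaults emulate the assay's study conditions: a probe melting near
    42.5 degC read on a 25-95 degC grid with 0.2 degC increments, a
    ~4 degC-wide transition (dH_vH 400 kJ/mol), and a post-transition
    quench starting 8 degC above Tm.
    """

    tm0: float = 42.5
    dh_vh: float = 400.0
    native_baseline: tuple[float, float] = (30.0, 0.3)
    unfolded_baseline: tuple[float, float] = (150.0, -1.0)
    amplitude: float = 800.0
    quench_onset: float = 50.5
    quench_rate: float = 0.02
    # ~0.12% of the default amplitude; with the default smoothing this
    # reproduces the ~0.1 degC replicate Tm scatter typical of the assay
    noise_sd: float = 1.0
    grid: tuple[float, float, float] = (25.0, 95.0, 0.2)

    def __post_init__(self) -> None:
        if self.dh_vh <= 0:
            raise ValidationError("dh_vh must be > 0")
        if self.amplitude < 0:
            raise ValidationError("amplitude must be >= 0")
        start, end, step = self.grid
        if step <= 0 or end <= start:
            raise ValidationError("grid must be (start, end, step) with step > 0 and end > start")
        if self.quench_onset <= self.tm0:
            raise ValidationError("quench_onset must be above tm0")

    def temperatures(self) -> np.ndarray:
        start, end, step = self.grid
        n = int(round((end - start) / step)) + 1
        return start + step * np.arange(n)


@dataclass(frozen=True)
class PlateSimSpec:
    """Generative parameters for a whole plate.

    ``binding`` is the (dTmax degC, K_D uM, site multiplicity) truth of
    the quadratic stabilization model; ``destab`` maps inhibitor dose to
    a (usually negative) Tm shift of the probe itself; ``suppression``
    is a (ic50, hill) truth for percent loss of the DNA-induced shift.
    Defaults mirror the dsDNA titration design: seven duplex
    concentrations 0.5-10 uM in triplicate with 0.1 degC Tm noise.

    Plate-level replicate variability is modelled at the Tm level
    (``tm_noise_sd``): each well's true Tm is jittered and a clean curve
    is generated from it.  Curve-level (RFU) noise belongs to
    :class:`SimSpec` and is off by default here so the two noise sources
    stay independently controllable.
    """

    probe: SimSpec = field(default_factory=lambda: SimSpec(noise_sd=0.0))
    probe_name: str = "p65_1-306"
    delta_t_max: float = 1.678
    kd: float = 2.228
    site_multiplicity: int = 1
    ligand_name: str = "2kB"
    ligand_concs: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    dna_conc: float = 10.0
    inhibitor_name: str = "WFA"
    destab: Mapping[float, float] | None = None
    suppression: tuple[float, float] | None = (16.4, 1.0)
    replicates: int = 3
    tm_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if any(c < 0 for c in self.ligand_concs):
            raise ValidationError("ligand concentrations must be >= 0")
        if self.site_multiplicity < 1:
            raise ValidationError("site_multiplicity must be >= 1")


def two_state_fraction_unfolded(t, tm: float, dh_vh: float):
    """Unfolded fraction at temperature ``t`` (degC) for a two-state
    transition with midpoint ``tm`` (degC) and van't Hoff enthalpy
    ``dh_vh`` (kJ/mol)."""
    if dh_vh <= 0:
        raise ValidationError("dh_vh must be > 0")
    t_k = np.asarray(t, dtype=float) + _ZERO_C
    tm_k = tm + _ZERO_C
    dg = dh_vh * (1.0 - t_k / tm_k)
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.exp(dg / (GAS_CONSTANT_KJ * t_k)))
    return float(f) if np.isscalar(t) else f


def simulate_melt_curve(
    spec: SimSpec,
    tm_override: float | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one (temperatures, RFU) trace; deterministic given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = spec.temperatures()
    tm = spec.tm0 if tm_override is None else tm_override
    f = two_state_fraction_unfolded(t, tm, spec.dh_vh)
    nb = spec.native_baseline[0] + spec.native_baseline[1] * t
    ub = spec.unfolded_baseline[0] + spec.unfolded_baseline[1] * t
    signal = nb * (1.0 - f) + (ub + spec.amplitude) * f
    quench = np.exp(-spec.quench_rate * np.maximum(0.0, t - spec.quench_onset))
    rfu = signal * quench
    if spec.noise_sd > 0:
        rfu = rfu + rng.normal(0.0, spec.noise_sd, size=t.size)
    return t, rfu


def _well_rng(seed: int, well_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(well_id.encode())]))


def _add_well(
    curves: dict[str, np.ndarray],
    layout: dict[str, WellCondition],
    spec: PlateSimSpec,
    well_id: str,
    tm: float,
    condition: WellCondition,
) -> float:
    rng = _well_rng(spec.seed, well_id)
    tm_jitter = rng.normal(0.0, spec.tm_noise_sd) if spec.tm_noise_sd > 0 else 0.0
    _, rfu = simulate_melt_curve(spec.probe, tm_override=tm + tm_jitter, seed=rng)
    curves[well_id] = rfu
    layout[well_id] = condition
    return tm + tm_jitter


def simulate_binding_experiment(
    spec: PlateSimSpec,
) -> tuple[MeltPlate, dict[str, WellCondition], dict]:
    """A dsDNA titration plate: reference wells at the apo Tm, ligand
    wells stabilized per the quadratic truth, replicates independently
    noised.  Returns (plate, layout, truth record)."""
    curves: dict[str, np.ndarray] = {}
    layout: dict[str, WellCondition] = {}
    for r in range(spec.replicates):
        well = f"REF_{r + 1}"
        _add_well(curves, layout, spec, well, spec.probe.tm0, WellCondition(
            well_id=well, probe=spec.probe_name, role="reference", replicate_group="reference",
        ))
    for conc in spec.ligand_concs:
        shift = predict_delta_tm(spec.delta_t_max, spec.kd, conc * spec.site_multiplicity)
        for r in range(spec.replicates):
            well = f"D{conc:g}_{r + 1}"
            _add_well(curves, layout, spec, well, spec.probe.tm0 + shift, WellCondition(
                well_id=well, probe=spec.probe_name, ligand=spec.ligand_name,
                ligand_conc=float(conc), replicate_group=f"D{conc:g}",
            ))
    plate = MeltPlate(temperatures=spec.probe.temperatures(), curves=curves,
                      metadata={"scenario": "binding", "seed": spec.seed})
    truth = {
        "delta_t_max": spec.delta_t_max,
        "kd": spec.kd,
        "site_multiplicity": spec.site_multiplicity,
        "tm0": spec.probe.tm0,
        "ligand_concs": list(spec.ligand_concs),
        "replicates": spec.replicates,
        "tm_noise_sd": spec.tm_noise_sd,
        "seed": spec.seed,
    }
    return plate, layout, truth


def _destab_shift(spec: PlateSimSpec, dose: float) -> float:
    if spec.destab is None or dose == 0:
        return 0.0
    return float(spec.destab.get(dose, 0.0))


def _suppression_percent(spec: PlateSimSpec, dose: float) -> float:
    if spec.suppression is None or dose == 0:
        return 0.0
    ic50, hill = spec.suppression
    return float(predict_4pl(dose, ic50, hill, top=100.0, bottom=0.0))


def simulate_inhibition_experiment(
    spec: PlateSimSpec,
    doses: Sequence[float],
) -> tuple[MeltPlate, dict[str, WellCondition], dict]:
    """An inhibitor plate mirroring the screening design.

    Per dose three well classes: probe + inhibitor, and probe +
    inhibitor + dsDNA; plus untreated probe-alone and probe + dsDNA
    wells (dose 0).  The inhibitor destabilizes the probe per the
    ``destab`` map and suppresses the DNA-induced shift per the
    ``suppression`` 4PL truth.
    """
    if any(d < 0 for d in doses):
        raise ValidationError("doses must be >= 0")
    base_shift = predict_delta_tm(spec.delta_t_max, spec.kd,
                                  spec.dna_conc * spec.site_multiplicity)
    curves: dict[str, np.ndarray] = {}
    layout: dict[str, WellCondition] = {}
    for r in range(spec.replicates):
        well = f"P0_{r + 1}"
        _add_well(curves, layout, spec, well, spec.probe.tm0, WellCondition(
            well_id=well, probe=spec.probe_name, role="reference", replicate_group="probe",
        ))
        well = f"PD0_{r + 1}"
        _add_well(curves, layout, spec, well, spec.probe.tm0 + base_shift, WellCondition(
            well_id=well, probe=spec.probe_name, ligand=spec.ligand_name,
            ligand_conc=spec.dna_conc, replicate_group="probe+dna",
        ))
    for dose in doses:
        if dose == 0:
            continue
        destab = _destab_shift(spec, dose)
        suppressed = base_shift * (1.0 - _suppression_percent(spec, dose) / 100.0)
        for r in range(spec.replicates):
            well = f"I{dose:g}_{r + 1}"
            _add_well(curves, layout, spec, well, spec.probe.tm0 + destab, WellCondition(
                well_id=well, probe=spec.probe_name, inhibitor=spec.inhibitor_name,
                inhibitor_conc=float(dose), replicate_group=f"I{dose:g}",
            ))
            well = f"ID{dose:g}_{r + 1}"
            _add_well(curves, layout, spec, well,
                      spec.probe.tm0 + destab + suppressed, WellCondition(
                well_id=well, probe=spec.probe_name, ligand=spec.ligand_name,
                ligand_conc=spec.dna_conc, inhibitor=spec.inhibitor_name,
                inhibitor_conc=float(dose), replicate_group=f"ID{dose:g}",
            ))
    plate = MeltPlate(temperatures=spec.probe.temperatures(), curves=curves,
                      metadata={"scenario": "inhibition", "seed": spec.seed})
    truth = {
        "tm0": spec.probe.tm0,
        "base_shift": float(base_shift),
        "doses": [float(d) for d in doses],
        "destab": dict(spec.destab) if spec.destab else {},
        "suppression": tuple(spec.suppression) if spec.suppression else None,
        "replicates": spec.replicates,
        "tm_noise_sd": spec.tm_noise_sd,
        "seed": spec.seed,
    }
    return plate, layout, truth
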