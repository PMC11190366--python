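"""End-to-end performance calculator: threshold, dose and lesion estimates.

Given a requested pulse train, the calculator clamps each parameter to the
experimentally studied range (interpolation only — the power-law fit was
never validated outside it), predicts the lethal EFT with the published
coefficients, wraps it in the ±33% maximum-relative-error band, computes the
adiabatic dosimetry at that threshold, and — when an applied voltage is
supplied — the expected lesion area under the study's two-needle electrode
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .datasets import PulseTrain
from .dosimetry import DoseReport, MediumProperties, dose_report
from .fieldmap import ElectrodeGeometry, analytic_field, lesion_area
from .regression import LogLogEFTRegressor, frozen_model

__all__ = [
    "ParameterRange",
    "CalculatorReport",
    "validate_and_clamp",
    "run_calculator",
    "RELATIVE_ERROR_BAND",
]

#: Maximum relative fitting error of the power-law model over the study data.
RELATIVE_ERROR_BAND = 0.33


@dataclass(frozen=True)
class ParameterRange:
    """Studied parameter ranges; the fit is interpolation-only inside them."""

    pulse_count: tuple[float, float] = (50, 400)
    phase_duration: tuple[float, float] = (0.2, 10.0)  # µs
    prf: tuple[float, float] = (2.0, 200.0)  # kHz

    def __post_init__(self) -> None:
        for name in ("pulse_count", "phase_duration", "prf"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class CalculatorReport:
    """Serializable output of one calculator run."""

    requested: PulseTrain
    effective: PulseTrain
    warnings: tuple[str, ...]
    eft: float  # kV/cm
    eft_band: tuple[float, float]  # kV/cm, prediction * (1 ∓ 0.33)
    dose: DoseReport
    lesion_area: float | None  # mm², present iff a voltage was supplied
    voltage: float | None

    def to_dict(self) -> dict:
        t, e = self.requested, self.effective
        return {
            "requested": {
                "pulse_count": t.pulse_count,
                "phase_duration_us": t.phase_duration,
                "prf_khz": t.prf,
            },
            "effective": {
                "pulse_count": e.pulse_count,
                "phase_duration_us": e.phase_duration,
                "prf_khz": e.prf,
            },
            "warnings": list(self.warnings),
            "eft_kvcm": self.eft,
            "eft_band_kvcm": list(self.eft_band),
            "dose": self.dose.to_dict(),
            "lesion_area_mm2": self.lesion_area,
            "voltage_v": self.voltage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalculatorReport":
        req = d["requested"]
        eff = d["effective"]
        dose = d["dose"]
        return cls(
            requested=PulseTrain(
                pulse_count=int(req["pulse_count"]),
                phase_duration=req["phase_duration_us"],
                prf=req["prf_khz"],
            ),
            effective=PulseTrain(
                pulse_count=int(eff["pulse_count"]),
                phase_duration=eff["phase_duration_us"],
                prf=eff["prf_khz"],
            ),
            warnings=tuple(d["warnings"]),
            eft=d["eft_kvcm"],
            eft_band=tuple(d["eft_band_kvcm"]),
            dose=DoseReport(
                field=dose["field_kvcm"],
                on_time=dose["on_time_s"],
                peak_sar=dose["peak_sar_w_per_kg"],
                absorbed_dose=dose["absorbed_dose_j_per_g"],
                adiabatic_heating=dose["adiabatic_heating_c"],
                final_temperature=dose["final_temperature_c"],
            ),
            lesion_area=d["lesion_area_mm2"],
            voltage=d["voltage_v"],
        )


_PARAM_LABELS = {
    "pulse_count": "pulse count",
    "phase_duration": "phase duration",
    "prf": "pulse repetition frequency",
}


def validate_and_clamp(
    inputs: PulseTrain, prange: ParameterRange = ParameterRange()
) -> tuple[PulseTrain, list[str]]:
    """Clamp each out-of-range parameter to its nearest bound.

    One warning per clamped parameter, naming it. Non-positive inputs are a
    hard error (raised by :class:`PulseTrain` itself), never clamped.
    """
    effective = inputs
    warnings_: list[str] = []
    for name in ("pulse_count", "phase_duration", "prf"):
        lo, hi = getattr(prange, name)
        v = getattr(inputs, name)
        clamped = min(max(v, lo), hi)
        if clamped != v:
            if name == "pulse_count":
                clamped = int(clamped)
            effective = replace(effective, **{name: clamped})
            warnings_.append(
                f"{_PARAM_LABELS[name]} {v:g} is outside the studied range "
                f"[{lo:g}, {hi:g}]; using {clamped:g}"
            )
    return effective, warnings_


def run_calculator(
    inputs: PulseTrain,
    medium: MediumProperties = MediumProperties(),
    voltage: float | None = None,
    model: LogLogEFTRegressor | None = None,
    geometry: ElectrodeGeometry = ElectrodeGeometry(),
    prange: ParameterRange = ParameterRange(),
    baseline_c: float = 37.0,
) -> CalculatorReport:
    """Predict lethal EFT, dose and (optionally) lesion area for a train.

    The predictor is evaluated strictly inside the studied range; anything
    outside is clamped first with a warning. Deterministic.
    """
    model = model if model is not None else frozen_model()
    effective, warn = validate_and_clamp(inputs, prange)
    eft = model.predict_train(effective)
    band = (eft * (1 - RELATIVE_ERROR_BAND), eft * (1 + RELATIVE_ERROR_BAND))
    dose = dose_report(eft, effective, medium, baseline_c=baseline_c)
    area = None
    if voltage is not None:
        fmap = analytic_field(geometry, voltage)
        area = lesion_area(fmap, eft)
    return CalculatorReport(
        requested=inputs,
        effective=effective,
        warnings=tuple(warn),
        eft=eft,
        eft_band=band,
        dose=dose,
        lesion_area=area,
        voltage=voltage,
    )
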