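"""Pulse-train dataset: typed records, CSV I/O and a synthetic-observation generator.

The packaged dataset holds the 52 pulse-parameter conditions of the study:
trains of 50–400 biphasic pulses with 0.2–10 µs phase duration delivered at
2–200 kHz, each with the measured cell-death areas (Calcein-AM and propidium
iodide), the lethal electric-field thresholds derived from them, and the
computed adiabatic heating. All quantities are condition means with standard
errors (n = 4–8 replicates per condition; replicate-level data unpublished).

Canonical units throughout: phase duration in µs, PRF in kHz, amplitude in V,
areas in mm², field thresholds in kV/cm, heating in °C.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PulseTrain",
    "EFTObservation",
    "ObservationTable",
    "load_observations",
    "write_observations",
    "generate_synthetic_observations",
    "ObservationParseError",
    "ObservationValidationError",
]

_PACKAGED_CSV = "eft_observations.csv"

#: CSV schema, in column order.
CSV_COLUMNS = [
    "pulse_count",
    "phase_duration_us",
    "phase_amplitude_v",
    "prf_khz",
    "pi_area_mm2",
    "pi_area_se",
    "pi_eft_kvcm",
    "pi_eft_se",
    "ca_area_mm2",
    "ca_area_se",
    "ca_eft_kvcm",
    "ca_eft_se",
    "ah_c",
    "ah_se",
]

_MEASUREMENTS = [
    ("pi_area_mm2", "pi_area_se"),
    ("pi_eft_kvcm", "pi_eft_se"),
    ("ca_area_mm2", "ca_area_se"),
    ("ca_eft_kvcm", "ca_eft_se"),
    ("ah_c", "ah_se"),
]


class ObservationParseError(ValueError):
    """A CSV cell could not be parsed; the message names the row and column."""


class ObservationValidationError(ValueError):
    """A record or table violates a dataset invariant."""


@dataclass(frozen=True)
class PulseTrain:
    """One biphasic pulse train.

    Parameters
    ----------
    pulse_count : int
        Number of biphasic pulses in the train (p#).
    phase_duration : float
        Duration of a single phase, µs (t_p).
    prf : float
        Pulse repetition frequency, kHz (inverse of the biphasic repetition
        period).
    phase_amplitude : float or None
        Phase amplitude, V (V_p). Optional: the regression does not use it.
    interphase_delay : float
        Zero-voltage gap between the two phases, µs; 1 µs for every condition
        in the study.
    """

    pulse_count: int
    phase_duration: float
    prf: float
    phase_amplitude: float | None = None
    interphase_delay: float = 1.0

    def __post_init__(self) -> None:
        if not float(self.pulse_count).is_integer() or self.pulse_count <= 0:
            raise ObservationValidationError(
                f"pulse_count must be a positive integer, got {self.pulse_count!r}"
            )
        for name in ("phase_duration", "prf", "interphase_delay"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ObservationValidationError(
                    f"{name} must be strictly positive, got {v!r}"
                )
        if self.phase_amplitude is not None and not (self.phase_amplitude > 0):
            raise ObservationValidationError(
                f"phase_amplitude must be strictly positive, got {self.phase_amplitude!r}"
            )

    @property
    def key(self) -> tuple[int, float, float]:
        """(pulse_count, phase_duration, prf) — unique per condition."""
        return (self.pulse_count, self.phase_duration, self.prf)


@dataclass(frozen=True)
class EFTObservation:
    """One experimental condition: a pulse train with its measured endpoints.

    Measurement fields are condition means; each has a companion standard
    error which is ``nan`` when unknown. Areas in mm², thresholds in kV/cm,
    adiabatic heating in °C.
    """

    train: PulseTrain
    pi_area: float = math.nan
    pi_area_se: float = math.nan
    pi_eft: float = math.nan
    pi_eft_se: float = math.nan
    ca_area: float = math.nan
    ca_area_se: float = math.nan
    ca_eft: float = math.nan
    ca_eft_se: float = math.nan
    ah: float = math.nan
    ah_se: float = math.nan
    n_replicates: int = 6  # range midpoint; the study reports n = 4-8

    def __post_init__(self) -> None:
        for name in (
            "pi_area", "pi_eft", "ca_area", "ca_eft", "ah",
            "pi_area_se", "pi_eft_se", "ca_area_se", "ca_eft_se", "ah_se",
        ):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ObservationValidationError(f"{name} must be non-negative, got {v}")
        # The two stains image the same lesion; wildly divergent thresholds
        # indicate a transcription or analysis error.
        if not math.isnan(self.ca_eft) and not math.isnan(self.pi_eft):
            lo, hi = sorted((self.ca_eft, self.pi_eft))
            if lo > 0 and hi / lo > 2:
                raise ObservationValidationError(
                    f"ca_eft ({self.ca_eft}) and pi_eft ({self.pi_eft}) differ by "
                    f"more than a factor of 2 for train {self.train.key}"
                )


@dataclass
class ObservationTable:
    """Ordered collection of :class:`EFTObservation` with provenance text."""

    records: list[EFTObservation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [r.train.key for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ObservationValidationError(
                f"duplicate (pulse_count, phase_duration, prf) triple: {dup}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EFTObservation]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EFTObservation:
        return self.records[i]

    def find(self, pulse_count: int, phase_duration: float, prf: float) -> EFTObservation:
        """Return the record for a parameter triple, or raise ``KeyError``."""
        key = (pulse_count, phase_duration, prf)
        for r in self.records:
            if r.train.key == key:
                return r
        raise KeyError(f"no record for (p#, t_p, prf) = {key}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            t = r.train
            rows.append(
                {
                    "pulse_count": t.pulse_count,
                    "phase_duration_us": t.phase_duration,
                    "phase_amplitude_v": t.phase_amplitude,
                    "prf_khz": t.prf,
                    "pi_area_mm2": r.pi_area,
                    "pi_area_se": r.pi_area_se,
                    "pi_eft_kvcm": r.pi_eft,
                    "pi_eft_se": r.pi_eft_se,
                    "ca_area_mm2": r.ca_area,
                    "ca_area_se": r.ca_area_se,
                    "ca_eft_kvcm": r.ca_eft,
                    "ca_eft_se": r.ca_eft_se,
                    "ah_c": r.ah,
                    "ah_se": r.ah_se,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


_PM_RE = re.compile(r"^\s*([^\s±]+)\s*±\s*([^\s±]+)\s*$")


def _parse_cell(raw: object, row: int, column: str) -> tuple[float, float]:
    """Parse a measurement cell: bare mean, 'mean ± se', or empty."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan, math.nan
    if isinstance(raw, (int, float)):
        return float(raw), math.nan
    text = str(raw).strip().replace(",", "")
    if not text:
        return math.nan, math.nan
    m = _PM_RE.match(text)
    try:
        if m:
            return float(m.group(1)), float(m.group(2))
        return float(text), math.nan
    except ValueError:
        raise ObservationParseError(
            f"cannot parse value {raw!r} in row {row}, column {column!r}"
        ) from None


def _parse_scalar(raw: object, row: int, column: str, *, optional: bool = False) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        if optional:
            return math.nan
        raise ObservationParseError(f"missing value in row {row}, column {column!r}")
    try:
        return float(str(raw).replace(",", ""))
    except ValueError:
        raise ObservationParseError(
            f"cannot parse value {raw!r} in row {row}, column {column!r}"
        ) from None


def load_observations(source: str | Path = "packaged") -> ObservationTable:
    """Load an observation table from a CSV file or the packaged dataset.

    Parameters
    ----------
    source : str or Path
        Path to a CSV file, or the literal ``"packaged"`` for the dataset
        shipped with the package (52 conditions).

    Measurement cells may be bare means, ``mean ± se`` strings, or may use
    the split ``*_se`` companion columns; ``±`` cells take precedence.
    """
    if source == "packaged":
        with resources.as_file(
            resources.files("pfacalc").joinpath("data", _PACKAGED_CSV)
        ) as p:
            table = load_observations(p)
        table.provenance = "packaged study dataset (52 conditions)"
        return table

    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = {"pulse_count", "phase_duration_us", "prf_khz"} - set(df.columns)
    if missing:
        raise ObservationParseError(f"CSV is missing required columns: {sorted(missing)}")

    records = []
    for i, row in df.iterrows():
        rownum = int(i) + 2  # 1-based, counting the header line
        p = _parse_scalar(row.get("pulse_count"), rownum, "pulse_count")
        tp = _parse_scalar(row.get("phase_duration_us"), rownum, "phase_duration_us")
        f = _parse_scalar(row.get("prf_khz"), rownum, "prf_khz")
        vp = _parse_scalar(
            row.get("phase_amplitude_v"), rownum, "phase_amplitude_v", optional=True
        )
        train = PulseTrain(
            pulse_count=int(p),
            phase_duration=tp,
            prf=f,
            phase_amplitude=None if math.isnan(vp) else vp,
        )
        values: dict[str, float] = {}
        for mean_col, se_col in _MEASUREMENTS:
            mean, se = _parse_cell(row.get(mean_col), rownum, mean_col)
            if math.isnan(se) and se_col in df.columns:
                se = _parse_scalar(row.get(se_col), rownum, se_col, optional=True)
            key = mean_col.rsplit("_", 1)[0] if mean_col != "ah_c" else "ah"
            values[key] = mean
            values[key + "_se"] = se
        records.append(
            EFTObservation(
                train=train,
                pi_area=values["pi_area"], pi_area_se=values["pi_area_se"],
                pi_eft=values["pi_eft"], pi_eft_se=values["pi_eft_se"],
                ca_area=values["ca_area"], ca_area_se=values["ca_area_se"],
                ca_eft=values["ca_eft"], ca_eft_se=values["ca_eft_se"],
                ah=values["ah"], ah_se=values["ah_se"],
            )
        )
    return ObservationTable(records=records, provenance=str(source))


def write_observations(table: ObservationTable, path: str | Path) -> None:
    """Write a table as CSV. ``load_observations`` round-trips it exactly."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


def generate_synthetic_observations(
    model,
    design: Sequence[PulseTrain],
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ObservationTable:
    """Draw synthetic lethal-threshold observations from a regression model.

    The Calcein-AM threshold for each design point is the model prediction
    times ``exp(eps)`` with ``eps ~ Normal(0, noise_cv)`` — multiplicative
    log-normal noise, matching the log-space error model of the regression.
    The PI threshold is set equal to the CA draw; areas are left unknown.

    Parameters
    ----------
    model : LogLogEFTRegressor or object with ``predict_train``
        Generating model.
    design : sequence of PulseTrain
        Conditions to simulate.
    noise_cv : float
        Standard deviation of the log-scale noise (≈ coefficient of
        variation for small values). 0 gives exact model predictions.
    seed : int, Generator or None
        Randomness source; fixed seeds give identical tables.
    """
    if len(design) == 0:
        raise ValueError("design must contain at least one pulse train")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be non-negative, got {noise_cv}")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_cv, size=len(design)) if noise_cv > 0 else np.zeros(len(design))
    records = []
    for train, e in zip(design, eps):
        eft = float(model.predict_train(train) * math.exp(e))
        records.append(EFTObservation(train=train, ca_eft=eft, pi_eft=eft))
    return ObservationTable(
        records=records,
        provenance=f"synthetic (noise_cv={noise_cv}, n={len(design)})",
    )
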