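"""Frequency-sweep configuration and single-point impedance calibration.

An AD5933-class impedance analyzer returns, for every frequency of a
programmed sweep, a pair of dimensionless readouts labelled real (``Rr``)
and imaginary (``Ir``).  These are *not* the real and imaginary parts of
the impedance: the instrument has a frequency-dependent gain and an
intrinsic (system) phase.  Both are removed by a single-point calibration
against a known reference resistor:

* gain factor   ``FG(f) = (1 / R_cal) / |raw(f)|``  measured on the resistor,
* system phase  ``phaseZ(f) = atan2(Ir, Rr)``       measured on the resistor.

A subsequent unknown measurement is then converted with

* ``|Z|(f)   = 1 / (FG(f) * |raw(f)|)``
* ``phaseC(f) = raw phase(f) - phaseZ(f)``  (wrapped to (-pi, pi])
* ``real = |Z| cos(phaseC)``, ``imag = |Z| sin(phaseC)``.

The default sweep mirrors the screening device's configuration: start
10 kHz, increment 280 Hz, 255 steps (256 frequencies), reference 470 ohm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SweepConfig",
    "RawSweep",
    "CalibrationModel",
    "ImpedanceSpectrum",
    "sweep_frequencies",
    "raw_magnitude",
    "gain_factor",
    "raw_phase",
    "calibrate_system",
    "apply_calibration",
    "error_percentage",
    "rc_series_impedance",
    "wrap_phase",
]


class CalibrationError(ValueError):
    """Degenerate calibration input (zero raw magnitude, mismatched grids)."""


def wrap_phase(phase: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    wrapped = np.mod(np.asarray(phase, dtype=float), 2.0 * np.pi)
    wrapped = np.where(wrapped > np.pi, wrapped - 2.0 * np.pi, wrapped)
    # mod maps -pi to +pi already; scalars come back as scalars
    if np.ndim(phase) == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class SweepConfig:
    """Sweep and calibration settings of the impedance analyzer.

    ``n_steps`` counts increments beyond the start point, so the sweep
    holds ``n_steps + 1`` frequencies.
    """

    start_frequency: float = 10_000.0  # Hz
    frequency_increment: float = 280.0  # Hz
    n_steps: int = 255
    calibration_resistance: float = 470.0  # ohm
    output_voltage: float = 2.0  # Vpp
    n_cycles: int = 511

    def __post_init__(self) -> None:
        if self.start_frequency <= 0:
            raise ValueError("start_frequency must be > 0")
        if self.frequency_increment <= 0:
            raise ValueError("frequency_increment must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.calibration_resistance <= 0:
            raise ValueError("calibration_resistance must be > 0")

    @property
    def frequencies(self) -> np.ndarray:
        return sweep_frequencies(self)


def sweep_frequencies(config: SweepConfig) -> np.ndarray:
    """Frequencies of the sweep: ``start + i * increment`` for i = 0..n_steps."""
    i = np.arange(config.n_steps + 1, dtype=float)
    return config.start_frequency + i * config.frequency_increment


@dataclass
class RawSweep:
    """Uncalibrated per-frequency device readouts (Rr, Ir)."""

    frequencies: np.ndarray
    rr: np.ndarray
    ir: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.ir = np.asarray(self.ir, dtype=float)
        if not (len(self.frequencies) == len(self.rr) == len(self.ir)):
            raise ValueError("frequencies, rr and ir must have equal length")


@dataclass
class CalibrationModel:
    """Per-frequency gain factor and system phase from a reference resistor."""

    frequencies: np.ndarray
    gain_factor: np.ndarray
    system_phase: np.ndarray
    calibration_resistance: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.gain_factor = np.asarray(self.gain_factor, dtype=float)
        self.system_phase = np.asarray(self.system_phase, dtype=float)
        if np.any(self.gain_factor <= 0):
            raise CalibrationError("gain factor must be positive at every frequency")
        if np.any(self.system_phase <= -np.pi) or np.any(self.system_phase > np.pi):
            raise ValueError("system phase must lie in (-pi, pi]")


@dataclass
class ImpedanceSpectrum:
    """Calibrated impedance per frequency: magnitude, phase, real, imaginary."""

    frequencies: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray
    real_part: np.ndarray = field(default=None)  # type: ignore[assignment]
    imaginary_part: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        if self.real_part is None:
            self.real_part = self.magnitude * np.cos(self.phase)
        if self.imaginary_part is None:
            self.imaginary_part = self.magnitude * np.sin(self.phase)
        self.real_part = np.asarray(self.real_part, dtype=float)
        self.imaginary_part = np.asarray(self.imaginary_part, dtype=float)

    def restrict(self, target_frequencies) -> "ImpedanceSpectrum":
        """Restriction to a subset of frequencies; see features.select_frequencies."""
        from .features import select_frequencies

        return select_frequencies(self, target_frequencies)


def raw_magnitude(rr, ir):
    """Dimensionless readout magnitude sqrt(Rr^2 + Ir^2)."""
    return np.hypot(rr, ir)


def gain_factor(calibration_resistance: float, raw_mag) -> float | np.ndarray:
    """Gain factor FG = (1/R_cal) / raw_magnitude.

    Defined so that the calibrated impedance 1/(FG * raw_magnitude) returns
    the reference resistance on the calibration readings themselves.
    """
    if calibration_resistance <= 0:
        raise ValueError("calibration_resistance must be > 0")
    raw_mag = np.asarray(raw_mag, dtype=float)
    if np.any(raw_mag <= 0):
        raise CalibrationError("raw magnitude must be positive for calibration")
    fg = (1.0 / calibration_resistance) / raw_mag
    return float(fg) if fg.ndim == 0 else fg


def raw_phase(rr, ir):
    """Four-quadrant raw phase atan2(Ir, Rr) in (-pi, pi]."""
    rr = np.asarray(rr, dtype=float)
    ir = np.asarray(ir, dtype=float)
    if np.any((rr == 0) & (ir == 0)):
        raise CalibrationError("phase undefined for (Rr, Ir) = (0, 0)")
    ph = wrap_phase(np.arctan2(ir, rr))
    return ph


def calibrate_system(cal_sweep: RawSweep, calibration_resistance: float) -> CalibrationModel:
    """Build the per-frequency calibration from a sweep of the reference resistor."""
    mag = raw_magnitude(cal_sweep.rr, cal_sweep.ir)
    zero = np.flatnonzero(mag == 0)
    if zero.size:
        raise CalibrationError(
            f"zero raw magnitude at {cal_sweep.frequencies[zero[0]]:.0f} Hz"
        )
    fg = gain_factor(calibration_resistance, mag)
    phase_z = raw_phase(cal_sweep.rr, cal_sweep.ir)
    return CalibrationModel(
        frequencies=cal_sweep.frequencies.copy(),
        gain_factor=np.atleast_1d(fg),
        system_phase=np.atleast_1d(phase_z),
        calibration_resistance=calibration_resistance,
    )


def apply_calibration(sweep: RawSweep, model: CalibrationModel) -> ImpedanceSpectrum:
    """Convert raw readouts into a calibrated impedance spectrum."""
    if len(sweep.frequencies) != len(model.frequencies) or not np.allclose(
        sweep.frequencies, model.frequencies
    ):
        raise CalibrationError("sweep frequencies do not match the calibration model")
    mag_raw = raw_magnitude(sweep.rr, sweep.ir)
    if np.any(mag_raw == 0):
        raise CalibrationError("zero raw magnitude implies infinite impedance")
    magnitude = 1.0 / (model.gain_factor * mag_raw)
    phase_c = wrap_phase(raw_phase(sweep.rr, sweep.ir) - model.system_phase)
    return ImpedanceSpectrum(
        frequencies=sweep.frequencies.copy(),
        magnitude=magnitude,
        phase=phase_c,
    )


def error_percentage(vt: float, vm: float) -> float:
    """Absolute relative error in percent: |(vt - vm) / vt| * 100."""
    if vt == 0:
        raise ZeroDivisionError("theoretical value must be nonzero")
    return abs((vt - vm) / vt) * 100.0


def rc_series_impedance(resistance: float, capacitance: float, frequency: float):
    """Magnitude and phase of a series RC phantom at one frequency.

    The RC phantom is the bench reference used to verify calibration:
    Xc = 1/(2 pi f C), |Z| = sqrt(R^2 + Xc^2), phase = atan2(-Xc, R).
    """
    if resistance <= 0 or capacitance <= 0 or frequency <= 0:
        raise ValueError("resistance, capacitance and frequency must be > 0")
    xc = 1.0 / (2.0 * math.pi * frequency * capacitance)
    magnitude = math.hypot(resistance, xc)
    phase = math.atan2(-xc, resistance)
    return magnitude, phase
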