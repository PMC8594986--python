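"""Synthetic cohort generator with known ground truth.

The clinical dataset behind the screening device (53 participants,
34 women / 19 men, ages 19-76, 20 with diagnosed type-2 diabetes, about
5 forearm measurements each, 256 samples in total) is available only on
request, so this module emulates its statistical structure end to end:

* per subject, a magnitude spectrum following the power law
  ``|Z|(f) = a * f^b`` — the very functional form the prediction stage's
  validity check assumes — with the diabetic class carrying a higher
  coefficient ``a`` (less conductive tissue), and a smooth small negative
  phase curve (a synthetic convention; the real phase marginals are
  unpublished);
* class-dependent biometrics (diabetic subjects older and heavier on
  average, mirroring the known risk factors);
* multiplicative log-normal measurement noise per frequency, calibrated
  so repeated measurements of one subject vary by about 2% RSD;
* optional label noise: a fraction of subjects have their *recorded*
  label flipped (physiology untouched), emulating well-managed diabetics
  and undiagnosed prediabetics;
* raw device readings obtainable by inverting the calibration transform,
  so the calibration path can be exercised on synthetic data.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationModel,
    ImpedanceSpectrum,
    RawSweep,
    SweepConfig,
    wrap_phase,
)
from .features import DEFAULT_FREQUENCIES, Biometrics, build_features, feature_table


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of the emulated study cohort."""

    n_subjects: int = 53
    n_female: int = 34
    n_diabetic: int = 20
    age_range: tuple[int, int] = (19, 76)
    total_samples: int = 256
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    class_effect: float = 1.5  # multiplicative shift of the coefficient a
    biometric_shift_age: float = 12.0  # years added for diabetic subjects
    biometric_shift_weight: float = 8.0  # kg added for diabetic subjects
    baseline_magnitude: float = 200.0  # ohm at 10 kHz, nondiabetic median
    subject_sd: float = 0.10  # between-subject log-scale spread of a
    exponent_mean: float = -0.15  # power-law exponent b
    exponent_sd: float = 0.02
    noise_sd: float = 0.02  # per-frequency multiplicative log-scale noise
    label_noise: float = 0.0  # fraction of subjects with flipped recorded label
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female > self.n_subjects:
            raise ValueError("n_female cannot exceed n_subjects")
        if self.n_diabetic > self.n_subjects:
            raise ValueError("n_diabetic cannot exceed n_subjects")
        if self.total_samples < self.n_subjects:
            raise ValueError("total_samples must cover at least one per subject")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError("label_noise must be in [0, 1]")


@dataclass
class GroundTruth:
    """Per-subject generating truth plus the calibration used for raw encoding."""

    subjects: pd.DataFrame
    calibration: CalibrationModel
    spec: CohortSpec


def default_calibration_model(config: Optional[SweepConfig] = None) -> CalibrationModel:
    """A plausible synthetic instrument response over the configured sweep.

    The raw-magnitude response falls gently with frequency and the system
    phase drifts a few degrees — enough structure for the calibration
    round-trip to be non-trivial.
    """
    config = config or SweepConfig()
    f = config.frequencies
    rel = (f - f[0]) / (f[-1] - f[0])
    raw_mag = 9000.0 * (1.0 - 0.25 * rel)
    fg = (1.0 / config.calibration_resistance) / raw_mag
    system_phase = -0.05 - 0.10 * rel  # radians
    return CalibrationModel(
        frequencies=f,
        gain_factor=fg,
        system_phase=system_phase,
        calibration_resistance=config.calibration_resistance,
    )


def encode_raw(spectrum: ImpedanceSpectrum, model: CalibrationModel) -> RawSweep:
    """Invert the calibration transform: spectrum -> raw (Rr, Ir) readouts.

    ``apply_calibration(encode_raw(S, M), M)`` reproduces S to floating
    precision, letting the calibration path be tested end to end.
    """
    if len(spectrum.frequencies) != len(model.frequencies) or not np.allclose(
        spectrum.frequencies, model.frequencies
    ):
        raise ValueError("spectrum and calibration model frequencies differ")
    if np.any(model.gain_factor <= 0):
        raise ValueError("gain factor must be positive")
    if np.any(spectrum.magnitude <= 0):
        raise ValueError("cannot encode a zero-magnitude spectrum")
    raw_mag = 1.0 / (model.gain_factor * spectrum.magnitude)
    raw_ph = wrap_phase(spectrum.phase + model.system_phase)
    return RawSweep(
        frequencies=spectrum.frequencies.copy(),
        rr=raw_mag * np.cos(raw_ph),
        ir=raw_mag * np.sin(raw_ph),
    )


def _subject_truth(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_subjects
    lo, hi = spec.age_range
    sex = np.array([0] * spec.n_female + [1] * (n - spec.n_female))
    rng.shuffle(sex)
    diabetic = np.zeros(n, dtype=int)
    diabetic[rng.choice(n, size=spec.n_diabetic, replace=False)] = 1
    age = np.where(
        diabetic == 1,
        rng.integers(min(lo + int(spec.biometric_shift_age), hi - 1), hi + 1, size=n),
        rng.integers(lo, hi + 1, size=n),
    )
    weight = np.where(sex == 0, rng.normal(66.0, 10.0, n), rng.normal(79.0, 11.0, n))
    weight = np.clip(weight + diabetic * spec.biometric_shift_weight, 42.0, 150.0)
    height = np.where(sex == 0, rng.normal(160.0, 6.0, n), rng.normal(172.0, 7.0, n))
    height = np.clip(height, 142.0, 200.0)
    # power law: coefficient anchored to the magnitude at 10 kHz
    b = rng.normal(spec.exponent_mean, spec.exponent_sd, n)
    mag10k = spec.baseline_magnitude * np.exp(rng.normal(0.0, spec.subject_sd, n))
    mag10k = mag10k * np.where(diabetic == 1, spec.class_effect, 1.0)
    a = mag10k / np.power(10_000.0, b)
    phase_scale = np.abs(rng.normal(0.12, 0.02, n))  # rad at the top frequency
    label = diabetic.copy()
    n_flip = int(round(spec.label_noise * n))
    if n_flip:
        flip = rng.choice(n, size=n_flip, replace=False)
        label[flip] = 1 - label[flip]
    # allocate measurements: near-even split hitting total_samples exactly
    base = spec.total_samples // n
    extra = spec.total_samples - base * n
    counts = np.full(n, base, dtype=int)
    counts[:extra] += 1
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "weight": np.round(weight, 1),
            "height": np.round(height, 1),
            "diabetic_true": diabetic,
            "label": label,
            "a": a,
            "b": b,
            "phase_scale": phase_scale,
            "n_measurements": counts,
        }
    )


def _measurement_spectrum(
    row: pd.Series, frequencies: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> ImpedanceSpectrum:
    f = np.asarray(frequencies, dtype=float)
    mag = row["a"] * np.power(f, row["b"])
    if noise_sd > 0:
        mag = mag * np.exp(rng.normal(0.0, noise_sd, size=f.size))
    phase = -row["phase_scale"] * np.sqrt(f / f.max())
    if noise_sd > 0:
        phase = phase + rng.normal(0.0, noise_sd * 0.5, size=f.size)
    return ImpedanceSpectrum(frequencies=f, magnitude=mag, phase=wrap_phase(phase))


def generate_cohort(spec: CohortSpec = CohortSpec()) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit the cohort feature table and its generating ground truth.

    The table follows the standard schema (``subject_id, label,
    f<freq>_mag/_phase/_real/_imag ..., age, weight, sex, height``) with
    exactly ``total_samples`` rows, and is byte-identical across runs
    with the same spec.
    """
    rng = np.random.default_rng(spec.rng_seed)
    subjects = _subject_truth(spec, rng)
    freqs = np.asarray(spec.frequencies, dtype=float)
    vectors = []
    for _, row in subjects.iterrows():
        bio = Biometrics(
            age=float(row["age"]),
            weight=float(row["weight"]),
            sex=int(row["sex"]),
            height=float(row["height"]),
        )
        for _ in range(int(row["n_measurements"])):
            spectrum = _measurement_spectrum(row, freqs, spec.noise_sd, rng)
            vectors.append(
                build_features(
                    spectrum, bio, label=int(row["label"]), subject_id=row["subject_id"]
                )
            )
    table = feature_table(vectors)
    truth = GroundTruth(
        subjects=subjects, calibration=default_calibration_model(), spec=spec
    )
    return table, truth


def cohort_raw_sweeps(
    spec: CohortSpec, truth: GroundTruth, config: Optional[SweepConfig] = None
) -> list[tuple[str, RawSweep]]:
    """Raw-encoded full sweeps (one per measurement) for pipeline testing."""
    config = config or SweepConfig()
    model = default_calibration_model(config)
    rng = np.random.default_rng(spec.rng_seed + 1)
    out = []
    for _, row in truth.subjects.iterrows():
        for k in range(int(row["n_measurements"])):
            spectrum = _measurement_spectrum(row, config.frequencies, spec.noise_sd, rng)
            out.append((f"{row['subject_id']}_m{k}", encode_raw(spectrum, model)))
    return out


def stability_series(
    spec: CohortSpec = CohortSpec(), n_hours: int = 12, per_hour: int = 10
) -> pd.DataFrame:
    """Repeated measurements of one subject across simulated hours.

    Only measurement noise varies, so the per-hour relative standard
    deviation (RSD%) of any magnitude column estimates the device's
    repeatability (about 2% at the default noise level).
    """
    rng = np.random.default_rng(spec.rng_seed)
    subjects = _subject_truth(spec, rng)
    row = subjects.iloc[0]
    freqs = np.asarray(spec.frequencies, dtype=float)
    records = []
    for hour in range(n_hours):
        for m in range(per_hour):
            s = _measurement_spectrum(row, freqs, spec.noise_sd, rng)
            rec = {"hour": hour, "measurement": m}
            for f, mag in zip(freqs, s.magnitude):
                rec[f"f{int(round(f))}_mag"] = mag
            records.append(rec)
    return pd.DataFrame(records)


def null_cohort(spec: CohortSpec = CohortSpec()) -> CohortSpec:
    """Variant with no class signal (classifier should be at chance)."""
    return replace(spec, class_effect=1.0, biometric_shift_age=0.0, biometric_shift_weight=0.0)
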