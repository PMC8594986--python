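"""Feature extraction and statistical screening.

A calibrated spectrum is reduced to four working frequencies (10, 32.4,
54.8 and 77.2 kHz by default); each contributes its magnitude, phase,
real and imaginary part, and the four biometrics (age, weight, sex,
height) are appended — 20 attributes in total.  Attribute order is fixed:
per-frequency blocks of (magnitude, phase, real, imaginary), ascending
frequency, followed by age, weight, sex, height.

Screening utilities: a Pearson chi-square independence test between each
(quantile-binned) attribute and the diabetes label, and the
Hosmer–Lemeshow decile-of-risk goodness-of-fit test for a fitted
probability model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FREQUENCIES = (10_000.0, 32_400.0, 54_800.0, 77_200.0)

BIOMETRIC_NAMES = ("age", "weight", "sex", "height")

SEX_FEMALE = 0
SEX_MALE = 1


@dataclass(frozen=True)
class Biometrics:
    """Participant biometrics. Sex coding: 0 = female, 1 = male."""

    age: float  # years
    weight: float  # kg
    sex: int
    height: float  # cm

    def __post_init__(self) -> None:
        if not (0 <= self.age <= 120):
            raise ValueError("age must be in [0, 120] years")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.sex not in (SEX_FEMALE, SEX_MALE):
            raise ValueError("sex must be 0 (female) or 1 (male)")


@dataclass
class FeatureVector:
    """Ordered attribute vector with optional label and subject id."""

    values: np.ndarray
    names: list[str]
    label: Optional[int] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names must have equal length")


def impedance_feature_names(frequencies: Sequence[float]) -> list[str]:
    """Per-frequency attribute names: f<freq>_mag/_phase/_real/_imag."""
    names: list[str] = []
    for f in frequencies:
        tag = f"f{int(round(f))}"
        names += [f"{tag}_mag", f"{tag}_phase", f"{tag}_real", f"{tag}_imag"]
    return names


def feature_names(frequencies: Sequence[float] = DEFAULT_FREQUENCIES) -> list[str]:
    return impedance_feature_names(frequencies) + list(BIOMETRIC_NAMES)


def select_frequencies(spectrum, target_frequencies) -> "ImpedanceSpectrum":
    """Restrict a spectrum to the given frequencies, in the given order."""
    from .calibration import ImpedanceSpectrum

    target = np.asarray(target_frequencies, dtype=float)
    idx = []
    for f in target:
        hits = np.flatnonzero(np.isclose(spectrum.frequencies, f))
        if hits.size == 0:
            raise KeyError(f"frequency {f:.0f} Hz not present in the spectrum")
        idx.append(hits[0])
    idx = np.asarray(idx, dtype=int)
    return ImpedanceSpectrum(
        frequencies=spectrum.frequencies[idx],
        magnitude=spectrum.magnitude[idx],
        phase=spectrum.phase[idx],
        real_part=spectrum.real_part[idx],
        imaginary_part=spectrum.imaginary_part[idx],
    )


def build_features(
    spectrum,
    bio: Optional[Biometrics] = None,
    label: Optional[int] = None,
    subject_id: Optional[str] = None,
) -> FeatureVector:
    """Flatten a (restricted) spectrum + biometrics into one feature vector.

    With F frequencies the impedance block has 4*F attributes; appending
    biometrics gives 4*F + 4 (20 for the default four frequencies).
    """
    blocks = np.column_stack(
        [spectrum.magnitude, spectrum.phase, spectrum.real_part, spectrum.imaginary_part]
    ).ravel()
    names = impedance_feature_names(spectrum.frequencies)
    if bio is not None:
        blocks = np.concatenate([blocks, [bio.age, bio.weight, bio.sex, bio.height]])
        names += list(BIOMETRIC_NAMES)
    return FeatureVector(values=blocks, names=names, label=label, subject_id=subject_id)


def feature_table(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the standard cohort table."""
    if not vectors:
        raise ValueError("no feature vectors given")
    names = vectors[0].names
    rows = []
    for v in vectors:
        if v.names != names:
            raise ValueError("inconsistent attribute names across vectors")
        rows.append(v.values)
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "label", [v.label for v in vectors])
    df.insert(0, "subject_id", [v.subject_id for v in vectors])
    return df


def attribute_columns(df: pd.DataFrame) -> list[str]:
    """Attribute columns of a cohort table (everything but id/label)."""
    return [c for c in df.columns if c not in ("subject_id", "label")]


def chi_square_screen(
    features: pd.DataFrame, labels: Sequence[int], n_bins: int = 4
) -> pd.Series:
    """Per-attribute chi-square independence p-value against the label.

    Continuous attributes are quantile-binned (``n_bins`` bins, duplicate
    edges collapsed); a constant attribute carries no information and is
    reported as p = 1.  p < 0.05 flags an attribute as significant.
    """
    labels = np.asarray(labels)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples in each class")
    pvals = {}
    cols = attribute_columns(features) if any(
        c in features.columns for c in ("subject_id", "label")
    ) else list(features.columns)
    for col in cols:
        x = features[col].to_numpy(dtype=float)
        if np.all(x == x[0]):
            pvals[col] = 1.0
            continue
        if len(np.unique(x)) <= n_bins:
            # already discrete: use the values themselves as categories
            binned = pd.factorize(x)[0]
        else:
            binned = pd.qcut(x, q=n_bins, duplicates="drop", labels=False)
        if pd.Series(binned).nunique() < 2:
            pvals[col] = 1.0
            continue
        table = pd.crosstab(binned, labels)
        _, p, _, _ = stats.chi2_contingency(table.to_numpy())
        pvals[col] = float(p)
    return pd.Series(pvals, name="chi2_p")


def hosmer_lemeshow(
    labels: Sequence[int], predicted_probabilities: Sequence[float], n_groups: int = 10
) -> tuple[float, float]:
    """Hosmer–Lemeshow goodness-of-fit test.

    Samples are sorted by predicted probability into ``n_groups``
    near-equal groups; the statistic sums (observed - expected)^2/expected
    over groups and both outcomes and is referred to chi-square with
    ``n_groups - 2`` degrees of freedom.
    """
    y = np.asarray(labels, dtype=float)
    p = np.asarray(predicted_probabilities, dtype=float)
    if len(y) != len(p):
        raise ValueError("labels and probabilities must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    n = len(y)
    if n < n_groups:
        raise ValueError("need at least as many samples as groups")
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    if min(len(g) for g in groups) < 2:
        raise ValueError("degenerate grouping: fewer than 2 samples per group")
    stat = 0.0
    for g in groups:
        obs1 = y[g].sum()
        exp1 = p[g].sum()
        exp0 = len(g) - exp1
        if exp1 <= 0 or exp0 <= 0:
            raise ValueError("expected count of zero in a group; reduce n_groups")
        stat += (obs1 - exp1) ** 2 / exp1 + ((len(g) - obs1) - exp0) ** 2 / exp0
    pvalue = float(stats.chi2.sf(stat, df=n_groups - 2))
    return float(stat), pvalue
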