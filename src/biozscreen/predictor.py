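"""Voting prediction with a power-law measurement-validity check.

A screening decision is made from a batch of repeated measurements
(10 on the device).  The magnitude spectrum of biological tissue follows
a decreasing power law in frequency, y = a * x^b; each measurement's
magnitudes are fitted in log-log space and measurements whose fit
correlation falls below a threshold (artefacts: loose electrodes,
movement) are excluded.  Every valid measurement is classified and the
class wins only if its share of the valid votes reaches the voting
threshold (80%); otherwise the result is "undefined".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import ClassifierModel

DECISION_DIABETIC = "diabetic"
DECISION_NONDIABETIC = "nondiabetic"
DECISION_UNDEFINED = "undefined"

_CLASS_NAME = {1: DECISION_DIABETIC, 0: DECISION_NONDIABETIC}


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of y = a * x^b in log-log space."""

    a: float
    b: float
    r_squared: float


@dataclass
class VoteResult:
    decision: str
    agreement: Optional[float]
    n_valid: int
    per_measurement: list[dict]
    reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "decision": self.decision,
            "agreement": self.agreement,
            "n_valid": self.n_valid,
            "reason": self.reason,
            "per_measurement": self.per_measurement,
        }


def fit_power_law(frequencies, magnitudes) -> PowerLawFit:
    """Fit y = a * x^b by linear regression of ln y on ln x.

    Returns the coefficient a, exponent b, and the r^2 of the log-log
    regression.  A constant spectrum is an exact power law with b = 0 and
    is reported with r^2 = 1.
    """
    x = np.asarray(frequencies, dtype=float)
    y = np.asarray(magnitudes, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 (frequency, magnitude) points")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("power-law fit requires positive frequencies and magnitudes")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (intercept + slope * lx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return PowerLawFit(a=float(np.exp(intercept)), b=float(slope), r_squared=r2)


def validate_measurement(fit: PowerLawFit, r2_threshold: float = 0.90) -> bool:
    """A measurement is physically plausible iff r^2 >= threshold."""
    return fit.r_squared >= r2_threshold


def magnitude_columns(names: Sequence[str]) -> tuple[list[str], np.ndarray]:
    """Magnitude attribute columns (f<freq>_mag) and their frequencies, ascending."""
    pairs = []
    for n in names:
        if n.startswith("f") and n.endswith("_mag"):
            try:
                pairs.append((float(n[1:-4]), n))
            except ValueError:
                continue
    pairs.sort()
    if len(pairs) < 3:
        raise ValueError("need at least 3 magnitude attributes for the validity check")
    return [n for _, n in pairs], np.array([f for f, _ in pairs])


def vote_predict(
    model: ClassifierModel,
    measurements: pd.DataFrame,
    vote_threshold: float = 0.80,
    r2_threshold: float = 0.90,
    min_valid: int = 5,
) -> VoteResult:
    """Classify a batch of repeated measurements and vote on the outcome.

    ``measurements`` holds one row per measurement in the feature-table
    schema (an optional ``measurement_id`` column tags rows).  Invalid
    measurements (power-law fit below ``r2_threshold``) are excluded from
    the vote; agreement is the modal-class share among valid measurements
    and the comparison with ``vote_threshold`` is closed (8/10 passes at
    0.8).  Fewer than ``min_valid`` valid measurements yields an
    undefined decision with a quality flag.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements given")
    mids = (
        list(measurements["measurement_id"])
        if "measurement_id" in measurements.columns
        else list(range(len(measurements)))
    )
    feats = measurements[list(model.attribute_names)]
    mag_cols, freqs = magnitude_columns(model.attribute_names)
    per = []
    votes = []
    for i in range(len(measurements)):
        row = feats.iloc[i]
        fit = fit_power_law(freqs, row[mag_cols].to_numpy(dtype=float))
        entry = {
            "measurement_id": mids[i],
            "r2": fit.r_squared,
            "a": fit.a,
            "b": fit.b,
            "valid": validate_measurement(fit, r2_threshold),
            "class": None,
            "probability": None,
        }
        if entry["valid"]:
            p = float(model.predict_probability(row.to_numpy(dtype=float))[0])
            cls = int(p >= model.threshold)
            entry["class"] = _CLASS_NAME[cls]
            entry["probability"] = p
            votes.append(cls)
        per.append(entry)
    n_valid = len(votes)
    if n_valid < min_valid:
        return VoteResult(
            decision=DECISION_UNDEFINED,
            agreement=None,
            n_valid=n_valid,
            per_measurement=per,
            reason="insufficient valid measurements",
        )
    counts = np.bincount(votes, minlength=2)
    modal = int(np.argmax(counts))
    agreement = counts[modal] / n_valid
    if agreement >= vote_threshold:
        return VoteResult(
            decision=_CLASS_NAME[modal],
            agreement=float(agreement),
            n_valid=n_valid,
            per_measurement=per,
        )
    return VoteResult(
        decision=DECISION_UNDEFINED,
        agreement=float(agreement),
        n_valid=n_valid,
        per_measurement=per,
        reason="vote below threshold",
    )
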