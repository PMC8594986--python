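"""Logistic-regression screening classifier with portable persistence.

The decision function is P = 1 / (1 + exp(-h)) with h = w . x_std + b,
where x_std is the z-scored attribute vector (scaler parameters learned
on the training data and stored with the model).  Training delegates to
scikit-learn's L-BFGS solver; prediction is computed directly from the
stored weights so that the JSON and C-header exports round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression


@dataclass
class ClassifierModel:
    """Fitted logistic model plus the standardization it was trained with."""

    attribute_names: list[str]
    weights: np.ndarray  # coefficients on the standardized scale
    bias: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    solver_tag: str = "lbfgs"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_sd = np.asarray(self.scaler_sd, dtype=float)
        n = len(self.attribute_names)
        if not (len(self.weights) == len(self.scaler_mean) == len(self.scaler_sd) == n):
            raise ValueError("weights and scaler lengths must match attribute count")

    # -- prediction ---------------------------------------------------------

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.attribute_names):
            raise ValueError(
                f"expected {len(self.attribute_names)} attributes, got {X.shape[1]}"
            )
        return X

    def decision_value(self, X) -> np.ndarray:
        X = self._check(X)
        xs = (X - self.scaler_mean) / self.scaler_sd
        return xs @ self.weights + self.bias

    def predict_probability(self, X) -> np.ndarray:
        """P = 1/(1 + e^-h) per sample."""
        h = self.decision_value(X)
        return 1.0 / (1.0 + np.exp(-h))

    def predict(self, X) -> np.ndarray:
        return (self.predict_probability(X) >= self.threshold).astype(int)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "attribute_names": list(self.attribute_names),
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "scaler": {
                    "means": self.scaler_mean.tolist(),
                    "sds": self.scaler_sd.tolist(),
                },
                "solver_tag": self.solver_tag,
                "threshold": self.threshold,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            attribute_names=list(d["attribute_names"]),
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            scaler_mean=np.asarray(d["scaler"]["means"], dtype=float),
            scaler_sd=np.asarray(d["scaler"]["sds"], dtype=float),
            solver_tag=d.get("solver_tag", "lbfgs"),
            threshold=float(d.get("threshold", 0.5)),
        )


def standardization_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and standard deviations; constant columns get sd = 1."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def train_logistic(
    X,
    labels,
    attribute_names: Optional[Sequence[str]] = None,
    C: float = 1.0,
    seed: int = 0,
    scaler: Optional[tuple[np.ndarray, np.ndarray]] = None,
    threshold: float = 0.5,
) -> ClassifierModel:
    """Fit the regularized logistic model (L-BFGS) on standardized attributes.

    ``scaler`` may pin pre-computed (mean, sd) — used by the active-training
    loop, where standardization is frozen at seeding time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x attributes)")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if attribute_names is None:
        attribute_names = [f"x{i}" for i in range(X.shape[1])]
    if scaler is None:
        mean, sd = standardization_params(X)
    else:
        mean, sd = (np.asarray(scaler[0], dtype=float), np.asarray(scaler[1], dtype=float))
    Xs = (X - mean) / sd
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, random_state=seed)
    clf.fit(Xs, y)
    return ClassifierModel(
        attribute_names=list(attribute_names),
        weights=clf.coef_[0],
        bias=float(clf.intercept_[0]),
        scaler_mean=mean,
        scaler_sd=sd,
        solver_tag="lbfgs",
        threshold=threshold,
    )


# -- microcontroller export -------------------------------------------------

_HEADER_TEMPLATE = """\
/* Logistic screening model — auto-generated; do not edit by hand.
 * P = 1 / (1 + exp(-(dot(W, (x - MU) / SIGMA) + B)))
 */
#ifndef BIOZSCREEN_MODEL_H
#define BIOZSCREEN_MODEL_H

#define N_FEATURES {n}

static const float W[N_FEATURES] = {{
{w}
}};
static const float B = {b}f;
static const float MU[N_FEATURES] = {{
{mu}
}};
static const float SIGMA[N_FEATURES] = {{
{sigma}
}};
/* threshold on P */
static const float THRESHOLD = {thr}f;

#endif /* BIOZSCREEN_MODEL_H */
"""


def _c_array(values: np.ndarray) -> str:
    return ",\n".join(f"    {float(v):.9g}f" for v in values)


def export_header(model: ClassifierModel) -> str:
    """Render the model as a C header for microcontroller deployment.

    Constants are emitted at float32 precision; predictions reconstructed
    from the header agree with the stored model to ~1e-5.
    """
    return _HEADER_TEMPLATE.format(
        n=len(model.attribute_names),
        w=_c_array(model.weights),
        b=f"{model.bias:.9g}",
        mu=_c_array(model.scaler_mean),
        sigma=_c_array(model.scaler_sd),
        thr=f"{model.threshold:.9g}",
    )


def parse_header(text: str) -> ClassifierModel:
    """Re-parse an exported header back into a model (testing/round-trip aid)."""
    import re

    def grab_array(name: str) -> np.ndarray:
        m = re.search(rf"{name}\[N_FEATURES\]\s*=\s*\{{(.*?)\}};", text, re.S)
        if m is None:
            raise ValueError(f"array {name} not found in header")
        vals = [float(v.strip().rstrip("f")) for v in m.group(1).split(",") if v.strip()]
        return np.asarray(vals, dtype=float)

    def grab_scalar(name: str) -> float:
        m = re.search(rf"float {name} = ([-0-9.eE+]+)f?;", text)
        if m is None:
            raise ValueError(f"scalar {name} not found in header")
        return float(m.group(1))

    w = grab_array("W")
    return ClassifierModel(
        attribute_names=[f"x{i}" for i in range(len(w))],
        weights=w,
        bias=grab_scalar("B"),
        scaler_mean=grab_array("MU"),
        scaler_sd=grab_array("SIGMA"),
        solver_tag="header",
        threshold=grab_scalar("THRESHOLD"),
    )
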