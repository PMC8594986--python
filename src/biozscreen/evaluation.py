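"""Repeated cross-validated comparison of traditional training vs ATSS.

Protocol: the cohort is split into stratified folds (grouped by subject,
so a participant's repeated measurements never straddle the train/test
boundary); per repeat a fresh seeded shuffle defines the folds and the
ATSS streaming order.  Each fold yields one test-set accuracy for the
traditionally trained logistic model (full training fold) and one for
the ATSS model, giving repeats x folds paired values per method —
150 at the default 30 repeats x 5 folds.  The paired lists feed a
two-sided Wilcoxon signed-rank test; pooled test predictions give each
method's Cohen kappa; silhouette summaries mirror the cohesion gain of
the selected population over the raw training data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .atss import run_atss, silhouette_widths
from .classifier import standardization_params, train_logistic
from .features import attribute_columns
from .metrics import cohen_kappa, wilcoxon_signed_rank


@dataclass
class ComparisonReport:
    accuracy_traditional: list[float]
    accuracy_atss: list[float]
    mean_traditional: float
    sd_traditional: float
    mean_atss: float
    sd_atss: float
    kappa_traditional: Optional[float]
    kappa_atss: Optional[float]
    wilcoxon_p: Optional[float]
    sw_summary: dict
    repeats: int
    folds: int

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "folds": self.folds,
            "mean_accuracy": {
                "traditional": self.mean_traditional,
                "atss": self.mean_atss,
            },
            "sd_accuracy": {"traditional": self.sd_traditional, "atss": self.sd_atss},
            "kappa": {"traditional": self.kappa_traditional, "atss": self.kappa_atss},
            "wilcoxon_p": self.wilcoxon_p,
            "sw_summary": self.sw_summary,
            "accuracy_traditional": self.accuracy_traditional,
            "accuracy_atss": self.accuracy_atss,
        }


def compare_methods(
    dataset: pd.DataFrame,
    repeats: int = 30,
    folds: int = 5,
    base_seed: int = 0,
    group_by_subject: bool = True,
    atss_fraction: float = 0.10,
    atss_capacity: Optional[int] = None,
    atss_monitor_fraction: float = 0.20,
) -> ComparisonReport:
    """Run the full repeated-CV comparison on a cohort feature table."""
    if repeats < 1 or folds < 2:
        raise ValueError("need repeats >= 1 and folds >= 2")
    cols = attribute_columns(dataset)
    X = dataset[cols].to_numpy(dtype=float)
    y = dataset["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    groups = (
        dataset["subject_id"].to_numpy()
        if group_by_subject and "subject_id" in dataset.columns
        else None
    )
    seeds = np.random.SeedSequence(base_seed).generate_state(2 * repeats) % (2**31)
    acc_trad: list[float] = []
    acc_atss: list[float] = []
    pooled = {"trad_y": [], "trad_p": [], "atss_y": [], "atss_p": []}
    seed_sw_means: list[float] = []
    final_sw_means: list[float] = []
    train_sw_means: list[float] = []
    for r in range(repeats):
        split_seed = int(seeds[2 * r])
        order_seed = int(seeds[2 * r + 1])
        if groups is not None:
            cv = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=split_seed)
            split_iter = cv.split(X, y, groups=groups)
        else:
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)
            split_iter = cv.split(X, y)
        for fold, (tr, te) in enumerate(split_iter):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValueError("a fold lost one of the classes; check stratification")
            model_t = train_logistic(X[tr], y[tr], attribute_names=cols)
            pred_t = model_t.predict(X[te])
            acc_trad.append(float(np.mean(pred_t == y[te])))
            ids_tr = list(groups[tr]) if groups is not None else None
            model_a, state = run_atss(
                X[tr],
                y[tr],
                ids=ids_tr,
                capacity=atss_capacity,
                fraction=atss_fraction,
                monitor_fraction=atss_monitor_fraction,
                order_seed=order_seed + fold,
                attribute_names=cols,
            )
            pred_a = model_a.predict(X[te])
            acc_atss.append(float(np.mean(pred_a == y[te])))
            pooled["trad_y"] += list(y[te])
            pooled["trad_p"] += list(pred_t)
            pooled["atss_y"] += list(y[te])
            pooled["atss_p"] += list(pred_a)
            seed_sw_means.append(state.seed_sw_mean)
            train_sw_means.append(state.train_sw_mean)
            mean, sd = state.scaler
            final_sw_means.append(
                float(np.mean(silhouette_widths((state.X_pop - mean) / sd, state.y_pop).s))
            )
    try:
        wp = wilcoxon_signed_rank(acc_atss, acc_trad)
    except ValueError:
        wp = None  # e.g. all paired differences zero on a toy dataset
    sw_summary = {
        "mean_sw_full_training": float(np.mean(train_sw_means)),
        "mean_sw_seed": float(np.mean(seed_sw_means)),
        "mean_sw_final_population": float(np.mean(final_sw_means)),
        "sw_gain_final_vs_full": float(np.mean(final_sw_means) - np.mean(train_sw_means)),
    }
    return ComparisonReport(
        accuracy_traditional=acc_trad,
        accuracy_atss=acc_atss,
        mean_traditional=float(np.mean(acc_trad)),
        sd_traditional=float(np.std(acc_trad, ddof=1)) if len(acc_trad) > 1 else 0.0,
        mean_atss=float(np.mean(acc_atss)),
        sd_atss=float(np.std(acc_atss, ddof=1)) if len(acc_atss) > 1 else 0.0,
        kappa_traditional=cohen_kappa(pooled["trad_y"], pooled["trad_p"]),
        kappa_atss=cohen_kappa(pooled["atss_y"], pooled["atss_p"]),
        wilcoxon_p=wp,
        sw_summary=sw_summary,
        repeats=repeats,
        folds=folds,
    )


def pca_2d(features, standardize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Project a feature table onto its top two principal components.

    Returns (n x 2 coordinates, explained-variance ratios).  Purely a
    visual diagnostic — no decision logic depends on it.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 attributes")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all samples identical")
    if standardize:
        mean, sd = standardization_params(X)
        X = (X - mean) / sd
    pca = PCA(n_components=2)
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_
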