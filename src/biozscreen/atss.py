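"""Active training by seed selection (ATSS).

The training set is not used wholesale.  Instead:

1.  Per-sample silhouette widths are computed on the standardized
    attributes: for sample i, ``a_i`` is the mean Euclidean distance to
    the other members of its own class, ``b_i`` the mean distance to the
    opposite class, and

        s_i = 1 - a_i / b_i   if a_i < b_i
        s_i = 0               if a_i = b_i
        s_i = b_i / a_i - 1   if a_i > b_i

    so s_i lies in [-1, 1] and a large s_i means the sample sits firmly
    inside its labelled class.

2.  A seed population — the top 10% of training samples by silhouette
    width, selected within each class — trains an initial logistic model.

3.  The remaining samples are streamed in random order.  A candidate is
    considered only if its silhouette width (w.r.t. the current
    population plus itself) exceeds the population's current minimum
    (condition 1).  It is then tentatively added (or, at capacity,
    swapped for the minimum-silhouette member), the model retrained, and
    the change kept only if accuracy on a held-out monitor set does not
    drop while precision or recall strictly improves (condition 2).

The result is a compact, high-cohesion training population; with noisy
labels it filters out misleading samples that would otherwise degrade
the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .classifier import ClassifierModel, standardization_params, train_logistic
from .metrics import performance

_ROUND = 12  # indicator comparisons rounded to 1e-12 to suppress float noise


@dataclass
class SilhouetteScores:
    """Per-sample silhouette components and widths."""

    a: np.ndarray  # mean within-class distance
    b: np.ndarray  # mean other-class distance
    s: np.ndarray  # silhouette width in [-1, 1]


def silhouette_widths(X, labels) -> SilhouetteScores:
    """Silhouette widths of every sample under its binary class label.

    Expects standardized attributes: Euclidean distance across raw
    ohm / year / kg scales would be dominated by the largest-scaled
    attribute.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and labels must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need samples from both classes")
    if counts.min() < 2:
        raise ValueError("a class with a single sample has undefined cohesion a_i")
    D = cdist(X, X)
    a = np.empty(n)
    b = np.empty(n)
    for c in classes:
        mask = y == c
        other = ~mask
        # exclude self from the within-class mean
        a[mask] = D[np.ix_(mask, mask)].sum(axis=1) / (mask.sum() - 1)
        b[mask] = D[np.ix_(mask, other)].mean(axis=1)
    s = np.where(a < b, 1.0 - a / b, np.where(a > b, b / a - 1.0, 0.0))
    return SilhouetteScores(a=a, b=b, s=s)


@dataclass
class AtssState:
    """Capacity-bounded training population with its fitted model."""

    X_pop: np.ndarray
    y_pop: np.ndarray
    ids_pop: list
    order_added: list[int]
    sw: np.ndarray
    capacity: int
    model: ClassifierModel
    X_monitor: np.ndarray
    y_monitor: np.ndarray
    attribute_names: list[str]
    scaler: tuple[np.ndarray, np.ndarray]
    seed_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    history: list[dict] = field(default_factory=list)
    indicators: dict = field(default_factory=dict)
    seed_sw_mean: float = float("nan")
    train_sw_mean: float = float("nan")
    _counter: int = 0

    @property
    def population_size(self) -> int:
        return len(self.y_pop)


def _indicators(model: ClassifierModel, X_mon, y_mon) -> dict:
    rep = performance(y_mon, model.predict(X_mon))
    return {"accuracy": rep.accuracy, "precision": rep.precision, "recall": rep.recall}


def _increased(new: Optional[float], old: Optional[float]) -> bool:
    """Strict indicator improvement; an undefined (0/0) new value never counts."""
    if new is None:
        return False
    if old is None:
        return True
    return round(new, _ROUND) > round(old, _ROUND)


def _not_decreased(new: float, old: float) -> bool:
    return round(new, _ROUND) >= round(old, _ROUND)


def _stratified_topk(s: np.ndarray, y: np.ndarray, k: int, floor: int = 2) -> np.ndarray:
    """Indices of the k highest-silhouette samples, allocated per class.

    Per-class quotas are proportional (largest-remainder rounding) with a
    floor per class, so the seed always contains both classes even when a
    global top-k would not.  The floor of 2 keeps every class's cohesion
    term a_i defined within the selected population.
    """
    classes = list(np.unique(y))
    n = len(y)
    sizes = {c: int(np.sum(y == c)) for c in classes}
    if min(sizes.values()) < floor:
        raise ValueError(f"each class needs at least {floor} samples")
    k = max(k, floor * len(classes))
    quota = {}
    frac = {}
    for c in classes:
        exact = k * sizes[c] / n
        quota[c] = min(sizes[c], max(floor, int(math.floor(exact))))
        frac[c] = exact - math.floor(exact)
    while sum(quota.values()) < k:
        grow = [c for c in classes if quota[c] < sizes[c]]
        if not grow:
            break
        c = max(grow, key=lambda cc: (frac[cc], -quota[cc]))
        quota[c] += 1
        frac[c] = -1.0
    while sum(quota.values()) > k:
        shrink = [c for c in classes if quota[c] > floor]
        if not shrink:
            break
        c = max(shrink, key=lambda cc: quota[cc])
        quota[c] -= 1
    chosen = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        top = idx[np.argsort(-s[idx], kind="stable")[: quota[c]]]
        chosen.append(top)
    return np.sort(np.concatenate(chosen))


def select_seed(
    X,
    labels,
    fraction: float = 0.10,
    ids: Optional[Sequence] = None,
    X_monitor=None,
    y_monitor=None,
    capacity: Optional[int] = None,
    scaler: Optional[tuple[np.ndarray, np.ndarray]] = None,
    attribute_names: Optional[Sequence[str]] = None,
) -> AtssState:
    """Build the initial ATSS state from the top-silhouette seed samples.

    The seed size is ceil(fraction * n) (minimum 2, at least one per
    class); the initial model is trained on the seed alone.  The scaler,
    fixed here, is used for all subsequent silhouette and model
    computations of the run.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if ids is None:
        ids = list(range(n))
    if scaler is None:
        scaler = standardization_params(X)
    mean, sd = scaler
    Xs = (X - mean) / sd
    scores = silhouette_widths(Xs, y)
    k = max(2, math.ceil(fraction * n))
    if k > n:
        raise ValueError("seed larger than the training set")
    seed_idx = _stratified_topk(scores.s, y, k)
    X_seed, y_seed = X[seed_idx], y[seed_idx]
    if capacity is None:
        capacity = max(k, math.ceil(0.6 * n))
    if capacity < k:
        raise ValueError("capacity smaller than the seed size")
    if attribute_names is None:
        attribute_names = [f"x{i}" for i in range(X.shape[1])]
    if X_monitor is None or y_monitor is None:
        raise ValueError("a labeled monitor set is required for indicator gating")
    X_monitor = np.atleast_2d(np.asarray(X_monitor, dtype=float))
    y_monitor = np.asarray(y_monitor, dtype=int)
    model = train_logistic(X_seed, y_seed, attribute_names=attribute_names, scaler=scaler)
    sw_seed = silhouette_widths((X_seed - mean) / sd, y_seed).s
    state = AtssState(
        X_pop=X_seed.copy(),
        y_pop=y_seed.copy(),
        ids_pop=[ids[i] for i in seed_idx],
        order_added=list(range(len(seed_idx))),
        sw=sw_seed,
        capacity=capacity,
        model=model,
        X_monitor=X_monitor,
        y_monitor=y_monitor,
        attribute_names=list(attribute_names),
        scaler=(np.asarray(mean, dtype=float), np.asarray(sd, dtype=float)),
        seed_indices=seed_idx,
        seed_sw_mean=float(np.mean(sw_seed)),
        train_sw_mean=float(np.mean(scores.s)),
    )
    state._counter = len(seed_idx)
    state.indicators = _indicators(model, X_monitor, y_monitor)
    return state


def consider_sample(state: AtssState, x, label: int, sample_id=None) -> str:
    """Offer one labelled candidate to the population; returns the decision.

    Decisions: ``"accepted"`` (population grew), ``"replaced"`` (swapped
    for the minimum-silhouette member, earliest-added on ties) or
    ``"rejected"``.  The state mutates only on commit; every
    consideration is appended to ``state.history``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(state.attribute_names):
        raise ValueError("candidate attribute count does not match the model")
    mean, sd = state.scaler
    s_min = float(state.sw.min())
    # candidate silhouette w.r.t. the current population including itself
    X_aug = np.vstack([state.X_pop, x])
    y_aug = np.append(state.y_pop, label)
    s_cand = float(silhouette_widths((X_aug - mean) / sd, y_aug).s[-1])
    old = state.indicators
    record = {
        "step": len(state.history),
        "id": sample_id,
        "decision": "rejected",
        "s_candidate": s_cand,
        "s_min": s_min,
        "acc_before": old["accuracy"],
        "acc_after": None,
        "prec_before": old["precision"],
        "prec_after": None,
        "rec_before": old["recall"],
        "rec_after": None,
        "prec_delta": None,
        "rec_delta": None,
    }
    if s_cand <= s_min:
        state.history.append(record)
        return "rejected"

    if state.population_size >= state.capacity:
        # replace the minimum-silhouette member; ties -> earliest added
        cand_idx = np.flatnonzero(state.sw == state.sw.min())
        drop = cand_idx[np.argmin([state.order_added[i] for i in cand_idx])]
        keep = np.ones(state.population_size, dtype=bool)
        keep[drop] = False
        X_new = np.vstack([state.X_pop[keep], x])
        y_new = np.append(state.y_pop[keep], label)
        ids_new = [v for v, k in zip(state.ids_pop, keep) if k] + [sample_id]
        order_new = [v for v, k in zip(state.order_added, keep) if k] + [state._counter]
        decision_if_commit = "replaced"
    else:
        X_new = np.vstack([state.X_pop, x])
        y_new = np.append(state.y_pop, label)
        ids_new = state.ids_pop + [sample_id]
        order_new = state.order_added + [state._counter]
        decision_if_commit = "accepted"

    counts = np.bincount(y_new, minlength=2)
    if counts.min() < 2:
        state.history.append(record)
        return "rejected"

    model_new = train_logistic(
        X_new, y_new, attribute_names=state.attribute_names, scaler=state.scaler
    )
    ind_new = _indicators(model_new, state.X_monitor, state.y_monitor)
    record["acc_after"] = ind_new["accuracy"]
    record["prec_after"] = ind_new["precision"]
    record["rec_after"] = ind_new["recall"]
    if ind_new["precision"] is not None and old["precision"] is not None:
        record["prec_delta"] = ind_new["precision"] - old["precision"]
    if ind_new["recall"] is not None and old["recall"] is not None:
        record["rec_delta"] = ind_new["recall"] - old["recall"]
    ok = _not_decreased(ind_new["accuracy"], old["accuracy"]) and (
        _increased(ind_new["precision"], old["precision"])
        or _increased(ind_new["recall"], old["recall"])
    )
    if not ok:
        state.history.append(record)
        return "rejected"

    state.X_pop, state.y_pop = X_new, y_new
    state.ids_pop, state.order_added = ids_new, order_new
    state.sw = silhouette_widths((X_new - mean) / sd, y_new).s
    state.model = model_new
    state.indicators = ind_new
    state._counter += 1
    record["decision"] = decision_if_commit
    state.history.append(record)
    return decision_if_commit


def _split_monitor(
    y: np.ndarray, ids, monitor_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (pool, monitor). Group-aware when subject ids are present.

    Subjects (groups of repeated measurements) are never split across the
    pool/monitor boundary, and both sides keep both classes.
    """
    n = len(y)
    if ids is not None:
        subjects: dict = {}
        for i, sid in enumerate(ids):
            subjects.setdefault(sid, []).append(i)
        sids = np.array(list(subjects.keys()), dtype=object)
        slabels = np.array([y[subjects[s][0]] for s in sids])
        mon_subj = []
        for c in np.unique(slabels):
            csubj = sids[slabels == c]
            csubj = csubj[rng.permutation(len(csubj))]
            n_mon = max(1, int(round(monitor_fraction * len(csubj))))
            n_mon = min(n_mon, len(csubj) - 1)
            mon_subj += list(csubj[:n_mon])
        mon = np.array(sorted(i for s in mon_subj for i in subjects[s]), dtype=int)
    else:
        picks: list[int] = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            idx = idx[rng.permutation(len(idx))]
            n_mon = max(1, int(round(monitor_fraction * len(idx))))
            n_mon = min(n_mon, len(idx) - 1)
            picks += list(idx[:n_mon])
        mon = np.asarray(sorted(picks), dtype=int)
    pool = np.setdiff1d(np.arange(n), mon)
    return pool, mon


def run_atss(
    X,
    labels,
    ids: Optional[Sequence] = None,
    capacity: Optional[int] = None,
    fraction: float = 0.10,
    monitor_fraction: float = 0.20,
    order_seed: int = 0,
    attribute_names: Optional[Sequence[str]] = None,
) -> tuple[ClassifierModel, AtssState]:
    """Full ATSS run: monitor split, seeding, then streamed consideration.

    The streaming order is a seeded random permutation of the non-seed
    pool samples; rejected samples are not re-offered.  Capacity defaults
    to 60% of the pool.  Returns the final model and the state (with the
    complete accept/reject history).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(order_seed)
    pool_idx, mon_idx = _split_monitor(y, ids, monitor_fraction, rng)
    X_pool, y_pool = X[pool_idx], y[pool_idx]
    ids_pool = [ids[i] for i in pool_idx] if ids is not None else list(pool_idx)
    if capacity is None:
        capacity = math.ceil(0.6 * len(pool_idx))
    scaler = standardization_params(X_pool)
    state = select_seed(
        X_pool,
        y_pool,
        fraction=fraction,
        ids=ids_pool,
        X_monitor=X[mon_idx],
        y_monitor=y[mon_idx],
        capacity=capacity,
        scaler=scaler,
        attribute_names=attribute_names,
    )
    seed_set = set(state.seed_indices.tolist())
    remaining = [i for i in range(len(y_pool)) if i not in seed_set]
    order = rng.permutation(len(remaining))
    for j in order:
        i = remaining[j]
        consider_sample(state, X_pool[i], int(y_pool[i]), sample_id=ids_pool[i])
    return state.model, state


def replay_history(state: AtssState) -> bool:
    """Verify from the history log that every commit obeyed both rules.

    Committed samples must have passed the silhouette gate
    (s_candidate > s_min) and the indicator gate (monitor accuracy
    non-decreasing, precision or recall strictly higher); the monitor
    accuracy sequence across the whole run must never decrease.
    """
    prev_acc = None
    for rec in state.history:
        if prev_acc is not None and round(rec["acc_before"], _ROUND) < round(prev_acc, _ROUND):
            return False
        if rec["decision"] in ("accepted", "replaced"):
            if not rec["s_candidate"] > rec["s_min"]:
                return False
            if rec["acc_after"] is None or not _not_decreased(
                rec["acc_after"], rec["acc_before"]
            ):
                return False
            if not (
                _increased(rec["prec_after"], rec["prec_before"])
                or _increased(rec["rec_after"], rec["rec_before"])
            ):
                return False
            prev_acc = rec["acc_after"]
        else:
            prev_acc = rec["acc_before"]
    return True
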