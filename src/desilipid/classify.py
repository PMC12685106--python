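"""Recursive maximum margin criterion discriminant analysis with LOPO CV.

The maximum margin criterion seeks directions w maximizing
tr(w'(S_b - S_w)w), where S_b and S_w are the between- and within-class
scatter matrices of the mean-centered data.  Components are extracted
recursively: the leading eigenvector of the symmetrized (S_b - S_w) is
taken, the data are deflated onto its orthogonal complement, the scatters
are recomputed, and the next component extracted — k times.  Class
assignment is nearest class mean in the projected score space.

Unlike Fisher LDA this eigenproblem needs no inversion of S_w, so it is
stable when features outnumber samples, the usual regime for MSI peak
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, FittingError, FoldError

_ORTHO_TOL = 1e-8


@dataclass
class ClassModel:
    projection: np.ndarray            # (n_features, k), unit-norm orthogonal columns
    class_means: dict[str, np.ndarray]  # label -> score-space mean (k,)
    scatter_between: np.ndarray
    scatter_within: np.ndarray
    k: int
    class_labels: tuple[str, str]
    feature_means: np.ndarray
    feature_scales: np.ndarray        # ones when standardize=False


@dataclass
class ConfusionMatrix:
    """Counts with cancer (the configured positive label) as positive class."""

    tp: int
    fn: int
    tn: int
    fp: int


def _scatters(X: np.ndarray, labels: np.ndarray, classes: tuple[str, str]):
    mu = X.mean(axis=0)
    Xc = X - mu
    p = X.shape[1]
    Sb = np.zeros((p, p))
    Sw = np.zeros((p, p))
    for c in classes:
        Xi = Xc[labels == c]
        mi = Xi.mean(axis=0)
        d = mi[:, None]
        Sb += Xi.shape[0] * (d @ d.T)
        R = Xi - mi
        Sw += R.T @ R
    return Sb, Sw


def fit_rmmc(
    profiles: np.ndarray,
    labels,
    k: int = 1,
    standardize: bool = True,
    class_order: tuple[str, str] | None = None,
    calibrate: str = "loo",
    patient_ids=None,
    min_class_size: int = 2,
) -> ClassModel:
    """Fit the maximum-margin-criterion projection and class means.

    ``class_order`` fixes the declared label order used for tie-breaking in
    prediction; by default labels are taken in sorted order.

    With ``calibrate="loo"`` (default) the score-space class means are
    estimated from leave-one-out scores — each sample (or each patient,
    when ``patient_ids`` is given) is scored by a projection refit without
    it.  In-sample scores are optimistically displaced away from the
    boundary, and far more so for the smaller class, which biases the
    nearest-mean rule on high-dimensional peak matrices; the leave-one-out
    means estimate where *unseen* profiles of each class actually score.
    ``calibrate="none"`` keeps the classical in-sample means.
    """
    X = np.asarray(profiles, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != labels.shape[0]:
        raise FittingError("profiles and labels are misaligned")
    classes = class_order or tuple(sorted(np.unique(labels)))
    if len(classes) != 2:
        raise FittingError(f"expected exactly 2 classes, got {classes}")
    for c in classes:
        if (labels == c).sum() < min_class_size:
            raise FittingError(
                f"class {c!r} has fewer than {min_class_size} samples"
            )
    if not (1 <= k <= min(X.shape[1], X.shape[0] - 1)):
        raise FittingError(f"k={k} outside [1, min(features, samples-1)]")

    feat_mu = X.mean(axis=0)
    if standardize:
        feat_sd = X.std(axis=0, ddof=1)
        feat_sd[feat_sd == 0] = 1.0
    else:
        feat_sd = np.ones(X.shape[1])
    Z = (X - feat_mu) / feat_sd

    comps: list[np.ndarray] = []
    D = Z.copy()
    p = Z.shape[1]
    Sb0 = Sw0 = None
    # complement basis: extracted components are removed from the search
    # space, so each step solves the eigenproblem strictly within the
    # orthogonal complement of the components found so far
    Q = np.eye(p)
    for _ in range(k):
        Sb, Sw = _scatters(D, labels, classes)
        if Sb0 is None:
            Sb0, Sw0 = Sb, Sw
        M = Sb - Sw
        M = (M + M.T) / 2.0  # suppress float asymmetry
        Mq = Q.T @ M @ Q
        _vals, vecs = np.linalg.eigh(Mq)
        w = Q @ vecs[:, -1]
        nw = np.linalg.norm(w)
        if nw < _ORTHO_TOL:
            raise FittingError("deflated data admit no further component")
        w = w / nw
        # fix sign deterministically: largest-magnitude loading positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        comps.append(w)
        D = D - np.outer(D @ w, w)
        # shrink the complement basis by the new component
        proj = Q.T @ w
        basis = np.linalg.svd(np.eye(Q.shape[1]) - np.outer(proj, proj))[0]
        Q = Q @ basis[:, : Q.shape[1] - 1]
    W = np.column_stack(comps)

    scores = Z @ W
    class_means = {c: scores[labels == c].mean(axis=0) for c in classes}
    if calibrate == "loo":
        loo = _loo_class_means(
            X, labels, k, standardize, classes, patient_ids
        )
        if loo is not None:
            class_means = loo
    elif calibrate != "none":
        raise FittingError(f"unknown calibrate option {calibrate!r}")
    return ClassModel(
        projection=W,
        class_means=class_means,
        scatter_between=Sb0,
        scatter_within=Sw0,
        k=k,
        class_labels=classes,
        feature_means=feat_mu,
        feature_scales=feat_sd,
    )


def _loo_class_means(X, labels, k, standardize, classes, patient_ids):
    """Score-space class means from leave-one-out scores.

    Returns None when a class is too small to refit without one member
    (the caller then keeps the in-sample means).
    """
    groups = np.asarray(patient_ids) if patient_ids is not None else np.arange(len(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 3:
        return None
    collected: dict[str, list] = {c: [] for c in classes}
    for g in dict.fromkeys(groups.tolist()):
        held = groups == g
        rest = ~held
        rest_counts = [int(((labels == c) & rest).sum()) for c in classes]
        if min(rest_counts) < 2:
            continue
        sub = fit_rmmc(
            X[rest], labels[rest], k=k, standardize=standardize,
            class_order=classes, calibrate="none",
        )
        s = transform(sub, X[held])
        for lab, row in zip(labels[held], s):
            collected[lab].append(row)
    if any(len(v) == 0 for v in collected.values()):
        return None
    return {c: np.mean(collected[c], axis=0) for c in classes}


def transform(model: ClassModel, profiles: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(profiles, dtype=np.float64))
    if X.shape[1] != model.projection.shape[0]:
        raise DimensionError(
            f"profile length {X.shape[1]} != model feature count "
            f"{model.projection.shape[0]}"
        )
    return ((X - model.feature_means) / model.feature_scales) @ model.projection


def predict(model: ClassModel, profile: np.ndarray) -> tuple[str, np.ndarray]:
    """Nearest-class-mean assignment; exact ties go to the first declared label."""
    s = transform(model, profile)[0]
    d = {c: float(np.linalg.norm(s - m)) for c, m in model.class_means.items()}
    a, b = model.class_labels
    label = a if d[a] <= d[b] else b
    return label, s


def margin_criterion(model: ClassModel) -> float:
    """tr(W'(S_b - S_w)W) of the fitted projection — the objective value."""
    W = model.projection
    return float(np.trace(W.T @ (model.scatter_between - model.scatter_within) @ W))


def lopo_cv(
    profiles: np.ndarray,
    labels,
    patient_ids,
    k: int = 1,
    standardize: bool = True,
    positive_label: str = "cancer",
    class_order: tuple[str, str] | None = None,
    calibrate: str = "loo",
):
    """Leave-one-patient-out cross-validation.

    All rows of the held-out patient are excluded from the training fold;
    the refit model predicts them and the patient-level call is the majority
    vote (ties toward the positive label).  Returns the patient-level
    confusion matrix and a per-patient prediction table.
    """
    X = np.asarray(profiles, dtype=np.float64)
    labels = np.asarray(labels)
    pids = np.asarray(patient_ids)
    if not (X.shape[0] == labels.shape[0] == pids.shape[0]):
        raise FittingError("profiles, labels, patient_ids misaligned")

    records = []
    tp = fn = tn = fp = 0
    for pid in sorted(dict.fromkeys(pids.tolist())):
        held = pids == pid
        train = ~held
        truth = labels[held]
        if len(set(truth.tolist())) != 1:
            raise FoldError(f"patient {pid!r} carries conflicting labels")
        if len(set(labels[train].tolist())) < 2:
            raise FoldError(f"training fold for patient {pid!r} lost a class")
        assert not np.any(pids[train] == pid)  # no within-patient leakage
        model = fit_rmmc(
            X[train], labels[train], k=k, standardize=standardize,
            class_order=class_order, calibrate=calibrate,
            patient_ids=pids[train], min_class_size=1,
        )
        calls = [predict(model, x)[0] for x in X[held]]
        n_pos = sum(c == positive_label for c in calls)
        call = positive_label if n_pos * 2 >= len(calls) else next(
            c for c in model.class_labels if c != positive_label
        )
        score = float(np.mean([predict(model, x)[1][0] for x in X[held]]))
        records.append(
            {"patient_id": pid, "truth": truth[0], "call": call, "score1": score}
        )
        if truth[0] == positive_label:
            tp += call == positive_label
            fn += call != positive_label
        else:
            tn += call != positive_label
            fp += call == positive_label
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp), records


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise FittingError("metrics undefined: an empty class")
    total = cm.tp + cm.fn + cm.tn + cm.fp
    return {
        "sensitivity": cm.tp / (cm.tp + cm.fn),
        "specificity": cm.tn / (cm.tn + cm.fp),
        "accuracy": (cm.tp + cm.tn) / total,
    }
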