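"""SVM backward elimination with Kullback-Leibler error and panel scoring.

The discovery engine repeatedly (default 10x) splits the cohort into
stratified training (2/3 per group) and test sets.  On each training set a
linear SVM (cost 1) drives a backward elimination: at every round each
remaining antibody is tentatively removed, the K-L classification error of
the reduced panel is measured on internally cross-validated decision
values, and the antibody whose removal gives the smallest K-L error is
eliminated.  This prunes antibodies carrying redundant information and
yields a complete elimination order per training set.

The K-L error of a panel is the cross-entropy between the true labels and
logistically mapped SVM decision values — the Kullback-Leibler divergence
from the point-mass truth to the predicted class probability, summed over
samples:

    p_i = 1 / (1 + exp(-d_i)),   clipped to [1e-6, 1 - 1e-6]
    KL  = sum_i  -log p_i  (if y_i = +1)  else  -log(1 - p_i)

Each antibody's *endurance* is its removal position (1 = first out,
N = last survivor); the mean endurance over repeats ranks antibodies, and
the top-k (default 25) form the consensus panel.  Per repeat, a model on
the last-25-surviving antibodies is trained, frozen, and evaluated on the
held-out test set (AUC, and sensitivity/specificity/PPV/NPV at decision
threshold zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .io import ExpressionMatrix

__all__ = [
    "SplitSpec",
    "DiscoveryConfig",
    "EliminationTrace",
    "PanelEvaluation",
    "PanelSVC",
    "BackwardEliminationSVM",
    "stratified_split",
    "train_linear_svm",
    "cv_decision_values",
    "kl_error",
    "backward_eliminate",
    "antibody_scores",
    "consensus_panel",
    "kl_minimum_panel",
    "evaluate_panel",
    "roc_auc",
    "run_signature_discovery",
]


@dataclass
class SplitSpec:
    """Repeated stratified train/test splitting parameters.

    ``train_fraction`` of each group (floor) goes to training; repeats use
    distinct seed-derived streams.  ``assignments`` is filled by
    :func:`stratified_split`: one ``sample_id -> {"train", "test"}`` map
    per repeat.
    """

    train_fraction: float = 2.0 / 3.0
    n_repeats: int = 10
    seed: int = 0
    assignments: list[dict[str, str]] = field(default_factory=list)


@dataclass
class DiscoveryConfig:
    """End-to-end signature-discovery parameters (defaults follow the
    published procedure: 2/3 split, 10 repeats, linear SVM with cost 1,
    25-antibody panels; the internal 5-fold CV supplies unbiased decision
    values during elimination)."""

    train_fraction: float = 2.0 / 3.0
    n_repeats: int = 10
    panel_size: int = 25
    cost: float = 1.0
    k_folds: int = 5
    seed: int = 0


@dataclass
class EliminationTrace:
    """Complete removal order for one training set.

    ``removal_order[0]`` is the first antibody eliminated; the final
    survivor closes the permutation.  ``kl_curve`` maps panel size to the
    K-L error of the panel of that size (the full-panel error at size N,
    then the error after each elimination round down to size 1).
    """

    removal_order: list[str]
    kl_curve: pd.Series  # index: panel size (N..1), values: K-L error
    repeat_index: int = 0

    def surviving_panel(self, size: int) -> list[str]:
        """Panel of the ``size`` longest-surviving antibodies."""
        if not 1 <= size <= len(self.removal_order):
            raise ValueError(f"size must be in 1..{len(self.removal_order)}")
        return sorted(self.removal_order[len(self.removal_order) - size:])


@dataclass
class PanelEvaluation:
    """Frozen-model test-set performance (percent scale for the point
    metrics; AUC in [0, 1])."""

    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    decision_values: pd.Series
    threshold: float = 0.0
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # TP, FP, TN, FN


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


try:  # fast path for the elimination hot loop: call libsvm without the
    # per-fit estimator scaffolding; parity with SVC is covered by tests
    from sklearn.svm import _libsvm as _raw_libsvm

    _raw_libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _raw_libsvm = None


def _linear_svm_decision(
    Xtr: np.ndarray, ybin: np.ndarray, Xte: np.ndarray, C: float
) -> np.ndarray:
    """Decision values of a linear C-SVC for test rows (positive = +1 class).

    Identical model to ``SVC(kernel="linear", C=C)`` (same libsvm solver
    and tolerance); the raw libsvm decision sign is flipped to sklearn's
    convention, where positive values predict the larger class label.
    """
    if _raw_libsvm is None:  # pragma: no cover
        svc = SVC(kernel="linear", C=C)
        svc.fit(Xtr, ybin)
        return svc.decision_function(Xte)
    res = _raw_libsvm.fit(
        np.ascontiguousarray(Xtr),
        np.ascontiguousarray(ybin, dtype=np.float64),
        svm_type=0,
        kernel="linear",
        C=C,
        tol=1e-3,
    )
    w = (res[3] @ res[1]).ravel()
    b = float(res[4][0])
    return -(Xte @ w + b)


def stratified_split(
    labels: pd.Series,
    groups: tuple[str, str],
    spec: SplitSpec,
) -> SplitSpec:
    """Assign samples to train/test, stratified per group, per repeat.

    ``labels`` maps sample_id to group; only samples of the two contrast
    groups are assigned.  Per repeat and group, exactly
    ``floor(train_fraction * n)`` samples go to training.
    """
    labels = pd.Series(labels)
    rngs = _rng_streams(spec.seed, spec.n_repeats)
    assignments: list[dict[str, str]] = []
    for g in groups:
        n_g = int((labels == g).sum())
        if n_g < 3:
            raise ValueError(f"group {g!r} has {n_g} samples; need >=3 to split")
    for rng in rngs:
        assign: dict[str, str] = {}
        for g in groups:
            ids = labels.index[labels == g].to_numpy()
            n_train = int(np.floor(spec.train_fraction * len(ids)))
            order = rng.permutation(len(ids))
            for k, i in enumerate(order):
                assign[ids[i]] = "train" if k < n_train else "test"
        assignments.append(assign)
    return SplitSpec(
        train_fraction=spec.train_fraction,
        n_repeats=spec.n_repeats,
        seed=spec.seed,
        assignments=assignments,
    )


class PanelSVC(ClassifierMixin, BaseEstimator):
    """Linear SVM on a fixed antibody panel with training-set standardization.

    Features are standardized with training-set mean/sd only (stored on the
    fitted model), preventing information leak into evaluation.  The
    positive class is ``positive_class`` (decision values > 0 predict it);
    by default the lexicographically later label, but discovery always
    passes the first-listed contrast group (the disease group).

    Fitted attributes: ``coef_`` (weights on the standardized scale),
    ``intercept_``, ``mean_``, ``scale_``, ``panel_``, ``classes_``.
    """

    def __init__(self, panel: list[str] | None = None, cost: float = 1.0,
                 positive_class: str | None = None, tol: float = 1e-6):
        self.panel = panel
        self.cost = cost
        self.positive_class = positive_class
        self.tol = tol  # tight solver tolerance: frozen models are reported

    def _select(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = self.panel if self.panel is not None else list(X.columns)
            return X[cols].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        Xa = self._select(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"PanelSVC is a binary classifier; got classes {classes}")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise ValueError(f"positive_class {pos!r} absent from training labels")
        neg = classes[classes != pos][0]
        ybin = np.where(y == pos, 1, -1)
        self.mean_ = Xa.mean(axis=0)
        sd = Xa.std(axis=0, ddof=1)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (Xa - self.mean_) / self.scale_
        svc = SVC(kernel="linear", C=self.cost, tol=self.tol)
        svc.fit(Z, ybin)
        self.coef_ = svc.coef_.ravel().copy()
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = np.array([neg, pos], dtype=object)
        self.panel_ = list(self.panel) if self.panel is not None else (
            list(X.columns) if isinstance(X, pd.DataFrame) else
            [f"x{i}" for i in range(Xa.shape[1])]
        )
        self.n_features_in_ = Xa.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        Z = (self._select(X) - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])


def train_linear_svm(
    m: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    panel: list[str],
    cost: float = 1.0,
    positive_class: str | None = None,
) -> PanelSVC:
    """Fit a frozen linear-kernel SVM (cost-of-constraints C) on a panel."""
    values = m.values if isinstance(m, ExpressionMatrix) else m
    labels = pd.Series(labels).loc[values.index.intersection(pd.Series(labels).index)]
    values = values.loc[labels.index]
    missing = [a for a in panel if a not in values.columns]
    if missing:
        raise ValueError(f"panel antibodies missing from matrix: {missing[:5]}")
    model = PanelSVC(panel=list(panel), cost=cost, positive_class=positive_class)
    return model.fit(values, labels.to_numpy())


def _stratified_folds(ybin: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold id per sample; every fold contains both classes.

    ``k`` is reduced (with a warning) when it exceeds the minority-class
    count, so no fold-model ever trains on a single class.
    """
    n_min = min(int((ybin == 1).sum()), int((ybin == -1).sum()))
    if n_min < 2:
        raise ValueError("need at least 2 samples of each class for CV")
    if k > n_min:
        warnings.warn(f"reducing k_folds from {k} to {n_min} (minority class size)")
        k = n_min
    folds = np.empty(len(ybin), dtype=int)
    for cls in (1, -1):
        idx = np.nonzero(ybin == cls)[0]
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % k
    return folds


def _cv_decisions_panel(
    X: np.ndarray, ybin: np.ndarray, folds: np.ndarray, cost: float
) -> np.ndarray:
    """Cross-validated decision values for one feature subset (array path)."""
    d = np.empty(len(ybin))
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        Xtr = X[tr]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        d[te] = _linear_svm_decision((Xtr - mu) / sd, ybin[tr], (X[te] - mu) / sd, cost)
    return d


def cv_decision_values(
    m: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    panel: list[str],
    k_folds: int = 5,
    seed: int = 0,
    cost: float = 1.0,
    positive_class: str | None = None,
) -> pd.Series:
    """Per-sample decision values from stratified k-fold cross-validation.

    Each sample's value comes from the fold model that did not train on
    it, so downstream K-L errors are not resubstitution-biased.
    ``k_folds=len(samples_of_minority_class)`` gives leave-one-out on the
    minority class.  Deterministic per seed.
    """
    values = m.values if isinstance(m, ExpressionMatrix) else m
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(values.index)]
    values = values.loc[labels.index]
    classes = np.unique(labels.to_numpy())
    if len(classes) != 2:
        raise ValueError("cv_decision_values needs exactly 2 classes")
    pos = positive_class if positive_class is not None else classes[-1]
    ybin = np.where(labels.to_numpy() == pos, 1, -1)
    X = values[list(panel)].to_numpy(dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    folds = _stratified_folds(ybin, k_folds, rng)
    d = _cv_decisions_panel(X, ybin, folds, cost)
    return pd.Series(d, index=values.index)


def kl_error(decision_values, labels) -> float:
    """Kullback-Leibler classification error (nats; lower is better).

    Decision values are mapped to class probabilities through the logistic
    link and the K-L divergence from the point-mass truth (equivalently
    the total cross-entropy) is summed over samples.  Probabilities are
    clipped to [1e-6, 1-1e-6] so confident mistakes stay finite.
    """
    d = np.asarray(
        decision_values.to_numpy() if isinstance(decision_values, pd.Series)
        else decision_values,
        dtype=float,
    )
    if d.size == 0:
        raise ValueError("empty decision-value vector")
    if not np.all(np.isfinite(d)):
        raise ValueError("decision values must be finite")
    y = np.asarray(labels.to_numpy() if isinstance(labels, pd.Series) else labels)
    if y.dtype != np.dtype(int) and not np.issubdtype(y.dtype, np.number):
        raise ValueError("labels must be +1/-1 integers for kl_error")
    p = 1.0 / (1.0 + np.exp(-d))
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    return float(np.sum(np.where(y == 1, -np.log(p), -np.log1p(-p))))


class BackwardEliminationSVM(BaseEstimator):
    """Backward feature elimination driven by cross-validated K-L error.

    ``fit(X, y)`` runs the full elimination on one training set: at every
    round, each remaining antibody is tentatively removed, the K-L error
    of the reduced panel computed from stratified-CV decision values
    (fold assignment fixed per round, shared across candidates), and the
    antibody whose removal minimizes the K-L error eliminated (ties
    broken lexicographically).  Redundant antibodies fall early because
    removing one of two correlated markers barely changes the error.

    Fitted attributes: ``removal_order_`` (first-out first),
    ``kl_curve_`` (pd.Series indexed by panel size, from the full panel
    down to a single antibody), ``support_`` / ``panel_`` for the
    ``panel_size`` longest survivors.
    """

    def __init__(self, cost: float = 1.0, k_folds: int = 5, seed: int = 0,
                 panel_size: int = 25, positive_class: str | None = None):
        self.cost = cost
        self.k_folds = k_folds
        self.seed = seed
        self.panel_size = panel_size
        self.positive_class = positive_class

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             columns=[f"x{i}" for i in range(np.shape(X)[1])])
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("binary labels required")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        ybin = np.where(y == pos, 1, -1)
        names = list(X.columns)
        if len(names) < 2:
            raise ValueError("need at least 2 antibodies to eliminate")
        Xa = X.to_numpy(dtype=float)

        n = len(names)
        round_rngs = _rng_streams(self.seed, n)
        alive = list(range(n))  # column indices, kept in lexicographic name order
        alive.sort(key=lambda j: names[j])
        removal: list[int] = []
        kl_curve: dict[int, float] = {}

        folds0 = _stratified_folds(ybin, self.k_folds, round_rngs[0])
        d_full = _cv_decisions_panel(Xa[:, alive], ybin, folds0, self.cost)
        kl_curve[n] = kl_error(d_full, ybin)

        for round_idx in range(n - 1):
            rng = round_rngs[round_idx]
            folds = _stratified_folds(ybin, self.k_folds, rng)
            uniq = np.unique(folds)
            # standardize the current panel once per fold; dropping a
            # candidate column afterwards equals standardizing the subset
            sub = Xa[:, alive]
            fold_Z: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
            for f in uniq:
                tr, te = folds != f, folds == f
                Xtr = sub[tr]
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=1)
                sd = np.where(sd > 0, sd, 1.0)
                fold_Z.append(((Xtr - mu) / sd, (sub[te] - mu) / sd, te))
            best_kl, best_pos = np.inf, 0
            mask = np.ones(len(alive), dtype=bool)
            d = np.empty(len(ybin))
            for c in range(len(alive)):
                mask[c] = False
                for (Ztr, Zte, te), f in zip(fold_Z, uniq):
                    d[te] = _linear_svm_decision(
                        Ztr[:, mask], ybin[folds != f], Zte[:, mask], self.cost
                    )
                kl = kl_error(d, ybin)
                mask[c] = True
                if kl < best_kl:  # candidates visited in lexicographic order,
                    best_kl, best_pos = kl, c  # so strict < breaks ties that way
            removal.append(alive.pop(best_pos))
            kl_curve[len(alive)] = best_kl
        removal.append(alive[0])  # final survivor closes the permutation

        self.removal_order_ = [names[j] for j in removal]
        self.kl_curve_ = pd.Series(kl_curve).sort_index(ascending=False)
        self.kl_curve_.index.name = "panel_size"
        size = min(self.panel_size, n)
        self.panel_ = sorted(self.removal_order_[n - size:])
        self.support_ = np.array([a in set(self.panel_) for a in names])
        self.feature_names_in_ = np.array(names, dtype=object)
        return self

    def trace(self, repeat_index: int = 0) -> EliminationTrace:
        return EliminationTrace(
            removal_order=list(self.removal_order_),
            kl_curve=self.kl_curve_.copy(),
            repeat_index=repeat_index,
        )


def backward_eliminate(
    m: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    cost: float = 1.0,
    k_folds: int = 5,
    start_panel: list[str] | None = None,
    positive_class: str | None = None,
    repeat_index: int = 0,
) -> EliminationTrace:
    """Functional wrapper over :class:`BackwardEliminationSVM`."""
    values = m.values if isinstance(m, ExpressionMatrix) else m
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(values.index)]
    values = values.loc[labels.index]
    if start_panel is not None:
        values = values[list(start_panel)]
    est = BackwardEliminationSVM(
        cost=cost, k_folds=k_folds, seed=seed, positive_class=positive_class
    ).fit(values, labels.to_numpy())
    return est.trace(repeat_index=repeat_index)


def antibody_scores(traces: list[EliminationTrace]) -> pd.DataFrame:
    """Endurance scores: mean removal position per antibody over repeats.

    Position 1 = first eliminated, N = last survivor, so the sum of scores
    is always N(N+1)/2.  Returns a DataFrame with ``score`` and the
    per-repeat ``endurances``, sorted descending by score (ties broken
    lexicographically).
    """
    if not traces:
        raise ValueError("no elimination traces given")
    ref = sorted(traces[0].removal_order)
    for t in traces:
        if sorted(t.removal_order) != ref:
            raise ValueError("traces cover different antibody sets")
    positions = {a: [] for a in ref}
    for t in traces:
        for pos, a in enumerate(t.removal_order, start=1):
            positions[a].append(pos)
    df = pd.DataFrame(
        {
            "score": [float(np.mean(positions[a])) for a in ref],
            "endurances": [positions[a] for a in ref],
        },
        index=pd.Index(ref, name="antibody_id"),
    )
    df["_ab"] = df.index.astype(str)
    df = df.sort_values(["score", "_ab"], ascending=[False, True],
                        kind="mergesort").drop(columns="_ab")
    return df


def consensus_panel(
    scores: pd.DataFrame, k: int = 25, annotation: pd.DataFrame | None = None
) -> dict:
    """Top-k antibodies by endurance score and the distinct antigens among
    them (n_nonredundant; a panel of k clones may target fewer antigens)."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds {len(scores)} scored antibodies")
    ranked = scores.copy()
    ranked["_ab"] = ranked.index.astype(str)
    ranked = ranked.sort_values(["score", "_ab"], ascending=[False, True],
                                kind="mergesort")
    panel = list(ranked.index[:k])
    if annotation is not None:
        ant = annotation.set_index("antibody_id")["antigen"]
        antigens = {str(ant.get(a, a)) for a in panel}
    else:
        antigens = set(panel)
    return {"panel": panel, "n_nonredundant": len(antigens)}


def kl_minimum_panel(trace: EliminationTrace) -> dict:
    """Panel size minimizing the K-L curve (ties -> smaller panel), with
    the surviving antibodies at that size."""
    curve = trace.kl_curve
    kl_min = float(curve.min())
    sizes = curve.index[curve.to_numpy() == kl_min]
    size = int(min(sizes))
    return {
        "panel_size": size,
        "kl_min": kl_min,
        "panel": trace.surviving_panel(size),
    }


def roc_auc(decision_values, ybin) -> float:
    """AUC as the Mann-Whitney rank statistic (ties counted 1/2)."""
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(ybin)
    pos, neg = d[y == 1], d[y != 1]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: test set is missing a class")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


def evaluate_panel(
    model: PanelSVC,
    m_test: ExpressionMatrix | pd.DataFrame,
    labels_test: pd.Series,
    threshold: float = 0.0,
) -> PanelEvaluation:
    """Apply a frozen model to an independent test set.

    AUC is the Mann-Whitney rank statistic over decision values;
    sensitivity/specificity/PPV/NPV come from the confusion matrix at the
    decision threshold (default 0).  When the test set lacks one class,
    AUC is reported NaN while the point metrics are still computed.
    Evaluation never alters model state.
    """
    values = m_test.values if isinstance(m_test, ExpressionMatrix) else m_test
    labels_test = pd.Series(labels_test)
    labels_test = labels_test[labels_test.index.isin(values.index)]
    values = values.loc[labels_test.index]
    d = model.decision_function(values)
    pos_label = model.classes_[1]
    y = np.where(labels_test.to_numpy() == pos_label, 1, -1)
    pred_pos = d > threshold
    tp = int(np.sum(pred_pos & (y == 1)))
    fp = int(np.sum(pred_pos & (y == -1)))
    tn = int(np.sum(~pred_pos & (y == -1)))
    fn = int(np.sum(~pred_pos & (y == 1)))

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else float("nan")

    try:
        auc = roc_auc(d, y)
    except ValueError:
        warnings.warn("test set missing a class; AUC undefined (NaN)")
        auc = float("nan")
    return PanelEvaluation(
        auc=auc,
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        decision_values=pd.Series(d, index=values.index),
        threshold=threshold,
        confusion=(tp, fp, tn, fn),
    )


def run_signature_discovery(
    m: ExpressionMatrix | pd.DataFrame,
    labels: pd.Series,
    contrast: tuple[str, str],
    config: DiscoveryConfig | None = None,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Full repeated-split discovery for one two-group contrast.

    For each repeat: stratified 2/3 split -> backward elimination on the
    training set -> model on the ``panel_size`` longest survivors, frozen
    -> evaluation on the test set.  Endurance scores aggregate the repeats
    into a consensus panel.  Returns a dict with ``traces``, ``scores``,
    ``consensus``, ``evaluations``, ``kl_minima`` and a ``summary`` of
    mean test metrics.  Deterministic per config seed.
    """
    config = config or DiscoveryConfig()
    values = m.values if isinstance(m, ExpressionMatrix) else m
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(values.index)]
    g1, g2 = contrast
    keep = labels.isin([g1, g2])
    labels = labels[keep]
    values = values.loc[labels.index]

    split_seed, elim_seed = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(2)
    ]
    spec = stratified_split(
        labels,
        (g1, g2),
        SplitSpec(
            train_fraction=config.train_fraction,
            n_repeats=config.n_repeats,
            seed=split_seed,
        ),
    )
    elim_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(elim_seed).spawn(config.n_repeats)
    ]

    traces: list[EliminationTrace] = []
    evaluations: list[PanelEvaluation] = []
    kl_minima: list[dict] = []
    for r, assign in enumerate(spec.assignments):
        train_ids = [s for s, part in assign.items() if part == "train"]
        test_ids = [s for s, part in assign.items() if part == "test"]
        trace = backward_eliminate(
            values.loc[train_ids],
            labels.loc[train_ids],
            seed=elim_seeds[r],
            cost=config.cost,
            k_folds=config.k_folds,
            positive_class=g1,
            repeat_index=r,
        )
        traces.append(trace)
        kl_minima.append(kl_minimum_panel(trace))
        panel = trace.surviving_panel(min(config.panel_size, len(trace.removal_order)))
        model = train_linear_svm(
            values.loc[train_ids], labels.loc[train_ids], panel,
            cost=config.cost, positive_class=g1,
        )
        evaluations.append(evaluate_panel(model, values.loc[test_ids],
                                          labels.loc[test_ids]))

    scores = antibody_scores(traces)
    consensus = consensus_panel(scores, k=min(config.panel_size, len(scores)),
                                annotation=annotation)
    summary = {
        "contrast": f"{g1}:{g2}",
        "n_repeats": config.n_repeats,
        "panel_size": config.panel_size,
        "mean_auc": float(np.nanmean([e.auc for e in evaluations])),
        "mean_sensitivity": float(np.nanmean([e.sensitivity for e in evaluations])),
        "mean_specificity": float(np.nanmean([e.specificity for e in evaluations])),
        "mean_ppv": float(np.nanmean([e.ppv for e in evaluations])),
        "mean_npv": float(np.nanmean([e.npv for e in evaluations])),
        "mean_kl_min": float(np.mean([km["kl_min"] for km in kl_minima])),
        "mean_kl_min_panel_size": float(np.mean([km["panel_size"] for km in kl_minima])),
    }
    return {
        "traces": traces,
        "scores": scores,
        "consensus": consensus,
        "evaluations": evaluations,
        "kl_minima": kl_minima,
        "summary": summary,
        "splits": spec,
    }
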