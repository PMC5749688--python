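"""Participant-independent nested 3-fold cross-validation with a linear
maximum-margin classifier.

Per fold rotation (fold i test, fold i+1 validation, remainder train):
features are standardized to training statistics, minority classes are
upsampled in whole-set copies, the complexity parameter C is tuned on the
validation set over a fixed log grid, the classifier is retrained on the
concatenated train+validation data with the tuned C, and predictions are
emitted for the fold's test set plus nine bootstrap resamples of it —
30 evaluation sets in total for k=3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from appraisal_decode.features import FeatureTable
from appraisal_decode.stats import uar

C_GRID = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
N_BOOTSTRAP = 9


@dataclass(frozen=True)
class FoldPlan:
    """Participant-disjoint k-way partition."""

    assignment: dict[str, int]
    k: int = 3

    def __post_init__(self) -> None:
        folds = set(self.assignment.values())
        if folds != set(range(self.k)):
            raise ValueError(f"fold indices must be exactly 0..{self.k - 1}")
        sizes = self.fold_sizes
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes {sizes} differ by more than 1")

    @property
    def fold_sizes(self) -> list[int]:
        return [sum(1 for f in self.assignment.values() if f == i) for i in range(self.k)]

    def members(self, fold: int) -> list[str]:
        return [p for p, f in self.assignment.items() if f == fold]

    def rotation(self, i: int) -> tuple[list[str], list[str], list[str]]:
        """(train, validation, test) participants for rotation i: fold i is
        test, fold i+1 is validation, the remainder trains."""
        test = self.members(i % self.k)
        val = self.members((i + 1) % self.k)
        train = [
            p for p, f in self.assignment.items()
            if f not in (i % self.k, (i + 1) % self.k)
        ]
        return train, val, test


def make_folds(participants: Sequence[str], k: int = 3, seed: int = 0) -> FoldPlan:
    """Seeded random partition of participants into k near-equal folds."""
    ids = list(dict.fromkeys(participants))
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} participants")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    base, extra = divmod(len(ids), k)
    assignment: dict[str, int] = {}
    pos = 0
    for f in range(k):
        size = base + (1 if f < extra else 0)
        for p in order[pos:pos + size]:
            assignment[p] = f
        pos += size
    return FoldPlan(assignment=dict(sorted(assignment.items())), k=k)


@dataclass
class Standardizer:
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)  # constant columns: center only
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def standardize(
    train: np.ndarray, *others: np.ndarray
) -> tuple[list[np.ndarray], Standardizer]:
    """Z-score every set by the training set's column means and sds."""
    if train.shape[0] == 0:
        raise ValueError("empty training set")
    st = Standardizer.fit(train)
    return [st.transform(train)] + [st.transform(o) for o in others], st


def upsample_minority(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate each minority class in whole-set copies.

    The copy count per class minimizes the distance to the majority count;
    ties go to fewer copies.  The majority class is untouched and the output
    order (majority-order-preserving, copies appended class by class) is
    deterministic.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts == 0).any() or len(classes) == 0:
        raise ValueError("every class must have at least one instance")
    majority = counts.max()
    keep = [np.arange(len(y))]
    for cls, count in zip(classes, counts):
        base = majority // count
        lo, hi = base * count, (base + 1) * count
        copies = base if (majority - lo) <= (hi - majority) else base + 1
        idx = np.flatnonzero(y == cls)
        for _ in range(copies - 1):
            keep.append(idx)
    sel = np.concatenate(keep)
    return X[sel], y[sel]


def train_linear(X: np.ndarray, y: np.ndarray, C: float) -> SVC:
    """Fit a linear maximum-margin classifier with box constraint C.

    Multi-class problems are handled one-vs-one (libsvm voting).  Training is
    deterministic for fixed inputs.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if not np.isfinite(X).all():
        raise ValueError("training features must be finite")
    model = SVC(kernel="linear", C=C, decision_function_shape="ovo")
    model.fit(X, y)
    return model


def tune_C(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    grid: Sequence[float] = C_GRID,
) -> float:
    """Grid value maximizing validation UAR; ties resolve to the smallest C."""
    best_c, best_uar = None, -np.inf
    for c in sorted(grid):
        model = train_linear(X_train, y_train, c)
        score = uar(y_val, model.predict(X_val))
        if score > best_uar:
            best_c, best_uar = c, score
    return best_c


@dataclass
class EvalSet:
    fold: int
    kind: str  # "test" | "bootstrap"
    replicate: int  # 0 for the original test set, 1..9 for resamples
    y_true: np.ndarray
    y_pred: np.ndarray


@dataclass
class SicvResult:
    eval_sets: list[EvalSet]
    plan: FoldPlan
    chosen_C: dict[int, float]
    n_test: dict[int, int]
    classes: tuple
    seed: int = 0

    @property
    def uars(self) -> np.ndarray:
        return np.array([uar(e.y_true, e.y_pred) for e in self.eval_sets])


def run_sicv(
    table: FeatureTable,
    seed: int = 0,
    grid: Sequence[float] = C_GRID,
    n_bootstrap: int = N_BOOTSTRAP,
    plan: Optional[FoldPlan] = None,
) -> SicvResult:
    """Run the full nested cross-validation on a feature table.

    Emits ``k * (1 + n_bootstrap)`` (= 30 for the default protocol)
    evaluation sets with provenance.  Fully reproducible given
    ``(table, seed)``; no participant ever appears on both sides of a
    train/test split.
    """
    participants = np.asarray(table.participants)
    y = np.asarray(table.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    if plan is None:
        plan = make_folds(list(dict.fromkeys(participants)), k=3, seed=seed)
    ss = np.random.SeedSequence([seed, 0xB007])
    fold_rngs = [np.random.default_rng(s) for s in ss.spawn(plan.k)]

    eval_sets: list[EvalSet] = []
    chosen: dict[int, float] = {}
    n_test: dict[int, int] = {}
    for i in range(plan.k):
        train_p, val_p, test_p = plan.rotation(i)
        tr = np.isin(participants, train_p)
        va = np.isin(participants, val_p)
        te = np.isin(participants, test_p)

        # development phase: train-statistics standardization, upsampled
        # training set, C tuned on the validation set
        (X_tr, X_va), _ = standardize(table.X[tr], table.X[va])
        X_tr_b, y_tr_b = upsample_minority(X_tr, y[tr])
        c = tune_C(X_tr_b, y_tr_b, X_va, y[va], grid)
        chosen[i] = c

        # final phase: train+validation become the training set
        dev = tr | va
        (X_dev, X_te), _ = standardize(table.X[dev], table.X[te])
        X_dev_b, y_dev_b = upsample_minority(X_dev, y[dev])
        model = train_linear(X_dev_b, y_dev_b, c)

        y_te = y[te]
        pred = model.predict(X_te)
        n = len(y_te)
        n_test[i] = n
        eval_sets.append(EvalSet(i, "test", 0, y_te.copy(), pred.copy()))
        rng = fold_rngs[i]
        for r in range(1, n_bootstrap + 1):
            idx = rng.integers(0, n, size=n)
            eval_sets.append(EvalSet(i, "bootstrap", r, y_te[idx], pred[idx]))
    return SicvResult(
        eval_sets=eval_sets,
        plan=plan,
        chosen_C=chosen,
        n_test=n_test,
        classes=tuple(np.unique(y)),
        seed=seed,
    )
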