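"""Classification and validation: all-pairs ECOC linear SVM, k-fold
cross-validation with a fully re-fit selection chain per fold, pooled
confusion metrics, grand block averages, and the accuracy sweep utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .selection import R2Selector, SubgroupPCA, SubjectScaler
from .types import CLASS_CODES, EvalReport, FeatureTable, Recording

CODE_TO_LABEL = {v: k for k, v in CLASS_CODES.items()}


class PairwiseECOC(BaseEstimator, ClassifierMixin):
    """All-pairs error-correcting output code over linear SVMs.

    One soft-margin linear SVM is trained per unordered class pair
    (C(C-1)/2 learners for C classes).  A test point gets the label that
    minimizes the aggregate Hamming loss over the learners' binary outputs;
    with the all-pairs code matrix (0 entries ignored) this is max-wins
    voting, ties broken toward the lowest class code.

    The windowing design leaves classes unbalanced: rest windows come from
    four times as many blocks as any one task condition, while task windows
    are correlated siblings cut with overlap from the same block.  A
    maximal-margin separator trained on classes of unequal size or unequal
    diversity systematically over-predicts the larger/more diverse class
    even on label-free data (class weights cannot help: with separable
    high-dimensional data no slack is active).  Balancing policies:

    - ``"block"`` (default, needs ``groups`` at fit time): each learner
      trains on an equal number of blocks per class, one window per block,
      equalizing both count and effective diversity;
    - ``"subsample"``: equalize window counts only;
    - ``None``: plain unbalanced fit (the convention this design descends
      from).

    Subsampling is deterministic given ``random_state``.
    """

    def __init__(self, C: float = 1.0, balance: str | None = "block",
                 random_state: int = 0):
        self.C = C
        self.balance = balance
        self.random_state = random_state

    def _pair_rows(self, y, groups, a, b, rng) -> np.ndarray:
        ia = np.flatnonzero(y == a)
        ib = np.flatnonzero(y == b)
        if self.balance == "block" and groups is not None:
            picked = []
            blocks_a = np.unique(groups[ia])
            blocks_b = np.unique(groups[ib])
            nb = min(len(blocks_a), len(blocks_b))
            for idx, blocks in ((ia, blocks_a), (ib, blocks_b)):
                chosen = (rng.choice(blocks, size=nb, replace=False)
                          if len(blocks) > nb else blocks)
                for blk in chosen:
                    rows = idx[groups[idx] == blk]
                    picked.append(rng.choice(rows) if len(rows) > 1 else rows[0])
            return np.sort(np.asarray(picked))
        if self.balance in ("subsample", "block"):
            # "block" without groups degrades to count subsampling
            n = min(len(ia), len(ib))
            ia = rng.choice(ia, size=n, replace=False) if len(ia) > n else ia
            ib = rng.choice(ib, size=n, replace=False) if len(ib) > n else ib
        elif self.balance is not None:
            raise ValueError("balance must be 'block', 'subsample' or None")
        return np.sort(np.concatenate([ia, ib]))

    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        groups = None if groups is None else np.asarray(groups)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        self.learners_ = []
        for a, b in combinations(self.classes_, 2):
            rows = self._pair_rows(y, groups, a, b, rng)
            clf = SVC(kernel="linear", C=self.C)
            clf.fit(X[rows], y[rows])
            self.learners_.append(((a, b), clf))
        return self

    def predict(self, X):
        check_is_fitted(self, "learners_")
        X = np.asarray(X, dtype=float)
        cindex = {c: i for i, c in enumerate(self.classes_)}
        # Hamming loss per class: learners whose pair excludes the class
        # contribute nothing; others contribute 1 when their binary output
        # disagrees with the class.  Ties (frequent in all-pairs voting)
        # break by the aggregate signed SVM margin, never by class order,
        # which would bias label-free data toward one class.
        loss = np.zeros((X.shape[0], len(self.classes_)))
        margin = np.zeros_like(loss)
        for (a, b), clf in self.learners_:
            dv = clf.decision_function(X)      # positive -> second class
            toward_b = clf.classes_[1] == b
            signed = dv if toward_b else -dv   # positive favors b
            pred = np.where(signed > 0, b, a)
            loss[:, cindex[a]] += pred != a
            loss[:, cindex[b]] += pred != b
            margin[:, cindex[a]] -= signed
            margin[:, cindex[b]] += signed
        # rescale margins so they only ever separate exact-loss ties
        tie_break = margin / (3.0 * (np.abs(margin).max() + 1.0))
        return self.classes_[np.argmin(loss - tie_break, axis=1)]


def train_binary(X, y, C: float = 1.0) -> SVC:
    """Soft-margin linear SVM on a two-class problem."""
    y = np.asarray(y)
    if len(np.unique(y)) != 2:
        raise ValueError("train_binary needs exactly two classes")
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def make_estimator(meta: pd.DataFrame, n_features: int | None = None,
                   C: float = 1.0, include_scaler: bool = False,
                   random_state: int = 0) -> Pipeline:
    """The per-fold chain: [scaler ->] subgroup PCA -> R^2 ranking -> ECOC."""
    steps = []
    if include_scaler:
        steps.append(("scale", SubjectScaler()))
    steps += [
        ("pca", SubgroupPCA(meta)),
        ("select", R2Selector(n_features=n_features)),
        ("ecoc", PairwiseECOC(C=C, random_state=random_state)),
    ]
    return Pipeline(steps)


def confusion_metrics(pooled: np.ndarray | pd.DataFrame,
                      class_index: int) -> dict[str, float | None]:
    """Sens/Spec/PPV/NPV of one class from a pooled confusion matrix.

    Rows are true classes, columns predicted.  Ratios with a zero
    denominator are reported as None rather than 0.
    """
    c = np.asarray(pooled, dtype=float)
    tp = c[class_index, class_index]
    fn = c[class_index].sum() - tp
    fp = c[:, class_index].sum() - tp
    tn = c.sum() - tp - fn - fp

    def ratio(num, den):
        return float(num / den) if den > 0 else None

    return {
        "Sens": ratio(tp, tp + fn),
        "Spec": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
    }


def metrics_table(pooled: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for i, cls in enumerate(pooled.index):
        rows[cls] = confusion_metrics(pooled, i)
    return pd.DataFrame(rows).T[["Sens", "Spec", "PPV", "NPV"]]


def _fold_indices(table: FeatureTable, k: int, seed: int,
                  partition: str) -> list[tuple[np.ndarray, np.ndarray]]:
    n = table.n_windows
    if k > n:
        raise ValueError(f"k={k} exceeds {n} windows")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    if partition == "window":
        return [(tr, te) for tr, te in kf.split(np.arange(n))]
    if partition == "block":
        # windows follow their source block; overlapping windows then never
        # straddle folds (stricter than the random-window convention)
        if table.windows is None:
            raise ValueError("block partition needs window provenance")
        blocks = np.array([w.source_block for w in table.windows])
        ublocks = np.unique(blocks)
        out = []
        for btr, bte in kf.split(ublocks):
            tr = np.flatnonzero(np.isin(blocks, ublocks[btr]))
            te = np.flatnonzero(np.isin(blocks, ublocks[bte]))
            out.append((tr, te))
        return out
    raise ValueError(f"unknown partition {partition!r}")


def crossvalidate(table: FeatureTable, case: list[str] | tuple[str, ...],
                  system: str = "hybrid", k: int = 10, seed: int = 0,
                  n_features: int | None = None, C: float = 1.0,
                  partition: str = "window", embargo: float = 0.0,
                  normalize: str = "subject") -> EvalReport:
    """k-fold cross-validation of one classification case on one system.

    The selection chain (subgroup PCA, R^2 ranking, truncation, SVMs) is
    re-fit inside each fold on training rows only.  Per-subject z-scoring
    is applied before the fold split by default (``normalize="subject"``,
    the convention reproduced here); ``normalize="fold"`` moves it inside
    the folds.  The pooled confusion matrix counts every window exactly
    once as a test observation.

    ``embargo`` (seconds) purges from each fold's training set any window
    closer in time than the margin to a test window, the standard guard
    against slow physiological autocorrelation (latent hemodynamic drive,
    Mayer waves) straddling the train/test split.  It requires window
    provenance and applies on top of either partition scheme.
    """
    sub = table.subset_system(system).subset_labels(case)
    if normalize == "subject":
        X = SubjectScaler().fit_transform(sub.X)
        sub = FeatureTable(X, sub.meta, sub.y, sub.windows)
    elif normalize != "fold":
        raise ValueError("normalize must be 'subject' or 'fold'")

    codes = sorted(CLASS_CODES[c] for c in case)
    labels = [CODE_TO_LABEL[c] for c in codes]
    pooled = np.zeros((len(codes), len(codes)), dtype=int)
    cpos = {c: i for i, c in enumerate(codes)}
    est = make_estimator(sub.meta, n_features=n_features, C=C,
                         include_scaler=(normalize == "fold"),
                         random_state=seed)

    fold_acc = []
    for tr, te in _fold_indices(sub, k, seed, partition):
        if embargo > 0:
            if sub.windows is None:
                raise ValueError("embargo needs window provenance")
            mid = np.array([(w.t_start + w.t_end) / 2 for w in sub.windows])
            half = np.array([(w.t_end - w.t_start) / 2 for w in sub.windows])
            gap = np.min(np.abs(mid[tr, None] - mid[None, te])
                         - half[tr, None] - half[None, te], axis=1)
            tr = tr[gap >= embargo]
        model = clone(est)
        if sub.windows is not None:
            blocks = np.array([w.source_block for w in sub.windows])
            model.fit(sub.X[tr], sub.y[tr], ecoc__groups=blocks[tr])
        else:
            model.fit(sub.X[tr], sub.y[tr])
        pred = model.predict(sub.X[te])
        fold_acc.append(float(np.mean(pred == sub.y[te])))
        for t, p in zip(sub.y[te], pred):
            pooled[cpos[t], cpos[p]] += 1

    pooled_df = pd.DataFrame(pooled, index=labels, columns=labels)
    return EvalReport(fold_accuracies=fold_acc, pooled_confusion=pooled_df,
                      classes=tuple(labels), k=k,
                      metrics=metrics_table(pooled_df))


# ---------------------------------------------------------------------------
# descriptive summaries and sweeps


def grand_block_average(recordings: list[Recording],
                        block_lists: list[list],
                        label: str, plane: int = 0,
                        n_points: int = 100,
                        normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Mean +/- sd time course over blocks of one class.

    Each matching block segment is resampled to ``n_points`` samples over
    its duration and (by default) z-scored per block and channel before
    averaging over (block x channel x recording).  Pass
    ``normalize=False`` to compare absolute amplitudes across classes.
    ``plane`` selects HbO (0) or HbR (1) for hemoglobin recordings.
    """
    courses = []
    for rec, blocks in zip(recordings, block_lists):
        wanted_kind = "rest" if label == "rest" else "task"
        for b in blocks:
            if b.kind != wanted_kind or b.label != label:
                continue
            seg = rec.time_slice(b.t_start, b.t_end)
            if rec.modality in ("hb", "fnirs_intensity"):
                seg = seg[plane]
            for ch in range(seg.shape[0]):
                x = seg[ch]
                if len(x) < 2:
                    continue
                grid = np.linspace(0, 1, n_points)
                src = np.linspace(0, 1, len(x))
                xr = np.interp(grid, src, x)
                if normalize:
                    sd = xr.std()
                    xr = (xr - xr.mean()) / sd if sd > 0 else xr - xr.mean()
                courses.append(xr)
    arr = np.array(courses)
    if arr.size == 0:
        raise ValueError(f"no blocks with label {label!r}")
    return arr.mean(axis=0), arr.std(axis=0)


def sweep_nfeatures(table: FeatureTable, case: list[str],
                    systems: tuple[str, ...] = ("eeg", "fnirs", "hybrid"),
                    grid: list[int] | None = None, k: int = 10,
                    seed: int = 0, **cv_kwargs) -> pd.DataFrame:
    """Mean CV accuracy as a function of retained feature count.

    The same seed (hence the same fold partition) is used for every system
    and grid point, a paired design.
    """
    rows = []
    for system in systems:
        n_max = int(table.system_mask(system).sum())
        points = [n for n in (grid or [2, 8, 32, 128, n_max]) if n <= n_max]
        for n in points:
            rep = crossvalidate(table, case, system=system, k=k, seed=seed,
                                n_features=n, **cv_kwargs)
            rows.append({"system": system, "n_features": n,
                         "accuracy": rep.mean_accuracy, "sd": rep.sd_accuracy})
    return pd.DataFrame(rows)


def sweep_window(tables: dict[float, FeatureTable], case: list[str],
                 systems: tuple[str, ...] = ("eeg", "fnirs", "hybrid"),
                 k: int = 10, seed: int = 0, **cv_kwargs) -> pd.DataFrame:
    """Mean CV accuracy as a function of window length.

    ``tables`` maps window length (s) to the feature table extracted at
    that length; the same seed is shared across systems and lengths.
    """
    rows = []
    for wlen, table in sorted(tables.items()):
        for system in systems:
            rep = crossvalidate(table, case, system=system, k=k, seed=seed,
                                **cv_kwargs)
            rows.append({"window_len": wlen, "system": system,
                         "accuracy": rep.mean_accuracy, "sd": rep.sd_accuracy})
    return pd.DataFrame(rows)
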