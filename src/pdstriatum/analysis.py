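"""Group statistics, SVM classification and feature-importance analysis.

The classification protocol mirrors the diagnostic framework: per-feature
two-sample Welch t-tests at alpha = 0.01 select the significant features;
a linear SVM on standardized selected features predicts PD vs NL; leave-n-out
cross-validation measures accuracy, with feature selection and
standardization refit inside every training split (no leakage); a random
forest quantifies feature importance, aggregated per statistic kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ImageVolume, LabelMap

GROUPS = ("NL", "PD")


@dataclass
class FeatureTable:
    """Subjects x features with group labels."""

    frame: pd.DataFrame   # columns: id, group, <feature names...>

    def __post_init__(self):
        missing = {"id", "group"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("id", "group")]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return (self.frame["group"] == "PD").to_numpy()

    def restrict(self, names) -> "FeatureTable":
        return FeatureTable(self.frame[["id", "group", *names]].copy())

    def subset(self, idx) -> "FeatureTable":
        return FeatureTable(self.frame.iloc[np.asarray(idx)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CVResult:
    n: int
    acc_mean: float
    wrong_mean: float
    n_partitions: int
    seed: int

    def __post_init__(self):
        assert 0.0 <= self.acc_mean <= 1.0
        assert self.wrong_mean <= self.n + 1e-9


@dataclass
class CVOptions:
    alpha: float = 0.01
    svm_c: float = 1.0
    n_random_partitions: int = 200   # for n > 1
    max_resample: int = 50


def select_features(table: FeatureTable, alpha: float = 0.01):
    """Two-sided Welch t-test per feature between PD and NL.

    Returns (selected feature names, p-value Series over all testable
    features). Features with zero variance in both groups have no defined
    test and are excluded with a warning.
    """
    y = table.y
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("both groups need >= 2 members for a t-test")
    X = table.X
    names = table.feature_names
    a, b = X[y], X[~y]
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    if degenerate.any():
        bad = [n for n, d in zip(names, degenerate) if d]
        warnings.warn(f"zero-variance feature(s) excluded from testing: {bad}",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant features (e.g. template-arm volumes) trip scipy's
        # catastrophic-cancellation notice; their p-values are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    pvals = pd.Series(p, index=names)[~degenerate]
    selected = list(pvals.index[pvals < alpha])
    return selected, pvals


def train_svm(table: FeatureTable, c: float = 1.0, seed: int = 0) -> Pipeline:
    """Linear SVM on standardized features (standardization statistics come
    from the table it is fitted on)."""
    if not table.feature_names:
        raise ValueError("no features selected; fall back to the lowest-p feature")
    X = table.X
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all candidate features are constant")
    y = table.y
    if y.all() or not y.any():
        raise ValueError("both groups must be present for training")
    clf = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="linear", C=c, random_state=seed)),
    ])
    clf.fit(X, y)
    return clf


def _fit_fold(train_table: FeatureTable, opts: CVOptions, seed: int):
    """Feature selection + SVM inside one training split; falls back to the
    single lowest-p feature if nothing passes alpha."""
    selected, pvals = select_features(train_table, alpha=opts.alpha)
    if not selected:
        selected = [pvals.idxmin()]
    clf = train_svm(train_table.restrict(selected), c=opts.svm_c, seed=seed)
    return clf, selected


def make_partitions(n_subjects: int, n: int, seed: int,
                    opts: CVOptions | None = None, groups: np.ndarray | None = None):
    """Held-out index sets for leave-n-out: exact LOO for n=1, repeated
    random subsets otherwise. Partitions whose training split would lose a
    class are resampled (bounded retries)."""
    opts = opts or CVOptions()
    if not 1 <= n <= n_subjects - 2:
        raise ValueError(f"n={n} out of range for {n_subjects} subjects")
    if n == 1:
        return [np.array([i]) for i in range(n_subjects)]
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(opts.n_random_partitions):
        for _retry in range(opts.max_resample):
            held = rng.choice(n_subjects, size=n, replace=False)
            if groups is None:
                break
            rest = np.setdiff1d(np.arange(n_subjects), held)
            if len(np.unique(groups[rest])) == 2:
                break
        else:
            raise RuntimeError("could not draw a class-preserving partition")
        partitions.append(np.sort(held))
    return partitions


def evaluate_partitions(table: FeatureTable, partitions, opts: CVOptions | None = None,
                        seed: int = 0, train_table: FeatureTable | None = None) -> tuple[float, float]:
    """Mean accuracy and mean wrong-prediction count over held-out sets.

    ``train_table`` lets the classifier be fitted on one arm's features and
    tested on another's (cross-arm transfer); it must index the same
    subjects in the same order.
    """
    opts = opts or CVOptions()
    source = train_table if train_table is not None else table
    if train_table is not None and len(train_table) != len(table):
        raise ValueError("train/test tables must cover the same subjects")
    accs, wrongs = [], []
    all_idx = np.arange(len(table))
    for held in partitions:
        rest = np.setdiff1d(all_idx, held)
        clf, selected = _fit_fold(source.subset(rest), opts, seed)
        test = table.subset(held).restrict(selected)
        pred = clf.predict(test.X)
        truth = test.y
        n_wrong = int((pred != truth).sum())
        accs.append(1.0 - n_wrong / len(held))
        wrongs.append(n_wrong)
    return float(np.mean(accs)), float(np.mean(wrongs))


def leave_n_out_cv(table: FeatureTable, n: int, opts: CVOptions | None = None,
                   seed: int = 0) -> CVResult:
    """Leave-n-out cross-validation with in-fold feature selection."""
    opts = opts or CVOptions()
    partitions = make_partitions(len(table), n, seed, opts, groups=table.y)
    acc, wrong = evaluate_partitions(table, partitions, opts, seed)
    return CVResult(n=n, acc_mean=acc, wrong_mean=wrong,
                    n_partitions=len(partitions), seed=seed)


@dataclass
class ArmComparison:
    ns: list[int]
    results_a: list[CVResult]
    results_b: list[CVResult]
    p_value: float          # paired t-test across n of wrong counts; 1.0 if identical
    identical: bool


def compare_arms(table_a: FeatureTable, table_b: FeatureTable, ns,
                 opts: CVOptions | None = None, seed: int = 0) -> ArmComparison:
    """Evaluate two arms on identical partitions (shared seed) for each n and
    compare their wrong-prediction counts with a paired t-test."""
    opts = opts or CVOptions()
    if len(table_a) != len(table_b) or not (table_a.y == table_b.y).all():
        raise ValueError("arms must cover the same subjects in the same order")
    res_a, res_b = [], []
    ns = list(ns)
    for n in ns:
        partitions = make_partitions(len(table_a), n, seed + n, opts, groups=table_a.y)
        acc_a, wr_a = evaluate_partitions(table_a, partitions, opts, seed)
        acc_b, wr_b = evaluate_partitions(table_b, partitions, opts, seed)
        res_a.append(CVResult(n, acc_a, wr_a, len(partitions), seed + n))
        res_b.append(CVResult(n, acc_b, wr_b, len(partitions), seed + n))
    wrong_a = np.array([r.wrong_mean for r in res_a])
    wrong_b = np.array([r.wrong_mean for r in res_b])
    if np.allclose(wrong_a, wrong_b):
        return ArmComparison(ns, res_a, res_b, p_value=1.0, identical=True)
    _, p = stats.ttest_rel(wrong_a, wrong_b)
    return ArmComparison(ns, res_a, res_b, p_value=float(p), identical=False)


def cross_arm_transfer(train_table: FeatureTable, test_table: FeatureTable,
                       opts: CVOptions | None = None, seed: int = 0) -> float:
    """Train on one arm's full feature table, test on another's; returns
    accuracy on the full cohort (e.g. manual-labels -> automatic arm)."""
    opts = opts or CVOptions()
    clf, selected = _fit_fold(train_table, opts, seed)
    test = test_table.restrict(selected)
    return float((clf.predict(test.X) == test.y).mean())


# ---------------------------------------------------------------------------
# Random-forest importance

AGGREGATE_ORDER = ("mean", "median", "q3", "q1", "max", "min", "volume")


def rf_importance(table: FeatureTable, seed: int = 0, include_volume: bool = True,
                  n_trees: int = 500):
    """Impurity-based random-forest feature importances (normalized to sum 1)
    plus per-statistic-kind aggregates obtained by summing member features.

    With ``include_volume`` the aggregate has 7 rows (six intensity
    statistics + volume), without it 6.
    """
    names = table.feature_names
    if not include_volume:
        names = [n for n in names if not n.endswith("_volume")]
    sub = table.restrict(names)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    rf.fit(sub.X, sub.y)
    imp = pd.Series(rf.feature_importances_, index=names)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    kinds = AGGREGATE_ORDER if include_volume else AGGREGATE_ORDER[:-1]
    agg = pd.Series(
        {k: imp[[n for n in names if _kind_of(n) == k]].sum() for k in kinds})
    return imp, agg


def _kind_of(name: str) -> str:
    if name.endswith("_volume"):
        return "volume"
    parts = name.rsplit("_", 2)
    return parts[-2] if len(parts) == 3 and parts[-1] == "sor" else "other"


def selection_null_rate(n_reps: int = 1000, n_pd: int = 49, n_nl: int = 18,
                        n_features: int = 90, alpha: float = 0.01,
                        seed: int = 0) -> float:
    """Type-I-error simulation: both groups drawn from the same distribution;
    returns the mean fraction of features passing p < alpha."""
    rng = np.random.default_rng(seed)
    frac = []
    for _ in range(n_reps):
        a = rng.standard_normal((n_pd, n_features))
        b = rng.standard_normal((n_nl, n_features))
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
        frac.append(np.mean(p < alpha))
    return float(np.mean(frac))


def importance_map(labels: LabelMap, partitions: dict, importances) -> ImageVolume:
    """Voxelwise importance heat map: each subregion (or whole region) voxel
    receives the summed importance of its features; background is 0.

    ``partitions`` maps region name -> SubRegionPartition for the subdivided
    regions; whole regions take their features directly from the label map.
    """
    importances = pd.Series(importances)
    out = np.zeros(labels.shape, dtype=np.float64)

    def _total_for(prefix: str) -> float:
        mask = importances.index.str.startswith(prefix)
        return float(importances[mask].sum())

    from .core import SAR_LABELS

    for region, lab in SAR_LABELS.items():
        if region in partitions:
            part = partitions[region]
            for sub in range(1, part.k + 1):
                vox = part.voxels_of(sub)
                out[vox[:, 0], vox[:, 1], vox[:, 2]] = _total_for(f"{region}_sub{sub}_")
        else:
            out[labels.data == lab] = _total_for(f"{region}_whole_")
    return ImageVolume(out, labels.spacing, labels.origin, modality="PET")
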