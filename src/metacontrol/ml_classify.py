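"""Data-driven feature extraction and SVM group decoding.

The decoding chain mirrors a hybrid filter-wrapper design:

1.  every CSD-transformed sample of every channel of the response-locked
    subject-average ERP in a -300..+1000 ms window is a candidate feature;
2.  features are z-scored per column;
3.  a two-sample t-test filter keeps columns with p < 0.01;
4.  sequential floating forward selection (SFFS) orders the survivors by
    stratified 10-fold cross-validated accuracy of an RBF-kernel SVM;
5.  99% t-based confidence bounds on the fold accuracies determine how many
    features are retained (a larger set is accepted only while consecutive
    bounds do not overlap);
6.  a label-permutation test (default 1000 shuffles) checks that the real
    accuracy beats chance.

By default z-scoring and filtering are computed on the full sample before
cross-validation (the classical, slightly optimistic procedure); a nested
mode moves both inside each training fold to eliminate that leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .erp_pipeline import ErpStack

__all__ = [
    "FeatureMatrix", "SizeResult", "SelectionResult", "PermutationResult",
    "extract_features", "zscore_columns", "ttest_filter", "make_folds",
    "cv_accuracy", "sfs", "sffs", "confidence_bounds", "choose_feature_count",
    "permutation_test", "selection_table", "run_decoding",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class FeatureMatrix:
    """Subjects x (channel, time) feature matrix with column metadata.

    ``meta`` has one row per column: electrode, time_ms.  ``labels`` is the
    binary group assignment aligned with rows.
    """

    X: np.ndarray
    meta: pd.DataFrame
    labels: np.ndarray
    subjects: np.ndarray
    zscored: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if len(self.meta) != self.X.shape[1]:
            raise ValueError("meta rows must match feature columns")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels must match subject rows")

    def column_index(self, electrode: str, time_ms: float,
                     tol_ms: float | None = None) -> int:
        """Column whose (electrode, time) is nearest ``time_ms``; raises if
        no sample lies within half a sampling period (or ``tol_ms``)."""
        sel = np.flatnonzero(self.meta["electrode"].to_numpy() == electrode)
        if len(sel) == 0:
            raise KeyError(f"no features at electrode {electrode!r}")
        times = self.meta["time_ms"].to_numpy()[sel]
        k = int(np.argmin(np.abs(times - time_ms)))
        if tol_ms is None:
            dt = np.median(np.diff(np.sort(np.unique(times)))) if len(times) > 1 else np.inf
            tol_ms = dt / 2 + 1e-9
        if abs(times[k] - time_ms) > tol_ms:
            raise KeyError(f"no sample within {tol_ms:g} ms of {time_ms} ms")
        return int(sel[k])


@dataclass(frozen=True)
class SizeResult:
    n_features: int
    features: tuple[int, ...]
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    ci_lo: float
    ci_hi: float


@dataclass
class SelectionResult:
    """SFFS output: best subset per size plus the chosen size."""
    per_size: list[SizeResult]
    chosen_n: int
    candidates: np.ndarray
    filter_pvalues: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    @property
    def selected(self) -> tuple[int, ...]:
        return self.per_size[self.chosen_n - 1].features


@dataclass(frozen=True)
class PermutationResult:
    real_accuracy: float
    null_accuracies: np.ndarray
    pct_real_exceeds_null: float


# ---------------------------------------------------------------------------
# feature construction

def extract_features(erps: ErpStack, labels: pd.Series,
                     window_ms: tuple[float, float] = (-300.0, 1000.0)
                     ) -> FeatureMatrix:
    """One row per subject, one column per channel x sample in the window.

    The ERPs must be response-locked subject averages in CSD units.
    """
    if erps.units != "csd":
        raise ValueError("features are defined on CSD-transformed ERPs")
    sl = erps.window_slice(*window_ms)
    times = erps.times_ms[sl]
    n_subj, n_ch, _ = erps.data.shape
    block = erps.data[:, :, sl]                       # subj x ch x t
    X = block.reshape(n_subj, n_ch * len(times))
    meta = pd.DataFrame({
        "electrode": np.repeat(erps.montage.names, len(times)),
        "time_ms": np.tile(times, n_ch),
    })
    y = np.asarray([labels[s] for s in erps.subjects])
    return FeatureMatrix(X=X, meta=meta, labels=y, subjects=np.asarray(erps.subjects))


def zscore_columns(features: FeatureMatrix):
    """z-score each column (sample sd, ddof=1); constant columns are excluded.

    Returns ``(features, kept_columns)`` where the new matrix keeps only
    non-constant columns and the index array maps back to the original
    column numbering.
    """
    X = features.X
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 subjects")
    sd = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    out = FeatureMatrix(X=Xz, meta=features.meta.iloc[keep].reset_index(drop=True),
                        labels=features.labels, subjects=features.subjects,
                        zscored=True)
    return out, keep


def ttest_filter(features: FeatureMatrix, alpha: float = 0.01):
    """Two-sample t-test per column; columns with p < alpha are candidates.

    Returns ``(candidate_columns, pvalues)``.
    """
    y = features.labels
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    a = features.X[y == classes[0]]
    b = features.X[y == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs at least 2 subjects")
    _, p = sps.ttest_ind(a, b, axis=0)
    p = np.asarray(p)
    return np.flatnonzero(p < alpha), p


# ---------------------------------------------------------------------------
# cross-validated criterion

def _default_svm() -> SVC:
    # toolbox defaults: RBF kernel, C = 1, gamma = 1 / (n_features * var(X))
    return SVC(C=1.0, kernel="rbf", gamma="scale")


def make_folds(labels: np.ndarray, k: int = 10, seed: int = 0):
    """Stratified k-fold assignment, drawn once and reused across a run."""
    y = np.asarray(labels)
    if len(y) < k:
        raise ValueError("need at least k subjects")
    if k == len(y):
        # leave-one-out: stratification is moot with singleton test folds
        idx = np.arange(len(y))
        return [(np.delete(idx, i), idx[i:i + 1]) for i in idx]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def cv_accuracy(X: np.ndarray, y: np.ndarray, folds,
                nested_zscore: bool = False) -> np.ndarray:
    """Per-fold test accuracies of the RBF SVM on the given feature subset."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    accs = np.empty(len(folds))
    for i, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a training fold lost a class; re-stratify")
        Xtr, Xte = X[tr], X[te]
        if nested_zscore:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = _default_svm().fit(Xtr, y[tr])
        accs[i] = (clf.predict(Xte) == y[te]).mean()
    return accs


def confidence_bounds(fold_accuracies, level: float = 0.99):
    """t-based confidence interval: mean ± t_{1-(1-level)/2, k-1} · sd/√k.

    Bounds are *not* clipped here; clip for reporting only, the feature-count
    rule compares unclipped bounds.
    """
    a = np.asarray(fold_accuracies, float)
    k = len(a)
    if k < 2:
        raise ValueError("need at least 2 folds")
    m = a.mean()
    s = a.std(ddof=1)
    if s < 1e-12 * max(1.0, abs(m)):
        return m, m
    half = sps.t.ppf(1 - (1 - level) / 2, k - 1) * s / np.sqrt(k)
    return m - half, m + half


# ---------------------------------------------------------------------------
# sequential selection

def _eval(X, y, subset, folds, cache, nested):
    key = tuple(sorted(subset))
    if key not in cache:
        cache[key] = cv_accuracy(X[:, list(key)], y, folds, nested).mean()
    return cache[key]


def sfs(X: np.ndarray, y: np.ndarray, candidates, folds,
        max_features: int | None = None, nested_zscore: bool = False):
    """Plain sequential forward selection; returns best subset per size."""
    candidates = list(candidates)
    max_features = max_features or len(candidates)
    cache: dict = {}
    subset: list[int] = []
    best = {}
    while len(subset) < min(max_features, len(candidates)):
        scores = [(_eval(X, y, subset + [c], folds, cache, nested_zscore), c)
                  for c in candidates if c not in subset]
        sc, pick = max(scores, key=lambda t: (t[0], -t[1]))
        subset.append(pick)
        best[len(subset)] = (sc, tuple(subset))
    return best


def sffs(features: FeatureMatrix, candidates, folds,
         max_features: int = 20, nested_zscore: bool = False,
         filter_pvalues=None, ci_level: float = 0.99) -> SelectionResult:
    """Sequential floating forward selection over the candidate columns.

    Forward steps add the feature maximizing mean CV accuracy; after each
    forward step, conditional backward steps remove features as long as the
    reduced subset beats the best known subset of its size.  The best subset
    found for every size is recorded; ties break toward the lowest column
    index.  The returned ``chosen_n`` applies the confidence-bound
    non-overlap rule.
    """
    candidates = [int(c) for c in candidates]
    if not candidates:
        raise ValueError("no candidate features survived the filter")
    X, y = features.X, features.labels
    max_features = min(max_features, len(candidates))
    cache: dict = {}
    best: dict[int, tuple[float, tuple[int, ...]]] = {}

    def record(subset):
        s = _eval(X, y, subset, folds, cache, nested_zscore)
        k = len(subset)
        if k not in best or s > best[k][0] + 1e-12:
            best[k] = (s, tuple(sorted(subset)))
        return s

    subset: list[int] = []
    while len(subset) < max_features:
        # forward step
        scores = [(_eval(X, y, subset + [c], folds, cache, nested_zscore), c)
                  for c in candidates if c not in subset]
        sc, pick = max(scores, key=lambda t: (t[0], -t[1]))
        subset.append(pick)
        record(subset)
        # conditional backward (floating) steps
        while len(subset) > 2:
            drops = [(_eval(X, y, [f for f in subset if f != r], folds,
                            cache, nested_zscore), r) for r in subset]
            sc_d, drop = max(drops, key=lambda t: (t[0], -t[1]))
            if sc_d > best[len(subset) - 1][0] + 1e-12:
                subset.remove(drop)
                best[len(subset)] = (sc_d, tuple(sorted(subset)))
            else:
                break

    per_size = []
    for k in sorted(best):
        if k > max_features:
            continue
        _, feats = best[k]
        accs = cv_accuracy(X[:, list(feats)], y, folds, nested_zscore)
        lo, hi = confidence_bounds(accs, ci_level)
        per_size.append(SizeResult(k, feats, tuple(accs), float(accs.mean()),
                                   float(lo), float(hi)))
    pvals = (np.asarray(filter_pvalues) if filter_pvalues is not None
             else np.full(features.X.shape[1], np.nan))
    result = SelectionResult(per_size=per_size, chosen_n=1,
                             candidates=np.asarray(candidates),
                             filter_pvalues=pvals, meta=features.meta)
    result.chosen_n = choose_feature_count(result)
    return result


def choose_feature_count(selection: SelectionResult) -> int:
    """Walk sizes 1, 2, ...; accept size s+1 only while its 99% CI does not
    overlap size s's CI.  Returns the last accepted size (>= 1)."""
    sizes = selection.per_size
    chosen = 1
    for prev, cur in zip(sizes, sizes[1:]):
        overlap = cur.ci_lo <= prev.ci_hi and prev.ci_lo <= cur.ci_hi
        if overlap:
            break
        chosen = cur.n_features
    return chosen


# ---------------------------------------------------------------------------
# permutation test

def permutation_test(features: FeatureMatrix, selected, k: int = 10,
                     n_perm: int = 1000, seed: int = 0,
                     mode: str = "fixed_features",
                     filter_alpha: float = 0.01,
                     max_features: int = 20,
                     nested_zscore: bool = False) -> PermutationResult:
    """Label-permutation null for the decoder.

    Each permutation shuffles the group labels (class sizes preserved) and
    recomputes the stratified 10-fold CV accuracy — on the fixed selected
    features in the default mode, or re-running filter + SFFS per permutation
    in ``mode="reselect"`` (slower, accounts for selection bias).  Reports
    the percentage of permutations whose null accuracy falls below the real
    accuracy.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("fixed_features", "reselect"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E1]))
    X, y = features.X, features.labels
    sel = list(selected)
    folds = make_folds(y, k, seed)
    real = cv_accuracy(X[:, sel], y, folds, nested_zscore).mean()
    null = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        fp = make_folds(yp, k, seed=int(rng.integers(2 ** 31)))
        if mode == "fixed_features":
            null[i] = cv_accuracy(X[:, sel], yp, fp, nested_zscore).mean()
        else:
            fm = FeatureMatrix(X=X, meta=features.meta, labels=yp,
                               subjects=features.subjects,
                               zscored=features.zscored)
            cand, pv = ttest_filter(fm, filter_alpha)
            if len(cand) == 0:
                # no features survive: degenerate majority-class accuracy
                _, counts = np.unique(yp, return_counts=True)
                null[i] = counts.max() / len(yp)
                continue
            res = sffs(fm, cand, fp, max_features=max_features,
                       nested_zscore=nested_zscore, filter_pvalues=pv)
            null[i] = res.per_size[res.chosen_n - 1].mean_accuracy
    pct = 100.0 * float((null < real - 1e-12).mean())
    return PermutationResult(real_accuracy=float(real), null_accuracies=null,
                             pct_real_exceeds_null=pct)


# ---------------------------------------------------------------------------
# reporting / orchestration

def selection_table(selection: SelectionResult,
                    permutation: PermutationResult | None = None) -> pd.DataFrame:
    """Summary table: feature number, electrode, time point, mean
    predictability (%), filter p-value, and the permutation percentage."""
    rows = []
    chosen = selection.per_size[selection.chosen_n - 1]
    order = []
    for sz in selection.per_size:
        for f in sz.features:
            if f not in order:
                order.append(f)
    for i, f in enumerate(order, start=1):
        sz = next((s for s in selection.per_size if s.n_features == i), None)
        rows.append({
            "feature_number": i,
            "electrode": selection.meta.iloc[f]["electrode"],
            "time_ms": float(selection.meta.iloc[f]["time_ms"]),
            "mean_predictability_pct": (100 * sz.mean_accuracy) if sz else np.nan,
            "filter_p": float(selection.filter_pvalues[f])
            if f < len(selection.filter_pvalues) else np.nan,
            "selected": f in chosen.features,
        })
    out = pd.DataFrame(rows)
    if permutation is not None:
        out["pct_better_than_permuted"] = permutation.pct_real_exceeds_null
    return out


def run_decoding(erps: ErpStack, labels: pd.Series,
                 window_ms=(-300.0, 1000.0), filter_alpha: float = 0.01,
                 k: int = 10, max_features: int = 20, n_perm: int = 1000,
                 seed: int = 0, nested: bool = False,
                 perm_mode: str = "fixed_features"):
    """Full decoding stage: extract -> z-score -> filter -> SFFS -> permute.

    In nested mode the z-scoring and filtering are recomputed inside each
    training fold (leakage-free); otherwise they use the full sample first,
    matching the classical procedure.
    """
    fm = extract_features(erps, labels, window_ms)
    if not nested:
        fm, _ = zscore_columns(fm)
    cand, pvals = ttest_filter(fm, filter_alpha)
    if len(cand) == 0:
        raise ValueError("no features passed the t-test filter")
    folds = make_folds(fm.labels, k, seed)
    selection = sffs(fm, cand, folds, max_features=max_features,
                     nested_zscore=nested, filter_pvalues=pvals)
    permutation = permutation_test(fm, selection.selected, k=k,
                                   n_perm=n_perm, seed=seed,
                                   nested_zscore=nested, mode=perm_mode)
    return fm, selection, permutation
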