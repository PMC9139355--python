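"""Two-stage radiomic feature reduction and selection.

Stage 0 — *stability*: features whose intra-class correlation between two
segmentations falls below 0.9 are discarded (ICC(2,1): two-way random
effects, absolute agreement, single rater).

Stage 1 — *consensus filter ranking*: six attribute scores (correlation
merit, gain ratio, information gain, one-rule accuracy, ReliefF and
symmetrical uncertainty) each rank all features; features placed in the
top-``cap`` (default 50) by at least ``min_filters`` (default 3) rankings
are retained, capped at 50 by mean rank.

Stage 2 — *wrapper*: greedy best-first forward search over the consensus
set, scoring candidate subsets with the internal cross-validated accuracy
of the actual downstream classifier.

Class imbalance is handled with SMOTE; by default inside each training
fold only (``paper_mode=True`` reproduces balancing the whole table before
cross-validation, which leaks synthetic neighbors into validation folds).

Continuous features are discretized for the information-theoretic scores
with supervised MDL (Fayyad–Irani) binning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "compute_icc", "stability_filter", "mdl_discretize", "rank_filters",
    "ConsensusSet", "consensus_select", "smote_balance", "WrapperResult",
    "wrapper_select", "FILTER_NAMES",
]

FILTER_NAMES = ("Correlation", "GainRatio", "InfoGain", "OneR", "ReliefF",
                "SymmetricalUncert")


# ---------------------------------------------------------------------------
# ICC stability


def compute_icc(values_reader1: pd.DataFrame,
                values_reader2: pd.DataFrame) -> pd.Series:
    """ICC(2,1) per feature from two paired measurement tables.

    Two-way random effects, absolute agreement, single measure:

        ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

    with n subjects and k = 2 raters.  Features with zero variance in both
    readers are returned as NaN (undefined, to be discarded).
    """
    x1 = np.asarray(values_reader1, dtype=float)
    x2 = np.asarray(values_reader2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("reader tables must be aligned")
    n = x1.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired cases")
    k = 2
    data = np.stack([x1, x2], axis=1)  # (n, k, p)
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)  # (n, p)
    rater = data.mean(axis=0)  # (k, p)
    ssr = k * ((subj - grand) ** 2).sum(axis=0)
    ssc = n * ((rater - grand) ** 2).sum(axis=0)
    sst = ((data - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc = np.where(sst > 0, icc, np.nan)
    cols = (values_reader1.columns if isinstance(values_reader1, pd.DataFrame)
            else None)
    return pd.Series(np.clip(icc, -1.0, 1.0), index=cols, name="ICC")


def stability_filter(table: pd.DataFrame, icc: pd.Series,
                     threshold: float = 0.9) -> pd.DataFrame:
    """Keep exactly the feature columns with ICC ≥ threshold."""
    missing = [c for c in table.columns if c not in icc.index]
    if missing:
        raise ValueError(f"ICC report does not cover columns {missing[:3]}...")
    keep = [c for c in table.columns if icc[c] >= threshold]
    if not keep:
        raise ValueError("no feature survives the stability filter")
    return table[keep]


# ---------------------------------------------------------------------------
# supervised MDL discretization (Fayyad & Irani)


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mdl_split(values, labels, lo, hi, cuts):
    n = hi - lo
    if n < 2:
        return
    y = labels[lo:hi]
    base_ent = _entropy(y)
    if base_ent == 0:
        return
    v = values[lo:hi]
    # candidate cuts: boundaries between distinct adjacent values;
    # incremental left/right class histograms keep the scan O(n·classes)
    best_gain, best_i = 0.0, None
    classes, y_idx = np.unique(y, return_inverse=True)
    c = len(classes)
    left = np.zeros(c)
    right = np.bincount(y_idx, minlength=c).astype(float)
    ents = None
    for i in range(1, n):
        left[y_idx[i - 1]] += 1
        right[y_idx[i - 1]] -= 1
        if v[i] == v[i - 1]:
            continue
        pl = left / left.sum()
        pr = right / right.sum()
        el = float(-(pl[pl > 0] * np.log2(pl[pl > 0])).sum())
        er = float(-(pr[pr > 0] * np.log2(pr[pr > 0])).sum())
        gain = base_ent - (i * el + (n - i) * er) / n
        if gain > best_gain:
            best_gain, best_i, ents = gain, i, (el, er, left.copy(), right.copy())
    if best_i is None:
        return
    el, er, lcnt, rcnt = ents
    c1 = int((lcnt > 0).sum())
    c2 = int((rcnt > 0).sum())
    delta = math.log2(3**c - 2) - (c * base_ent - c1 * el - c2 * er)
    threshold = (math.log2(n - 1) + delta) / n
    if best_gain <= threshold:
        return
    cuts.append((values[lo + best_i - 1] + values[lo + best_i]) / 2.0)
    _mdl_split(values, labels, lo, lo + best_i, cuts)
    _mdl_split(values, labels, lo + best_i, hi, cuts)


def mdl_discretize(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Supervised entropy-based binning; returns sorted cut points.

    An empty result means the MDL criterion accepts no split (the feature
    is uninformative and collapses to a single bin).
    """
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _mdl_split(np.asarray(values, dtype=float)[order],
               np.asarray(labels)[order], 0, len(values), cuts)
    return np.sort(np.asarray(cuts))


def _bin_feature(values, cuts):
    return np.digitize(values, cuts) if len(cuts) else np.zeros(len(values), int)


# ---------------------------------------------------------------------------
# the six attribute filters


def _info_gain(binned, y) -> float:
    hy = _entropy(y)
    total = len(y)
    cond = 0.0
    for b in np.unique(binned):
        sel = binned == b
        cond += sel.sum() / total * _entropy(y[sel])
    return hy - cond


def _score_correlation(x, y_codes, classes) -> float:
    # class-weighted mean |point-biserial correlation| against each
    # one-vs-rest class indicator
    if x.std() == 0:
        return 0.0
    score = 0.0
    total = len(y_codes)
    for ci in range(len(classes)):
        ind = (y_codes == ci).astype(float)
        w = ind.sum() / total
        if ind.std() == 0:
            continue
        score += w * abs(np.corrcoef(x, ind)[0, 1])
    return float(score)


def _score_oner(binned, y) -> float:
    # accuracy of the one-rule: majority class per bin
    correct = 0
    for b in np.unique(binned):
        sel = binned == b
        _, counts = np.unique(y[sel], return_counts=True)
        correct += counts.max()
    return correct / len(y)


def _relieff(X: np.ndarray, y_codes: np.ndarray, k: int = 10) -> np.ndarray:
    """ReliefF weights, all instances, k nearest hits/misses, Manhattan
    distance on range-scaled features, class-prior-weighted misses."""
    n, p = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    Z = (X - X.min(axis=0)) / rng_span
    classes, counts = np.unique(y_codes, return_counts=True)
    priors = counts / n
    w = np.zeros(p)
    # pairwise Manhattan distances, blockwise to bound memory
    for i in range(n):
        d = np.abs(Z - Z[i]).sum(axis=1)
        d[i] = np.inf
        for ci, cls in enumerate(classes):
            sel = np.nonzero(y_codes == cls)[0]
            sel = sel[sel != i]
            if len(sel) == 0:
                continue
            kk = min(k, len(sel))
            nearest = sel[np.argsort(d[sel], kind="stable")[:kk]]
            diff = np.abs(Z[nearest] - Z[i]).mean(axis=0)
            if cls == y_codes[i]:
                w -= diff
            else:
                w += priors[ci] / (1.0 - priors[y_codes[i]]) * diff
    return w / n


def rank_filters(table: pd.DataFrame, labels: pd.Series,
                 relieff_k: int = 10) -> dict[str, pd.DataFrame]:
    """Rank every feature with each of the six attribute filters.

    Returns ``{filter_name: DataFrame(feature, score)}`` sorted by
    descending score with lexicographic tie-breaking, each a permutation
    of the feature set.  Constant features score 0 everywhere.
    """
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 classes and >= 2 features")
    names = list(table.columns)
    hy = _entropy(y)

    binned_cols = []
    for j in range(X.shape[1]):
        cuts = mdl_discretize(X[:, j], y)
        binned_cols.append(_bin_feature(X[:, j], cuts))

    scores: dict[str, np.ndarray] = {name: np.zeros(X.shape[1])
                                     for name in FILTER_NAMES}
    for j in range(X.shape[1]):
        b = binned_cols[j]
        ig = _info_gain(b, y) if b.max() > 0 else 0.0
        hx = _entropy(b)
        scores["InfoGain"][j] = ig
        scores["GainRatio"][j] = ig / hx if hx > 0 else 0.0
        scores["SymmetricalUncert"][j] = (2 * ig / (hy + hx)
                                          if (hy + hx) > 0 else 0.0)
        scores["OneR"][j] = _score_oner(b, y) if b.max() > 0 else \
            np.bincount(y_codes).max() / len(y)
        scores["Correlation"][j] = _score_correlation(X[:, j], y_codes, classes)
    scores["ReliefF"] = _relieff(X, y_codes, k=relieff_k)

    out = {}
    for name in FILTER_NAMES:
        df = pd.DataFrame({"feature": names, "score": scores[name]})
        df = df.sort_values(["score", "feature"], ascending=[False, True],
                            kind="stable").reset_index(drop=True)
        out[name] = df
    return out


@dataclass
class ConsensusSet:
    """Features top-ranked by at least ``min_filters`` of the six filters."""

    features: list
    filter_counts: dict
    cap: int = 50
    min_filters: int = 3


def consensus_select(rankings: dict[str, pd.DataFrame], cap: int = 50,
                     min_filters: int = 3) -> ConsensusSet:
    """Select up to ``cap`` features appearing in the top-``cap`` of at
    least ``min_filters`` rankings; qualifiers beyond the cap are dropped
    by mean rank (ties broken lexicographically).  If fewer than ``cap``
    features qualify, all qualifiers are returned."""
    counts: dict[str, int] = {}
    mean_rank: dict[str, float] = {}
    for df in rankings.values():
        order = list(df["feature"])
        for rank, feat in enumerate(order):
            mean_rank[feat] = mean_rank.get(feat, 0.0) + rank / len(rankings)
            if rank < cap:
                counts[feat] = counts.get(feat, 0) + 1
    qualifiers = [f for f, c in counts.items() if c >= min_filters]
    qualifiers.sort(key=lambda f: (mean_rank[f], f))
    selected = qualifiers[:cap]
    return ConsensusSet(features=selected,
                        filter_counts={f: counts[f] for f in selected},
                        cap=cap, min_filters=min_filters)


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(table: pd.DataFrame, labels: pd.Series, seed: int,
                  k: int = 5) -> tuple[pd.DataFrame, pd.Series]:
    """Oversample every minority class to the majority count.

    Synthetic rows are convex combinations x + λ·(x_nn − x) of a minority
    row and one of its k nearest same-class neighbors (λ ~ U[0,1]); the
    result is then row-shuffled with the given seed.  Original rows are
    preserved bit-identically.  Classes smaller than k+1 reduce k with a
    warning.
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    n_major = counts.max()
    new_rows, new_labels = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = n_major - cnt
        if need == 0:
            continue
        idx = np.nonzero(y == cls)[0]
        kk = k
        if cnt < k + 1:
            kk = max(cnt - 1, 1)
            _warnings.warn(
                f"class {cls!r} has {cnt} members; SMOTE k reduced to {kk}")
        Xc = X[idx]
        # same-class nearest neighbors (Euclidean)
        d = np.linalg.norm(Xc[:, None, :] - Xc[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1, kind="stable")[:, :kk]
        pick = rng.integers(0, cnt, size=need)
        pick_nn = nn[pick, rng.integers(0, kk, size=need)]
        lam = rng.random(size=(need, 1))
        synth = Xc[pick] + lam * (Xc[pick_nn] - Xc[pick])
        new_rows.append(synth)
        new_labels.append(np.full(need, cls, dtype=y.dtype))
    Xb = np.vstack(new_rows)
    yb = np.concatenate(new_labels)
    perm = rng.permutation(len(yb))
    out = pd.DataFrame(Xb[perm], columns=table.columns)
    return out, pd.Series(yb[perm], name=getattr(labels, "name", "entity"))


# ---------------------------------------------------------------------------
# wrapper / best-first


@dataclass
class WrapperResult:
    classifier: str
    features: list
    score: float
    trajectory: list = field(default_factory=list)


def _cv_accuracy(build, X, y, folds, seed):
    from sklearn.model_selection import StratifiedKFold

    _, counts = np.unique(y, return_counts=True)
    folds = min(folds, counts.min())
    if folds < 2:
        raise ValueError("too few cases per class for internal CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    acc = []
    for tr, va in skf.split(X, y):
        model = build()
        model.fit(X[tr], y[tr])
        acc.append(float((model.predict(X[va]) == y[va]).mean()))
    return float(np.mean(acc))


def wrapper_select(table: pd.DataFrame, labels: pd.Series, classifier_spec,
                   seed: int, folds: int = 5,
                   max_stale: int = 5) -> WrapperResult:
    """Best-first forward subset search scored by internal CV accuracy.

    Expands the best open subset by one feature at a time and stops after
    ``max_stale`` consecutive expansions without improving on the best
    subset found.  Deterministic for a fixed seed.
    """
    from .classify import build_classifier

    X = table.to_numpy(dtype=float)
    y = np.asarray(labels)
    names = list(table.columns)
    if X.shape[1] == 0 or len(np.unique(y)) < 2:
        raise ValueError("degenerate table for wrapper selection")

    def score(subset: tuple) -> float:
        cols = list(subset)
        return _cv_accuracy(
            lambda: build_classifier(classifier_spec, n_features=len(cols),
                                     n_classes=len(np.unique(y))),
            X[:, cols], y, folds, seed)

    best = (-1.0, ())
    open_set: list[tuple[float, tuple]] = [(0.0, ())]
    scored: dict[tuple, float] = {(): 0.0}
    trajectory = []
    stale = 0
    while open_set and stale < max_stale:
        open_set.sort(key=lambda t: (-t[0], t[1]))
        cur_score, cur = open_set.pop(0)
        improved = False
        for j in range(len(names)):
            if j in cur:
                continue
            cand = tuple(sorted(cur + (j,)))
            if cand in scored:
                continue
            s = score(cand)
            scored[cand] = s
            open_set.append((s, cand))
            if s > best[0] + 1e-12:
                best = (s, cand)
                improved = True
        trajectory.append(best[0])
        stale = 0 if improved else stale + 1
    return WrapperResult(
        classifier=getattr(classifier_spec, "family", str(classifier_spec)),
        features=[names[j] for j in best[1]],
        score=best[0],
        trajectory=trajectory,
    )
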