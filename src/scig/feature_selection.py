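"""Screen-prune-search-extend feature selection.

The pipeline: (1) a two-sided Wilcoxon rank-sum screen keeps features that
separate CIGs from both control and housekeeping genes; (2) correlated
features (|r| > 0.9) are pruned, keeping the member with the stronger
CIG-vs-control difference; (3) every 3-feature combination is scored by
mean 10-fold cross-validated MCC of an L1-logistic model; (4) the best
triple is greedily extended by forward selection until the MCC stops
improving.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold

from .io_formats import LabelSet
from .sequence_features import FeatureTable


def wilcoxon_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value: exact enumeration when both groups are
    small (n <= 8) and tie-free, else the tie-corrected normal approximation
    with continuity correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size <= 1:
        return 1.0
    exact = len(a) <= 8 and len(b) <= 8 and np.unique(pooled).size == pooled.size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
    return float(min(res.pvalue, 1.0))


@dataclass
class ScreenReport:
    """Per-feature screen outcome; dropped features carry a reason."""

    table: pd.DataFrame  # index: feature; p_vs_control, p_vs_housekeeping, kept, drop_reason

    @property
    def kept_features(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def wilcoxon_screen(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    alpha: float = 0.05,
    rule: str = "both",
) -> ScreenReport:
    """Drop features that fail to separate CIGs from the reference classes.

    With ``rule="both"`` a feature is kept iff p <= alpha against both the
    control and the housekeeping group; ``rule="any"`` requires only one.
    Missing values are dropped pairwise; a feature with fewer than two
    usable values in any class is dropped.
    """
    df = table.df if isinstance(table, FeatureTable) else table
    groups = {
        lab: df.index.intersection(labels.genes_with(lab))
        for lab in ("cig", "control", "housekeeping")
    }
    rows = []
    for feat in df.columns:
        col = df[feat]
        vals = {lab: col.loc[idx].dropna().to_numpy() for lab, idx in groups.items()}
        if any(v.size < 2 for v in vals.values()):
            rows.append((feat, np.nan, np.nan, False, "insufficient_values"))
            continue
        p_ctrl = wilcoxon_pvalue(vals["cig"], vals["control"])
        p_hk = wilcoxon_pvalue(vals["cig"], vals["housekeeping"])
        sig = (p_ctrl <= alpha, p_hk <= alpha)
        kept = all(sig) if rule == "both" else any(sig)
        reason = "" if kept else "p_above_alpha"
        rows.append((feat, p_ctrl, p_hk, kept, reason))
    rep = pd.DataFrame(
        rows, columns=["feature", "p_vs_control", "p_vs_housekeeping", "kept", "drop_reason"]
    ).set_index("feature")
    return ScreenReport(rep)


def correlation_prune(
    table: FeatureTable | pd.DataFrame,
    screen: ScreenReport,
    r_max: float = 0.90,
) -> list[str]:
    """Break up highly correlated feature pairs among screen survivors.

    Pairs with |Pearson r| > r_max (pairwise-complete) are processed in
    descending |r| (ties by pair name); in each still-live pair the feature
    with the larger CIG-vs-control p-value is dropped (ties by the
    lexicographically larger name).
    """
    df = table.df if isinstance(table, FeatureTable) else table
    kept = screen.kept_features
    if len(kept) < 2:
        return kept
    corr = df[kept].corr(method="pearson").abs()
    pairs = []
    for i, f1 in enumerate(kept):
        for f2 in kept[i + 1 :]:
            r = corr.loc[f1, f2]
            if np.isfinite(r) and r > r_max:
                pairs.append((r, *sorted((f1, f2))))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    dropped: set[str] = set()
    pvals = screen.table["p_vs_control"]
    for _, f1, f2 in pairs:
        if f1 in dropped or f2 in dropped:
            continue
        p1, p2 = pvals.get(f1, np.nan), pvals.get(f2, np.nan)
        if np.isnan(p1):
            p1 = np.inf
        if np.isnan(p2):
            p2 = np.inf
        if p1 > p2 or (p1 == p2 and f1 > f2):
            dropped.add(f1)
        else:
            dropped.add(f2)
    return [f for f in kept if f not in dropped]


# ---------------------------------------------------------------------------
# CV machinery shared by triple search and forward selection


def _binary_labels(df: pd.DataFrame, labels: LabelSet) -> tuple[pd.DataFrame, np.ndarray]:
    cig = df.index.intersection(labels.genes_with("cig"))
    ctrl = df.index.intersection(labels.genes_with("control"))
    sub = df.loc[list(cig) + list(ctrl)]
    y = np.array([1] * len(cig) + [0] * len(ctrl))
    return sub, y


class _FoldedData:
    """Pre-standardized feature columns per CV fold.

    Standardization (median imputation + z-scoring) is refit on each fold's
    training rows so that the per-fold model never sees test statistics;
    the fold assignment is shared across all candidate feature sets so MCC
    comparisons are paired.
    """

    def __init__(self, X: pd.DataFrame, y: np.ndarray, cv: int, seed: int):
        self.y = y
        self.features = list(X.columns)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        self.folds = list(skf.split(np.zeros(len(y)), y))
        arr = X.to_numpy(dtype=float)
        self.z = []  # per fold: standardized full matrix
        for train_idx, _ in self.folds:
            train = arr[train_idx]
            med = np.nanmedian(train, axis=0)
            filled = np.where(np.isnan(arr), med, arr)
            mu = filled[train_idx].mean(axis=0)
            sd = filled[train_idx].std(axis=0)
            sd[sd == 0] = 1.0
            self.z.append((filled - mu) / sd)

    def mean_cv_mcc(self, cols: list[int], C: float = 1.0, seed: int = 0) -> float:
        mccs = []
        for (train_idx, test_idx), z in zip(self.folds, self.z):
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=C, tol=1e-4,
                intercept_scaling=10.0, random_state=seed, max_iter=1000,
            )
            clf.fit(z[np.ix_(train_idx, cols)], self.y[train_idx])
            pred = clf.predict(z[np.ix_(test_idx, cols)])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mccs.append(matthews_corrcoef(self.y[test_idx], pred))
        return float(np.mean(mccs))


@dataclass
class SelectionResult:
    """Ranked candidate combinations and the forward-selection outcome."""

    candidates: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)
    trace: list[tuple[str, float]] = field(default_factory=list)  # (feature added, MCC after)

    def to_dict(self) -> dict:
        return {
            "candidates": [[list(f), m] for f, m in self.candidates],
            "final_features": self.final_features,
            "trace": [[f, m] for f, m in self.trace],
        }


def triple_search(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    pool: list[str],
    top_k: int = 10000,
    cv: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> SelectionResult:
    """Exhaustively score every 3-feature combination by mean CV-MCC.

    Returns the top ``top_k`` combinations sorted by MCC (descending),
    ties broken by the feature-name tuple. The stratified fold assignment
    is fixed by ``seed`` and shared across all triples.
    """
    if len(pool) < 3:
        raise ValueError("triple_search needs a pool of >= 3 features")
    df = table.df if isinstance(table, FeatureTable) else table
    X, y = _binary_labels(df[pool], labels)
    if min((y == 1).sum(), (y == 0).sum()) < cv:
        raise ValueError("each class must have at least `cv` members")
    folded = _FoldedData(X, y, cv=cv, seed=seed)
    results = []
    for combo in combinations(range(len(pool)), 3):
        mcc = folded.mean_cv_mcc(list(combo), C=C, seed=seed)
        results.append((tuple(pool[i] for i in combo), mcc))
    results.sort(key=lambda t: (-t[1], t[0]))
    return SelectionResult(candidates=results[:top_k])


def forward_select(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    seed_set: tuple[str, ...],
    pool: list[str],
    cv: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
    C: float = 1.0,
) -> SelectionResult:
    """Greedily grow ``seed_set`` with the pool feature that most improves
    mean CV-MCC; stop when the best improvement is <= tol."""
    df = table.df if isinstance(table, FeatureTable) else table
    all_feats = list(dict.fromkeys(list(seed_set) + list(pool)))
    X, y = _binary_labels(df[all_feats], labels)
    folded = _FoldedData(X, y, cv=cv, seed=seed)
    idx_of = {f: i for i, f in enumerate(all_feats)}
    current = list(seed_set)
    current_mcc = folded.mean_cv_mcc([idx_of[f] for f in current], C=C, seed=seed)
    trace = [("+".join(seed_set), current_mcc)]
    remaining = [f for f in pool if f not in current]
    while remaining:
        scored = [
            (folded.mean_cv_mcc([idx_of[f] for f in current + [cand]], C=C, seed=seed), cand)
            for cand in remaining
        ]
        best_mcc, best_feat = max(scored, key=lambda t: (t[0], t[1]))
        if best_mcc - current_mcc <= tol:
            break
        current.append(best_feat)
        current_mcc = best_mcc
        trace.append((best_feat, best_mcc))
        remaining.remove(best_feat)
    return SelectionResult(final_features=current, trace=trace)


def run_selection(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    alpha: float = 0.05,
    r_max: float = 0.90,
    top_k: int = 10000,
    cv: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
    screen_rule: str = "both",
    n_seeds: int = 1,
    max_pool: int | None = None,
) -> tuple[ScreenReport, list[str], SelectionResult]:
    """Full screen -> prune -> triple search -> forward selection pipeline.

    ``n_seeds`` forward-extends the top-k triples and returns the best
    final set (default: only the single best triple). ``max_pool`` caps the
    pool entering the exhaustive triple search at the features with the
    smallest CIG-vs-control p-values (ties by name), which keeps the
    combinatorial stage tractable on wide feature tables.
    """
    screen = wilcoxon_screen(table, labels, alpha=alpha, rule=screen_rule)
    pruned = correlation_prune(table, screen, r_max=r_max)
    if max_pool is not None and len(pruned) > max_pool:
        pvals = screen.table["p_vs_control"]
        pruned = sorted(pruned, key=lambda f: (pvals.get(f, np.inf), f))[:max_pool]
    if len(pruned) < 3:
        result = SelectionResult(final_features=pruned)
        return screen, pruned, result
    triples = triple_search(table, labels, pruned, top_k=top_k, cv=cv, seed=seed)
    best: SelectionResult | None = None
    best_mcc = -np.inf
    for combo, _ in triples.candidates[: max(1, n_seeds)]:
        fwd = forward_select(table, labels, combo, pruned, cv=cv, tol=tol, seed=seed)
        final_mcc = fwd.trace[-1][1]
        if final_mcc > best_mcc:
            best, best_mcc = fwd, final_mcc
    assert best is not None
    best.candidates = triples.candidates
    return screen, pruned, best
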