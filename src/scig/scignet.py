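"""Master-TF ranking from gene-regulatory-network features (SCIGNet).

Edges from several curated GRN resources are collapsed by vote count and
filtered to those supported by at least two sources. For each TF, 23
network features are computed (edge counts, the TF's own CIG score and
expression, and mean/median/CV of CIG score and expression over its
children, parents and their union); a class-balanced (SMOTE) L1-logistic
model then ranks TFs by master-regulator character.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cig_model import (
    EvalReport,
    ScoreResult,
    TrainedCIGModel,
    cross_validate,
    empirical_pvalues,
    standardize,
    train_cig_model,
)
from .feature_selection import run_selection
from .io_formats import LabelSet

log = logging.getLogger(__name__)

NETWORK_FEATURE_NAMES = (
    ["n_children", "n_parents", "n_total", "tf_cig_score", "tf_expression"]
    + [
        f"{group}_{quantity}_{stat}"
        for group in ("children", "parents", "neighbors")
        for quantity in ("cig_score", "expression")
        for stat in ("mean", "median", "cv")
    ]
)


@dataclass
class GRN:
    """Directed regulator -> target edge set with per-edge source votes."""

    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    self_loops: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._children: dict[str, list[str]] = {}
        self._parents: dict[str, list[str]] = {}
        for (reg, tgt), votes in self.edges.items():
            if votes < 1:
                raise ValueError(f"edge {reg}->{tgt} has vote {votes} < 1")
            self._children.setdefault(reg, []).append(tgt)
            self._parents.setdefault(tgt, []).append(reg)

    @property
    def nodes(self) -> set[str]:
        out = set()
        for reg, tgt in self.edges:
            out.add(reg)
            out.add(tgt)
        return out

    def children(self, node: str) -> list[str]:
        return self._children.get(node, [])

    def parents(self, node: str) -> list[str]:
        return self._parents.get(node, [])

    def edge_frame(self) -> pd.DataFrame:
        rows = [(r, t, v) for (r, t), v in sorted(self.edges.items())]
        return pd.DataFrame(rows, columns=["regulator", "target", "votes"])


def read_edge_list(path: str) -> pd.DataFrame:
    """Two-column TSV: regulator, target (a header row is tolerated)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if list(df.iloc[0]) == ["regulator", "target"]:
        df = df.iloc[1:]
    df.columns = ["regulator", "target"]
    return df.reset_index(drop=True)


def compile_grn(
    edge_lists: list[pd.DataFrame],
    min_votes: int = 2,
    keep_nodes: set[str] | None = None,
) -> GRN:
    """Collapse per-source edge lists by distinct-source vote count.

    Duplicate rows within one source count once; edges below ``min_votes``
    are removed; ``keep_nodes`` restricts both endpoints (e.g. to
    protein-coding genes). Self-loops are kept but flagged.
    """
    if len(edge_lists) < min_votes:
        raise ValueError(
            f"need >= min_votes ({min_votes}) sources, got {len(edge_lists)}"
        )
    votes: dict[tuple[str, str], int] = {}
    for df in edge_lists:
        pairs = {(str(r), str(t)) for r, t in zip(df["regulator"], df["target"])}
        for pair in pairs:
            votes[pair] = votes.get(pair, 0) + 1
    kept = {
        pair: v
        for pair, v in votes.items()
        if v >= min_votes
        and (keep_nodes is None or (pair[0] in keep_nodes and pair[1] in keep_nodes))
    }
    if not kept:
        log.warning("compiled GRN is empty")
    loops = [pair for pair in kept if pair[0] == pair[1]]
    if loops:
        log.warning("GRN contains %d self-loop edges", len(loops))
    return GRN(edges=kept, self_loops=loops)


def _agg(values: list[float]) -> dict[str, float]:
    arr = np.array(values, dtype=float)
    if arr.size == 0:
        return {"mean": np.nan, "median": np.nan, "cv": np.nan}
    mean = float(arr.mean())
    cv = float(arr.std() / mean) if arr.size >= 2 and mean != 0 else np.nan
    return {"mean": mean, "median": float(np.median(arr)), "cv": cv}


def tf_network_features(
    grn: GRN,
    scores: pd.Series,
    expr: pd.Series,
    tfs: list[str],
) -> pd.DataFrame:
    """The 23 per-TF network features.

    Children = out-neighbours (targets), parents = in-neighbours
    (regulators); "neighbors" concatenates both lists, so a gene that is
    simultaneously child and parent contributes twice, making the combined
    mean equal (sum_children + sum_parents) / (n_children + n_parents).
    Genes without a score/expression value are excluded from aggregates.
    """
    rows = {}
    for tf in tfs:
        children = grn.children(tf)
        parents = grn.parents(tf)
        rec = {
            "n_children": float(len(children)),
            "n_parents": float(len(parents)),
            "n_total": float(len(children) + len(parents)),
            "tf_cig_score": float(scores.get(tf, np.nan)),
            "tf_expression": float(expr.get(tf, np.nan)),
        }
        for group_name, members in (
            ("children", children),
            ("parents", parents),
            ("neighbors", children + parents),
        ):
            for qty_name, series in (("cig_score", scores), ("expression", expr)):
                vals = [series[g] for g in members if g in series.index and np.isfinite(series[g])]
                for stat, v in _agg(vals).items():
                    rec[f"{group_name}_{qty_name}_{stat}"] = v
        rows[tf] = rec
    return pd.DataFrame.from_dict(rows, orient="index")[NETWORK_FEATURE_NAMES]


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    X: pd.DataFrame,
    y: np.ndarray,
    target_per_class: int,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Balance both classes to ``target_per_class`` rows.

    Synthetic minority rows interpolate between a minority point and one of
    its k nearest minority neighbours (Euclidean distance on standardized
    features, interpolation in the original feature space); the majority
    class is subsampled without replacement.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance needs exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    X_min = X[y == minority]
    X_maj = X[y == majority]
    if len(X_min) < 2:
        raise ValueError("minority class must have >= 2 members")
    k_eff = min(k, len(X_min) - 1)

    new_rows = []
    n_needed = target_per_class - len(X_min)
    if n_needed < 0:
        log.warning(
            "target %d below minority size %d; subsampling minority instead",
            target_per_class, len(X_min),
        )
        idx = rng.choice(len(X_min), size=target_per_class, replace=False)
        X_min = X_min.iloc[idx]
        n_needed = 0
    if n_needed > 0:
        Xz, _ = standardize(X_min)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xz.to_numpy())
        _, nbr = nn.kneighbors(Xz.to_numpy())
        arr = X_min.to_numpy(dtype=float)
        for j in range(n_needed):
            i = int(rng.integers(len(X_min)))
            m = int(nbr[i][1 + rng.integers(k_eff)])  # skip self at position 0
            u = rng.uniform()
            new_rows.append(arr[i] + u * (arr[m] - arr[i]))
    synthetic = pd.DataFrame(
        new_rows,
        columns=X.columns,
        index=[f"synthetic_{minority}_{j}" for j in range(len(new_rows))],
    )
    if target_per_class > len(X_maj):
        raise ValueError(
            f"majority class ({len(X_maj)}) smaller than target {target_per_class}"
        )
    keep = rng.choice(len(X_maj), size=target_per_class, replace=False)
    X_maj_sub = X_maj.iloc[np.sort(keep)]
    parts = [df for df in (X_min, synthetic, X_maj_sub) if len(df)]
    X_out = pd.concat(parts)
    y_out = np.concatenate(
        [
            np.full(len(X_min) + len(synthetic), minority),
            np.full(len(X_maj_sub), majority),
        ]
    )
    return X_out, y_out


# ---------------------------------------------------------------------------
# master-TF model


def train_master_tf_model(
    features: pd.DataFrame,
    master_tfs: set[str],
    target_per_class: int | None = None,
    k: int = 5,
    cv: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[TrainedCIGModel, EvalReport, list[str]]:
    """Balance, select features and fit the master-TF logistic model.

    Feature selection reuses the screen/triple-search/forward-selection
    machinery on the 23 network columns (the control class doubles as the
    housekeeping reference for the screen). Returns the fitted model, the
    10-fold CV report on the balanced data and the selected feature list.
    """
    y = np.array([1 if tf in master_tfs else 0 for tf in features.index])
    if target_per_class is None:
        # oversample the minority up to the majority size, capped at 221
        # rows per class (the balance used for the reference training set)
        counts = np.bincount(y, minlength=2)
        target_per_class = int(min(counts.max(), 221))
    usable = features.dropna(axis=1, how="all")
    Xb, yb = smote_balance(usable, y, target_per_class=target_per_class, k=k, seed=seed)
    label_series = pd.Series(
        np.where(yb == 1, "cig", "control"), index=Xb.index
    )
    # the screen needs a third reference class; reuse a slice of the controls
    ctrl_idx = label_series[label_series == "control"].index
    hk = ctrl_idx[: max(2, len(ctrl_idx) // 3)]
    label_series.loc[hk] = "housekeeping"
    labels = LabelSet(label_series)
    n_ctrl = int((label_series == "control").sum())
    cv_sel = max(2, min(cv, target_per_class, n_ctrl))
    screen, pruned, selection = run_selection(
        Xb, labels, cv=cv_sel, seed=seed, top_k=50, n_seeds=1
    )
    selected = selection.final_features or pruned or list(usable.columns)[:3]
    # refit/evaluate with the housekeeping rows restored as controls
    full_labels = LabelSet(pd.Series(np.where(yb == 1, "cig", "control"), index=Xb.index))
    cv_eval = max(2, min(cv, target_per_class))
    report = cross_validate(Xb, full_labels, selected, cv=cv_eval, seed=seed, C=C)
    model = train_cig_model(Xb, full_labels, selected, C=C, seed=seed)
    model.metadata["kind"] = "master_tf"
    return model, report, selected


def rank_tfs(
    model: TrainedCIGModel,
    features: pd.DataFrame,
    control_scores: np.ndarray,
    fdr_threshold: float = 0.05,
) -> ScoreResult:
    """Score all TFs, attach empirical p / BH-FDR and a 1-based rank."""
    from statsmodels.stats.multitest import multipletests

    probs = model.predict_proba(features)
    pvals = empirical_pvalues(probs.to_numpy(), control_scores)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "score": probs,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        },
        index=features.index,
    )
    out = out.sort_values(["score", "fdr"], ascending=[False, True])
    out = out.iloc[np.lexsort((out.index, -out["score"].to_numpy()))]
    out["rank"] = np.arange(1, len(out) + 1)
    return ScoreResult(out)
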