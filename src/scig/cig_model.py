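"""The L1-logistic cell-identity-gene classifier.

A gene's CIG score is the logistic probability that it belongs to the
positive (cell identity) class given its standardized features. Statistical
calls are made against an empirical null built from the scores of reference
control genes: p(g) = (#{controls scoring >= g} + 1) / (n_controls + 1),
adjusted by Benjamini-Hochberg across all scored genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, LabelSet
from .sequence_features import FeatureTable

#: feature name under which the per-sample expression level enters the model
EXPRESSION_FEATURE = "expression"


def standardize(
    table: pd.DataFrame, fit_rows: list | pd.Index | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-impute then z-score; parameters come from ``fit_rows`` only.

    Returns the transformed table and a parameter frame (median, mean, sd
    per feature, population sd). Constant features raise by name.
    """
    table = table.astype(float)
    fit = table.loc[fit_rows] if fit_rows is not None else table
    med = fit.median()
    filled = table.fillna(med)
    fit_filled = filled.loc[fit.index]
    mu = fit_filled.mean()
    sd = fit_filled.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant feature(s) in fit rows: {constant}")
    params = pd.DataFrame({"median": med, "mean": mu, "sd": sd})
    return (filled - mu) / sd, params


@dataclass
class TrainedCIGModel:
    """Selected features, standardization parameters and logistic weights."""

    feature_names: list[str]
    medians: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    C: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.medians = np.asarray(self.medians, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")
        if (self.sds <= 0).any():
            raise ValueError("standardization sd must be positive")

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks model features: {missing}")
        x = features[self.feature_names].to_numpy(dtype=float)
        x = np.where(np.isnan(x), self.medians, x)
        return (x - self.means) / self.sds

    def predict_proba(self, features: pd.DataFrame) -> pd.Series:
        z = self.transform(features) @ self.coefficients + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-z)), index=features.index, name="cig_score")

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "medians": self.medians.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedCIGModel":
        return cls(
            feature_names=list(d["feature_names"]),
            medians=d["medians"],
            means=d["means"],
            sds=d["sds"],
            coefficients=d["coefficients"],
            intercept=float(d["intercept"]),
            C=float(d.get("C", 1.0)),
            metadata=d.get("metadata", {}),
        )


def fit_l1_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-6,
    seed: int = 0,
    params: pd.DataFrame | None = None,
) -> TrainedCIGModel:
    """Fit the L1-penalized logistic model on standardized features.

    ``params`` carries the standardization statistics to embed in the
    returned model; when omitted, identity scaling is stored (the caller
    standardized elsewhere or the features are already on model scale).
    """
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit")
    clf = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=C, tol=tol,
        intercept_scaling=10.0, random_state=seed, max_iter=5000,
    )
    clf.fit(X.to_numpy(dtype=float), y)
    if clf.n_iter_ is not None and np.max(clf.n_iter_) >= 5000:
        raise RuntimeError(f"L1 logistic did not converge in {np.max(clf.n_iter_)} iterations")
    p = X.shape[1]
    if params is not None:
        med = params["median"].to_numpy()
        mu = params["mean"].to_numpy()
        sd = params["sd"].to_numpy()
    else:
        med = np.zeros(p)
        mu = np.zeros(p)
        sd = np.ones(p)
    return TrainedCIGModel(
        feature_names=list(X.columns),
        medians=med,
        means=mu,
        sds=sd,
        coefficients=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        C=C,
        metadata={"seed": seed, "n_pos": int((y == 1).sum()), "n_neg": int((y == 0).sum())},
    )


# ---------------------------------------------------------------------------
# metrics


def auroc_rank(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the Mann-Whitney statistic; ties receive half credit."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n1 = int((y_true == 1).sum())
    n0 = int((y_true == 0).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class EvalReport:
    """Confusion-matrix metrics plus optional per-fold/bootstrap detail."""

    metrics: dict[str, float]
    per_fold: pd.DataFrame | None = None
    bootstrap: pd.DataFrame | None = None

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


def classification_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> EvalReport:
    """Sensitivity/specificity/accuracy/MCC/F1 at the 0.5 cut, plus AUROC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / len(y_true)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    f1 = (2 * tp / (2 * tp + fp + fn)) if (2 * tp + fp + fn) else np.nan
    auroc = auroc_rank(y_true, scores) if scores is not None else np.nan
    return EvalReport(
        metrics={
            "sensitivity": sens, "specificity": spec, "accuracy": acc,
            "mcc": float(mcc), "f1": f1, "auroc": auroc,
        }
    )


def _prepare_xy(
    table: FeatureTable | pd.DataFrame, labels: LabelSet, features: list[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    df = table.df if isinstance(table, FeatureTable) else table
    cig = df.index.intersection(labels.genes_with("cig"))
    ctrl = df.index.intersection(labels.genes_with("control"))
    X = df.loc[list(cig) + list(ctrl), features]
    y = np.array([1] * len(cig) + [0] * len(ctrl))
    return X, y


def cross_validate(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    features: list[str],
    cv: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> EvalReport:
    """Stratified k-fold evaluation with in-fold standardization.

    Out-of-fold predictions are pooled and scored once; per-fold metrics
    are reported alongside.
    """
    X, y = _prepare_xy(table, labels, features)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    oof_score = np.zeros(len(y))
    fold_rows = []
    for k, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        Xz, params = standardize(X, fit_rows=X.index[tr])
        model = fit_l1_logistic(Xz.iloc[tr], y[tr], C=C, tol=1e-6, seed=seed, params=None)
        probs = model.predict_proba(Xz.iloc[te]).to_numpy()
        oof_score[te] = probs
        rep = classification_metrics(y[te], (probs >= 0.5).astype(int), probs)
        fold_rows.append({"fold": k, **rep.metrics})
    pooled = classification_metrics(y, (oof_score >= 0.5).astype(int), oof_score)
    pooled.per_fold = pd.DataFrame(fold_rows)
    return pooled


def bootstrap_evaluate(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    features: list[str],
    iterations: int = 500,
    train_frac: float = 0.8,
    seed: int = 0,
    C: float = 1.0,
) -> EvalReport:
    """Repeated stratified 80/20 splits; mean and sd of test metrics."""
    X, y = _prepare_xy(table, labels, features)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(iterations) % (2**31 - 1)
    for it in range(iterations):
        tr, te = train_test_split(
            np.arange(len(y)), train_size=train_frac, stratify=y,
            random_state=int(child_seeds[it]),
        )
        Xz, _ = standardize(X, fit_rows=X.index[tr])
        model = fit_l1_logistic(Xz.iloc[tr], y[tr], C=C, tol=1e-6, seed=seed)
        probs = model.predict_proba(Xz.iloc[te]).to_numpy()
        rep = classification_metrics(y[te], (probs >= 0.5).astype(int), probs)
        rows.append({"iteration": it, **rep.metrics})
    boot = pd.DataFrame(rows)
    metric_cols = [c for c in boot.columns if c != "iteration"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summary = {f"{c}_mean": float(np.nanmean(boot[c])) for c in metric_cols}
        summary.update({f"{c}_sd": float(np.nanstd(boot[c])) for c in metric_cols})
    return EvalReport(metrics=summary, bootstrap=boot)


def train_cig_model(
    table: FeatureTable | pd.DataFrame,
    labels: LabelSet,
    features: list[str],
    C: float = 1.0,
    seed: int = 0,
) -> TrainedCIGModel:
    """Fit the final model on all labeled genes (CIG vs control)."""
    X, y = _prepare_xy(table, labels, features)
    Xz, params = standardize(X)
    model = fit_l1_logistic(Xz, y, C=C, tol=1e-6, seed=seed, params=params)
    model.metadata["features"] = features
    return model


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ScoreResult:
    """Per-gene CIG score with empirical p, BH-FDR and significance call."""

    table: pd.DataFrame  # columns: cig_score, pvalue, fdr, significant

    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def empirical_pvalues(scores: np.ndarray, control_scores: np.ndarray) -> np.ndarray:
    """p(g) = (#{controls >= score_g} + 1) / (n_controls + 1)."""
    control = np.sort(np.asarray(control_scores, dtype=float))
    n = control.size
    ge = n - np.searchsorted(control, np.asarray(scores, dtype=float), side="left")
    return (ge + 1.0) / (n + 1.0)


def score_genes(
    model: TrainedCIGModel,
    feature_table: FeatureTable | pd.DataFrame,
    control_scores: np.ndarray,
    fdr_threshold: float = 0.05,
) -> ScoreResult:
    """Score genes and call significance against the control-score null."""
    df = feature_table.df if isinstance(feature_table, FeatureTable) else feature_table
    probs = model.predict_proba(df)
    pvals = empirical_pvalues(probs.to_numpy(), control_scores)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "cig_score": probs,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
        },
        index=df.index,
    )
    return ScoreResult(out.sort_values("cig_score", ascending=False))


def score_single_cells(
    model: TrainedCIGModel,
    static_features: pd.DataFrame,
    umi: ExpressionMatrix,
    mode: str = "log_cp10k",
    lengths: pd.Series | None = None,
) -> pd.DataFrame:
    """Gene x cell CIG score matrix.

    ``static_features`` holds the sequence + specificity columns (shared by
    every cell); the per-cell expression feature replaces the
    ``expression`` column for each cell in turn. Genes lacking static
    features are dropped with a warning.
    """
    from .expression_features import per_cell_expression_features

    import logging

    log = logging.getLogger(__name__)
    needed = [f for f in model.feature_names if f != EXPRESSION_FEATURE]
    missing_cols = [f for f in needed if f not in static_features.columns]
    if missing_cols:
        raise ValueError(f"static features lack model features: {missing_cols}")
    genes = static_features.index.intersection(umi.genes)
    dropped = umi.genes.difference(static_features.index)
    if len(dropped):
        log.warning("%d genes lack sequence features and are skipped", len(dropped))
    percell = per_cell_expression_features(umi, mode=mode, lengths=lengths)
    base = static_features.loc[genes, needed].copy()
    cols = {}
    for cell in percell.samples:
        feats = base.copy()
        feats[EXPRESSION_FEATURE] = percell.values.loc[genes, cell]
        cols[cell] = model.predict_proba(feats)
    return pd.DataFrame(cols, index=genes)
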