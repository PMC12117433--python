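"""Expression level, tissue-specificity and single-cell expression features.

Specificity indices (tau, Gini, Simpson, Shannon, ROKU) quantify how
concentrated a gene's expression is across a panel of tissues or cell
types; all five live in [0, 1] with 0 = uniform and 1 = confined to a
single sample (tau/Simpson/Shannon). They are computed once from a
reference atlas and joined to genes as constants; per-cell scoring only
swaps in the cell's own expression level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneModel
from .sequence_features import region_length

log = logging.getLogger(__name__)

SPECIFICITY_METRICS = ("tau", "gini", "simpson", "shannon_spec", "roku_spec")


def gene_lengths(models: list[GeneModel], length_mode: str = "exonic") -> pd.Series:
    """Per-gene length in bp under ``gene_span`` or ``exonic`` accounting."""
    if length_mode not in ("gene_span", "exonic"):
        raise ValueError(f"unknown length_mode {length_mode!r}")
    out = {}
    for m in models:
        out[m.gene_id] = (
            m.end - m.start if length_mode == "gene_span" else region_length(m.exons)
        )
    return pd.Series(out, dtype=float)


def compute_tpm(
    counts: ExpressionMatrix,
    models: list[GeneModel],
    length_mode: str = "exonic",
    log2: bool = False,
) -> ExpressionMatrix:
    """Length-normalized transcripts-per-million per sample.

    TPM_g = (c_g / L_g) / sum_j (c_j / L_j) * 1e6 with L in bp. With
    ``log2`` the companion log2(TPM + 1) matrix is returned instead.
    Samples with an empty library yield all-zero columns with a warning.
    """
    if counts.kind != "counts":
        raise ValueError(f"compute_tpm needs raw counts, got kind={counts.kind!r}")
    lengths = gene_lengths(models, length_mode).reindex(counts.genes)
    if lengths.isna().any() or (lengths <= 0).any():
        missing = lengths.index[lengths.isna() | (lengths <= 0)].tolist()
        raise ValueError(f"genes without a usable length: {missing[:5]}")
    rate = counts.values.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero_lib = denom == 0
    if zero_lib.any():
        log.warning("samples with zero library size: %s", list(denom.index[zero_lib]))
        denom = denom.replace(0, np.nan)
    tpm = (rate / denom * 1e6).fillna(0.0)
    if log2:
        return ExpressionMatrix(np.log2(tpm + 1.0), kind="log2tpm")
    return ExpressionMatrix(tpm, kind="tpm")


# ---------------------------------------------------------------------------
# specificity indices


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def tukey_biweight(x: np.ndarray, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate (median/MAD start)."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    if w.sum() == 0:
        return float(med)
    return float((w * x).sum() / w.sum())


def _specificity_one(x: np.ndarray) -> dict[str, float]:
    n = x.size
    total = x.sum()
    if total == 0:
        return {m: 0.0 for m in SPECIFICITY_METRICS}
    xmax = x.max()
    tau = float((1 - x / xmax).sum() / (n - 1))
    gini = float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n**2 * x.mean()))
    p = x / total
    simpson = float((p**2).sum())
    shannon = 1.0 - _entropy_bits(p) / np.log2(n)
    dev = np.abs(x - tukey_biweight(x))
    if dev.sum() == 0:
        roku = 0.0
    else:
        pp = dev / dev.sum()
        roku = 1.0 - _entropy_bits(pp) / np.log2(n)
    return {
        "tau": tau,
        "gini": gini,
        "simpson": simpson,
        "shannon_spec": float(shannon),
        "roku_spec": float(roku),
    }


def specificity_scores(expr: ExpressionMatrix) -> pd.DataFrame:
    """All five specificity indices per gene over the matrix's samples.

    Requires at least two samples and non-negative values; an all-zero
    gene scores 0 on every index by convention.
    """
    if expr.shape[1] < 2:
        raise ValueError("specificity needs >= 2 samples")
    rows = {
        gene: _specificity_one(expr.values.loc[gene].to_numpy(dtype=float))
        for gene in expr.genes
    }
    return pd.DataFrame.from_dict(rows, orient="index")[list(SPECIFICITY_METRICS)]


def gini_sorted(x: np.ndarray) -> float:
    """O(n log n) Gini via the sorted-vector identity (test oracle partner)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if x.sum() == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n**2 * x.mean()))


# ---------------------------------------------------------------------------
# single-cell handling


def pseudobulk_aggregate(umi: ExpressionMatrix, group_of: dict[str, str]) -> ExpressionMatrix:
    """Sum UMI counts of member cells per group (pseudo-bulk samples)."""
    if umi.kind != "counts":
        raise ValueError("pseudobulk_aggregate needs raw counts")
    missing = [c for c in umi.samples if c not in group_of]
    if missing:
        raise ValueError(f"cells without a group: {missing[:10]}")
    groups = pd.Series({c: group_of[c] for c in umi.samples})
    agg = umi.values.T.groupby(groups).sum().T
    return ExpressionMatrix(agg, kind="counts")


def per_cell_expression_features(
    umi: ExpressionMatrix,
    mode: str = "log_cp10k",
    lengths: pd.Series | None = None,
) -> ExpressionMatrix:
    """Per-cell normalized expression: log2(counts-per-10k + 1) by default.

    ``log_tpm`` additionally divides by gene length (bp) before
    normalizing. Zero-count cells yield all-zero columns with a warning.
    """
    if umi.kind != "counts":
        raise ValueError("per-cell features need raw counts")
    vals = umi.values
    if mode == "log_tpm":
        if lengths is None:
            raise ValueError("log_tpm mode requires gene lengths")
        vals = vals.div(lengths.reindex(vals.index), axis=0)
        scale = 1e6
    elif mode == "log_cp10k":
        scale = 1e4
    else:
        raise ValueError(f"unknown mode {mode!r}")
    totals = vals.sum(axis=0)
    zero = totals == 0
    if zero.any():
        log.warning("cells with zero counts: %s", list(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    norm = np.log2(vals / totals * scale + 1.0).fillna(0.0)
    return ExpressionMatrix(norm, kind="percell_lognorm")
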