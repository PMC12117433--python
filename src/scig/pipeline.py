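"""One-shot orchestration: extract -> select -> train -> score -> rank TFs.

A run reads every input named in a :class:`RunConfig`, writes the feature
table, selection report, trained model, gene scores and (when GRN edges are
supplied) TF ranks into a run directory together with a manifest of input
checksums, parameters and library versions. Re-running the same config on
the same inputs reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cig_model import (
    EXPRESSION_FEATURE,
    bootstrap_evaluate,
    cross_validate,
    score_genes,
    train_cig_model,
)
from .expression_features import compute_tpm, specificity_scores
from .feature_selection import run_selection
from .io_formats import (
    read_bed,
    read_gene_list,
    read_gene_models,
    read_genome,
    read_labels,
    read_matrix,
    read_motifs,
    read_track,
    save_model,
)
from .scignet import compile_grn, rank_tfs, read_edge_list, tf_network_features, train_master_tf_model
from .sequence_features import SequenceFeatureConfig, build_sequence_feature_table

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All inputs and tunables of a pipeline run (seed mandatory)."""

    fasta: str
    gtf: str
    labels: str
    bulk_counts: str
    atlas_counts: str
    seed: int
    outdir: str
    motifs: str | None = None
    rbp_bed: str | None = None
    mirna_bed: str | None = None
    bedgraph: str | None = None
    umi_counts: str | None = None
    edges: list[str] = field(default_factory=list)
    tf_list: str | None = None
    master_labels: str | None = None
    windows: tuple[int, ...] = (500, 1000, 2000, 5000)
    score_fraction: float = 0.8
    length_mode: str = "exonic"
    alpha: float = 0.05
    r_max: float = 0.90
    top_k: int = 10000
    max_pool: int = 12
    cv: int = 10
    bootstrap: int = 500
    C: float = 1.0
    fdr: float = 0.05
    min_votes: int = 2

    def __post_init__(self) -> None:
        for name, value, lo, hi in (
            ("alpha", self.alpha, 0, 1),
            ("r_max", self.r_max, 0, 1),
            ("fdr", self.fdr, 0, 1),
            ("score_fraction", self.score_fraction, 0, 1),
        ):
            if not (lo < value <= hi):
                raise ValueError(f"{name}={value} outside ({lo},{hi}]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "windows" in raw:
            raw["windows"] = tuple(raw["windows"])
        return cls(**raw)


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic child seed per pipeline stage (stable across runs)."""
    return int((seed * 1000003 + stage) % (2**31 - 1))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(cfg: RunConfig, min_overlap: float = 0.5) -> dict:
    """Cross-check id spaces and emptiness; returns a report, raises nothing."""
    report: dict[str, list[str]] = {"issues": [], "warnings": []}
    try:
        models = read_gene_models(cfg.gtf)
        gtf_genes = {m.gene_id for m in models}
    except Exception as exc:  # report-only contract
        report["issues"].append(f"gtf unreadable: {exc}")
        return report
    if not gtf_genes:
        report["issues"].append("gtf contains no gene models")
    for name, path in (("bulk_counts", cfg.bulk_counts), ("labels", cfg.labels)):
        try:
            if name == "labels":
                ids = set(read_labels(path).labels.index)
            else:
                ids = set(read_matrix(path).genes)
        except Exception as exc:
            report["issues"].append(f"{name} unreadable: {exc}")
            continue
        if not ids:
            report["issues"].append(f"{name} is empty")
            continue
        absent = sorted(ids - gtf_genes)
        if absent:
            report["warnings"].append(
                f"{name}: {len(absent)} ids absent from GTF (e.g. {absent[:5]})"
            )
        overlap = len(ids & gtf_genes) / len(ids)
        if overlap < min_overlap:
            report["issues"].append(
                f"{name}: only {overlap:.0%} of ids overlap the GTF gene set"
            )
    return report


def build_feature_table(cfg: RunConfig) -> pd.DataFrame:
    """Sequence + expression + specificity features for every gene."""
    genome = read_genome(cfg.fasta)
    models = read_gene_models(cfg.gtf)
    seq_cfg = SequenceFeatureConfig(
        promoter_windows=tuple(cfg.windows), score_fraction=cfg.score_fraction
    )
    seq = build_sequence_feature_table(
        models,
        genome,
        motifs=read_motifs(cfg.motifs) if cfg.motifs else None,
        rbp_sites=read_bed(cfg.rbp_bed) if cfg.rbp_bed else None,
        mirna_sites=read_bed(cfg.mirna_bed) if cfg.mirna_bed else None,
        track=read_track(cfg.bedgraph) if cfg.bedgraph else None,
        config=seq_cfg,
    ).df

    bulk = read_matrix(cfg.bulk_counts)
    log2tpm = compute_tpm(bulk, models, length_mode=cfg.length_mode, log2=True)
    expression = log2tpm.values.iloc[:, 0].rename(EXPRESSION_FEATURE)

    atlas = read_matrix(cfg.atlas_counts)
    atlas_log = compute_tpm(atlas, models, length_mode=cfg.length_mode, log2=True)
    spec = specificity_scores(atlas_log)

    features = seq.join(expression, how="inner").join(spec, how="left")
    return features


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage failure aborts with the stage name after removing the files
    this run had already written.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    log_lines: list[str] = []

    def _stage(name: str):
        log_lines.append(f"{name}\t{time.time() - t0:.1f}s")
        log.info("stage %s (t=%.1fs)", name, time.time() - t0)

    def _write_df(df: pd.DataFrame, name: str, **kw) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kw)
        written.append(path)
        return path

    try:
        stage = "io_formats"
        _stage(stage)
        labels = read_labels(cfg.labels)

        stage = "features"
        _stage(stage)
        features = build_feature_table(cfg)
        _write_df(features, "features.tsv")
        inventory = {"columns": list(features.columns), "n_genes": len(features)}
        inv_path = outdir / "feature_inventory.json"
        inv_path.write_text(json.dumps(inventory, indent=1))
        written.append(inv_path)

        stage = "selection"
        _stage(stage)
        screen, pruned, selection = run_selection(
            features,
            labels,
            alpha=cfg.alpha,
            r_max=cfg.r_max,
            top_k=cfg.top_k,
            cv=cfg.cv,
            seed=stage_seed(cfg.seed, 1),
            max_pool=cfg.max_pool,
        )
        sel_path = outdir / "selection.json"
        sel_path.write_text(
            json.dumps(
                {
                    "screened": screen.kept_features,
                    "pruned_pool": pruned,
                    "selected": selection.final_features,
                    "trace": selection.to_dict()["trace"],
                    "top_candidates": selection.to_dict()["candidates"][:50],
                },
                indent=1,
            )
        )
        written.append(sel_path)
        selected = selection.final_features

        stage = "train"
        _stage(stage)
        cv_report = cross_validate(
            features, labels, selected, cv=cfg.cv, seed=stage_seed(cfg.seed, 2), C=cfg.C
        )
        boot_report = bootstrap_evaluate(
            features, labels, selected, iterations=cfg.bootstrap,
            seed=stage_seed(cfg.seed, 3), C=cfg.C,
        )
        model = train_cig_model(
            features, labels, selected, C=cfg.C, seed=stage_seed(cfg.seed, 4)
        )
        model.metadata["cv_metrics"] = cv_report.metrics
        model.metadata["bootstrap_metrics"] = boot_report.metrics
        model_path = outdir / "model.json"
        save_model(model, model_path)
        written.append(model_path)

        stage = "score"
        _stage(stage)
        control_genes = features.index.intersection(labels.genes_with("control"))
        control_scores = model.predict_proba(features.loc[control_genes]).to_numpy()
        scores = score_genes(model, features, control_scores, fdr_threshold=cfg.fdr)
        _write_df(scores.table, "scores.tsv")

        if cfg.edges:
            stage = "scignet"
            _stage(stage)
            grn = compile_grn([read_edge_list(p) for p in cfg.edges], min_votes=cfg.min_votes)
            tfs = read_gene_list(cfg.tf_list) if cfg.tf_list else sorted(grn.nodes)
            net_feats = tf_network_features(
                grn,
                scores.table["cig_score"],
                features[EXPRESSION_FEATURE],
                tfs,
            )
            if cfg.master_labels:
                master_df = pd.read_csv(
                    cfg.master_labels, sep="\t", header=None, names=["tf", "class"]
                )
                masters = set(master_df.loc[master_df["class"] == "master", "tf"])
                tf_model, tf_cv, _sel = train_master_tf_model(
                    net_feats, masters, cv=cfg.cv, seed=stage_seed(cfg.seed, 5), C=cfg.C
                )
                ctrl_tfs = [t for t in net_feats.index if t not in masters]
                ctrl_scores = tf_model.predict_proba(net_feats.loc[ctrl_tfs]).to_numpy()
                ranks = rank_tfs(tf_model, net_feats, ctrl_scores, fdr_threshold=cfg.fdr)
                _write_df(ranks.table, "tf_ranks.tsv")

        stage = "manifest"
        _stage(stage)
        inputs = {
            k: getattr(cfg, k)
            for k in ("fasta", "gtf", "labels", "bulk_counts", "atlas_counts",
                      "motifs", "rbp_bed", "mirna_bed", "bedgraph", "umi_counts")
            if getattr(cfg, k)
        }
        manifest = {
            "config": dataclasses.asdict(cfg),
            "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
            "edges_sha256": [_sha256(p) for p in cfg.edges],
            "versions": {
                "scig": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        return outdir
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
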