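"""Shared fixtures: synthetic input bundles generated once per session."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from scig.io_formats import (
    read_bed,
    read_gene_models,
    read_genome,
    read_labels,
    read_matrix,
    read_motifs,
    read_track,
)
from scig.synthetic_fixtures import FixtureConfig, simulate_bundle

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A compact fixture bundle for unit-level IO and feature tests."""
    cfg = FixtureConfig(
        seed=101, n_genes=120, n_cig=25, n_control=25, n_housekeeping=30,
        n_contigs=2, n_cells=40, n_tfs=40, n_masters=8,
    )
    outdir = tmp_path_factory.mktemp("small_bundle")
    bundle = simulate_bundle(cfg, outdir)
    bundle["cfg"] = cfg
    return bundle


@pytest.fixture(scope="session")
def small_inputs(small_bundle):
    """Loaded in-memory objects of the small bundle."""
    return {
        "models": read_gene_models(small_bundle["gtf"]),
        "genome": read_genome(small_bundle["fasta"]),
        "motifs": read_motifs(small_bundle["motifs"]),
        "rbp": read_bed(small_bundle["rbp_bed"]),
        "mirna": read_bed(small_bundle["mirna_bed"]),
        "track": read_track(small_bundle["bedgraph"]),
        "labels": read_labels(small_bundle["labels"]),
        "atlas": read_matrix(small_bundle["atlas"]),
        "bulk": read_matrix(small_bundle["bulk"]),
        "umi": read_matrix(small_bundle["umi"]),
    }


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default study conditions: 1000 genes, 60 CIG / 60 control /
    100 housekeeping, default planted effect sizes."""
    cfg = FixtureConfig(seed=424242)
    outdir = tmp_path_factory.mktemp("default_bundle")
    bundle = simulate_bundle(cfg, outdir)
    bundle["cfg"] = cfg
    return bundle


@pytest.fixture(scope="session")
def default_features(default_bundle):
    """Joined sequence+expression+specificity features of the default bundle."""
    from scig.pipeline import RunConfig, build_feature_table

    rc = RunConfig(
        fasta=str(default_bundle["fasta"]),
        gtf=str(default_bundle["gtf"]),
        labels=str(default_bundle["labels"]),
        bulk_counts=str(default_bundle["bulk"]),
        atlas_counts=str(default_bundle["atlas"]),
        motifs=str(default_bundle["motifs"]),
        rbp_bed=str(default_bundle["rbp_bed"]),
        mirna_bed=str(default_bundle["mirna_bed"]),
        bedgraph=str(default_bundle["bedgraph"]),
        seed=1,
        outdir="unused",
    )
    features = build_feature_table(rc)
    labels = read_labels(default_bundle["labels"])
    return {"features": features, "labels": labels}


@pytest.fixture(scope="session")
def default_selection(default_features):
    """Screen/prune/search/extend outcome on the default feature table."""
    from scig.feature_selection import run_selection

    screen, pruned, result = run_selection(
        default_features["features"], default_features["labels"],
        seed=7, max_pool=12,
    )
    return {"screen": screen, "pruned": pruned, "result": result}


def labeled_xy(features: pd.DataFrame, labels, feature_names):
    """CIG-vs-control design matrix used by several tests."""
    import numpy as np

    cig = features.index.intersection(labels.genes_with("cig"))
    ctrl = features.index.intersection(labels.genes_with("control"))
    X = features.loc[list(cig) + list(ctrl), feature_names]
    y = np.array([1] * len(cig) + [0] * len(ctrl))
    return X, y
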