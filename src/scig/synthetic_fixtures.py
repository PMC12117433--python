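"""Seeded synthetic input bundles with planted cell-identity signal.

The generator emulates every external input the pipeline consumes — genome
FASTA, GTF gene models, motif set, RBP/miRNA site BEDs, a conservation
bedGraph, a multi-tissue expression atlas, bulk counts of the profiled cell
type, single-cell UMIs, label lists and multi-source GRN edge lists — with
configurable planted effects whose directions mirror what is reported for
real identity genes: denser TF motifs in promoter and gene body, elevated
promoter conservation, longer 3'UTRs, more RBP/miRNA sites, higher and more
tissue-specific expression, and master TFs with more children and
high-scoring parents.

Everything is derived from a single seed; the same config writes
byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Effect fields are multipliers/shifts applied to CIG-labeled genes
    relative to background; 1.0 (multipliers) or 0.0 (shifts) plants no
    signal.
    """

    seed: int = 0
    n_genes: int = 1000
    n_cig: int = 60
    n_control: int = 60
    n_housekeeping: int = 100
    n_contigs: int = 4
    intergenic_gap: int = 400

    # sequence-level planted effects
    motif_density_multiplier: float = 3.0
    base_motif_rate: float = 1.0  # planted instances per kb (promoter + body)
    conservation_shift: float = 1.5
    conservation_sd: float = 0.5
    conservation_bin: int = 50
    utr3_multiplier: float = 3.0
    site_multiplier: float = 2.0
    rbp_rate: float = 0.5  # sites per kb of gene span
    mirna_rate: float = 1.0  # sites per kb of UTR/CDS

    # expression (negative-binomial atlas + Poisson-thinned UMIs)
    n_tissues: int = 12
    dispersion: float = 0.3
    cig_home_mean: float = 300.0
    cig_away_mean: float = 0.5
    control_mean: float = 30.0
    housekeeping_mean: float = 200.0
    specificity_shift: float = 1.0  # 0 = CIGs uniform, 1 = full home/away contrast
    expression_shift: float = 1.0  # 0 = CIG bulk mean equals control mean

    # single cells
    n_cells: int = 150
    n_cell_types: int = 3
    cell_depth: int = 3000

    # GRN
    n_tfs: int = 150
    n_masters: int = 20
    child_multiplier: float = 3.0
    base_children_mean: float = 8.0
    parent_mean_master: float = 4.0
    parent_mean_control: float = 2.0
    n_sources: int = 3
    decoy_fraction: float = 0.2

    def __post_init__(self) -> None:
        n_labeled = self.n_cig + self.n_control + self.n_housekeeping
        if n_labeled > self.n_genes:
            raise ValueError("label counts exceed n_genes")
        if self.n_masters > self.n_tfs:
            raise ValueError("n_masters exceeds n_tfs")


# ---------------------------------------------------------------------------
# gene structures


@dataclass
class _GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    utr5_len: int
    cds_len: int
    utr3_len: int
    label: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def spliced_to_genomic(self, a: int, b: int) -> list[tuple[int, int]]:
        order = self.exons if self.strand == "+" else self.exons[::-1]
        out = []
        pos = 0
        for s, e in order:
            length = e - s
            lo, hi = max(a, pos), min(b, pos + length)
            if lo < hi:
                if self.strand == "+":
                    out.append((s + (lo - pos), s + (hi - pos)))
                else:
                    out.append((e - (hi - pos), e - (lo - pos)))
            pos += length
        return sorted(out)

    @property
    def utr5_ivs(self) -> list[tuple[int, int]]:
        return self.spliced_to_genomic(0, self.utr5_len)

    @property
    def cds_ivs(self) -> list[tuple[int, int]]:
        return self.spliced_to_genomic(self.utr5_len, self.utr5_len + self.cds_len)

    @property
    def utr3_ivs(self) -> list[tuple[int, int]]:
        s = self.utr5_len + self.cds_len
        return self.spliced_to_genomic(s, s + self.utr3_len)


def _assign_labels(cfg: FixtureConfig, rng: np.random.Generator) -> list[str]:
    labels = (
        ["cig"] * cfg.n_cig
        + ["control"] * cfg.n_control
        + ["housekeeping"] * cfg.n_housekeeping
        + ["unlabeled"] * (cfg.n_genes - cfg.n_cig - cfg.n_control - cfg.n_housekeeping)
    )
    rng.shuffle(labels)
    return labels


def _make_structure(
    cfg: FixtureConfig, rng: np.random.Generator, gene_id: str, chrom: str,
    cursor: int, label: str,
) -> _GeneTruth:
    hk = label == "housekeeping"
    n_exons = int(min(1 + rng.poisson(1.5 if hk else 2.0), 6))
    exon_lens = rng.integers(120, 400, size=n_exons)
    intron_lens = (
        rng.integers(50, 150, size=n_exons - 1)
        if hk
        else rng.integers(150, 600, size=n_exons - 1)
    )
    utr5 = int(rng.integers(30, 120))
    utr3 = int(rng.integers(80, 250))
    if label == "cig":
        utr3 = int(round(utr3 * cfg.utr3_multiplier))
    spliced = int(exon_lens.sum())
    min_cds = 90
    if spliced < utr5 + utr3 + min_cds:
        exon_lens[-1] += utr5 + utr3 + min_cds - spliced
        spliced = int(exon_lens.sum())
    cds = spliced - utr5 - utr3
    rem = cds % 3
    cds -= rem
    utr3 += rem
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = cursor
    for i, length in enumerate(exon_lens):
        exons.append((pos, pos + int(length)))
        pos += int(length)
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    return _GeneTruth(
        gene_id=gene_id, chrom=chrom, strand=strand, start=cursor, end=pos,
        exons=exons, utr5_len=utr5, cds_len=cds, utr3_len=utr3, label=label,
    )


# ---------------------------------------------------------------------------
# motifs


def _make_motifs(rng: np.random.Generator) -> list[dict]:
    """Three sharp PWMs plus two consensus motifs, with their best-match
    strings used for planting instances."""
    motifs = []
    for i in range(3):
        L = int(rng.integers(7, 10))
        best = rng.integers(0, 4, size=L)
        pwm = np.full((4, L), 0.05)
        pwm[best, np.arange(L)] = 0.85
        consensus = "".join("ACGT"[b] for b in best)
        motifs.append({"name": f"pwm_{i}", "pwm": pwm, "plant": consensus})
    for i in range(2):
        L = int(rng.integers(6, 9))
        consensus = "".join("ACGT"[b] for b in rng.integers(0, 4, size=L))
        motifs.append({"name": f"consensus_{i}", "consensus": consensus, "plant": consensus})
    return motifs


def _write_motif_file(motifs: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m['name']}\n")
            if "pwm" in m:
                for base, row in zip("ACGT", m["pwm"]):
                    fh.write(f"{base}: " + " ".join(f"{v:.4f}" for v in row) + "\n")
            else:
                fh.write(m["consensus"] + "\n")


# ---------------------------------------------------------------------------
# main generators


def simulate_genome_annotation(cfg: FixtureConfig, outdir: str | Path) -> dict:
    """Write FASTA, GTF, motif file, RBP/miRNA BEDs, bedGraph and labels.

    Returns a dict of file paths plus the internal gene truth records.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    labels = _assign_labels(cfg, rng)
    genes: list[_GeneTruth] = []
    contig_cursor = {f"chr{i + 1}": 6000 for i in range(cfg.n_contigs)}
    for i in range(cfg.n_genes):
        chrom = f"chr{i % cfg.n_contigs + 1}"
        g = _make_structure(
            cfg, rng, f"g{i + 1:05d}", chrom, contig_cursor[chrom], labels[i]
        )
        genes.append(g)
        contig_cursor[chrom] = g.end + int(
            rng.integers(cfg.intergenic_gap, 3 * cfg.intergenic_gap)
        )
    contig_len = {c: cursor + 6000 for c, cursor in contig_cursor.items()}

    seqs = {
        c: rng.integers(0, 4, size=n).astype(np.uint8) for c, n in contig_len.items()
    }

    motifs = _make_motifs(rng)
    for g in genes:
        mult = cfg.motif_density_multiplier if g.label == "cig" else 1.0
        regions = [
            (max(0, g.tss - 1000), min(contig_len[g.chrom], g.tss + 1000)),
            (g.start, g.end),
        ]
        for lo, hi in regions:
            n_plant = rng.poisson(cfg.base_motif_rate * mult * (hi - lo) / 1000.0)
            for _ in range(n_plant):
                m = motifs[int(rng.integers(len(motifs)))]
                plant = m["plant"]
                if hi - lo <= len(plant):
                    continue
                p = int(rng.integers(lo, hi - len(plant)))
                codes = np.frombuffer(plant.encode(), dtype=np.uint8)
                seqs[g.chrom][p : p + len(plant)] = np.searchsorted(_BASES, codes)

    fasta_path = outdir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            s = bytes(_BASES[seqs[chrom]]).decode()
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")

    gtf_path = outdir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_biotype "protein_coding";'
            )

            def row(feature: str, s: int, e: int) -> str:
                return (
                    f"{g.chrom}\tsim\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )

            fh.write(row("gene", g.start, g.end))
            fh.write(row("transcript", g.start, g.end))
            for s, e in g.exons:
                fh.write(row("exon", s, e))
            for s, e in g.cds_ivs:
                fh.write(row("CDS", s, e))
            for s, e in g.utr5_ivs:
                fh.write(row("five_prime_utr", s, e))
            for s, e in g.utr3_ivs:
                fh.write(row("three_prime_utr", s, e))

    motif_path = outdir / "motifs.txt"
    _write_motif_file(motifs, motif_path)

    rbp_rows, mirna_rows = [], []
    for g in genes:
        mult = cfg.site_multiplier if g.label == "cig" else 1.0
        span_kb = (g.end - g.start) / 1000.0
        for _ in range(rng.poisson(cfg.rbp_rate * mult * span_kb)):
            p = int(rng.integers(g.start, max(g.start + 1, g.end - 7)))
            rbp_rows.append((g.chrom, p, p + 7, f"rbp_site_{len(rbp_rows)}"))
        for ivs, rate in (
            (g.utr3_ivs, cfg.mirna_rate * mult),
            (g.utr5_ivs, cfg.mirna_rate * 0.5),
            (g.cds_ivs, cfg.mirna_rate * 0.5),
        ):
            for s, e in ivs:
                for _ in range(rng.poisson(rate * (e - s) / 1000.0)):
                    p = int(rng.integers(s, max(s + 1, e - 7)))
                    mirna_rows.append((g.chrom, p, p + 7, f"mirna_site_{len(mirna_rows)}"))
    rbp_path = outdir / "rbp_sites.bed"
    mirna_path = outdir / "mirna_sites.bed"
    for rows, path in ((rbp_rows, rbp_path), (mirna_rows, mirna_path)):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df = df.sort_values(["chrom", "start", "end", "name"])
        df.to_csv(path, sep="\t", header=False, index=False)

    cons_path = outdir / "conservation.bedgraph"
    cig_promoters: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.label == "cig":
            cig_promoters.setdefault(g.chrom, []).append((g.tss - 1000, g.tss + 1000))
    with open(cons_path, "w") as fh:
        for chrom in sorted(contig_len):
            n = contig_len[chrom]
            edges = np.arange(0, n, cfg.conservation_bin)
            vals = rng.normal(0.0, cfg.conservation_sd, size=edges.size)
            proms = cig_promoters.get(chrom, [])
            for i, s in enumerate(edges):
                e = min(int(s) + cfg.conservation_bin, n)
                v = vals[i]
                if any(s < phi and e > plo for plo, phi in proms):
                    v += cfg.conservation_shift
                fh.write(f"{chrom}\t{int(s)}\t{e}\t{v:.3f}\n")

    labels_path = outdir / "truth_labels.tsv"
    with open(labels_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.label}\n")

    return {
        "fasta": fasta_path,
        "gtf": gtf_path,
        "motifs": motif_path,
        "rbp_bed": rbp_path,
        "mirna_bed": mirna_path,
        "bedgraph": cons_path,
        "labels": labels_path,
        "genes": genes,
    }


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_expression(cfg: FixtureConfig, labels: pd.Series, outdir: str | Path) -> dict:
    """Write the reference atlas, bulk counts and single-cell UMI matrix.

    Tissue 0 is the profiled cell type: CIGs are high there and low
    elsewhere (contrast scaled by ``specificity_shift``), housekeeping
    genes are uniformly high, control genes uniformly moderate. Bulk
    counts come from the tissue-0 profile; UMIs are Poisson-thinned from
    the first ``n_cell_types`` tissue profiles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    genes = list(labels.index)
    n = len(genes)
    tissues = [f"tissue_{t}" for t in range(cfg.n_tissues)]

    away = cfg.cig_home_mean * (cfg.cig_away_mean / cfg.cig_home_mean) ** cfg.specificity_shift
    mean = np.zeros((n, cfg.n_tissues))
    for i, g in enumerate(genes):
        lab = labels.loc[g]
        if lab == "cig":
            mean[i, :] = away
            mean[i, 0] = cfg.cig_home_mean
        elif lab == "housekeeping":
            mean[i, :] = cfg.housekeeping_mean * rng.uniform(0.8, 1.2)
        elif lab == "control":
            mean[i, :] = cfg.control_mean * rng.lognormal(0.0, 0.3, size=cfg.n_tissues)
        else:
            if rng.random() < 0.3:
                home = int(rng.integers(cfg.n_tissues))
                mean[i, :] = 5.0
                mean[i, home] = rng.uniform(50, 300)
            else:
                mean[i, :] = rng.uniform(5, 80)

    atlas_counts = _nb_sample(rng, mean, cfg.dispersion)
    atlas = pd.DataFrame(atlas_counts, index=genes, columns=tissues)
    atlas_path = outdir / "atlas_counts.tsv"
    atlas.to_csv(atlas_path, sep="\t")

    bulk_mean = mean[:, 0].copy()
    for i, g in enumerate(genes):
        if labels.loc[g] == "cig":
            bulk_mean[i] = cfg.control_mean * (
                cfg.cig_home_mean / cfg.control_mean
            ) ** cfg.expression_shift
    bulk = pd.DataFrame(
        {"bulk_sample": _nb_sample(rng, bulk_mean, cfg.dispersion)}, index=genes
    )
    bulk_path = outdir / "bulk_counts.tsv"
    bulk.to_csv(bulk_path, sep="\t")

    n_types = min(cfg.n_cell_types, cfg.n_tissues)
    cell_types = rng.integers(0, n_types, size=cfg.n_cells)
    umi = np.zeros((n, cfg.n_cells), dtype=np.int64)
    for c in range(cfg.n_cells):
        profile = mean[:, cell_types[c]]
        p = profile / profile.sum()
        umi[:, c] = rng.poisson(cfg.cell_depth * p)
    cells = [f"cell_{c + 1:04d}" for c in range(cfg.n_cells)]
    umi_df = pd.DataFrame(umi, index=genes, columns=cells)
    umi_path = outdir / "umi_counts.tsv"
    umi_df.to_csv(umi_path, sep="\t")
    cell_type_path = outdir / "cell_types.tsv"
    pd.DataFrame({"cell": cells, "cell_type": [f"type_{t}" for t in cell_types]}).to_csv(
        cell_type_path, sep="\t", index=False
    )
    return {
        "atlas": atlas_path,
        "bulk": bulk_path,
        "umi": umi_path,
        "cell_types": cell_type_path,
    }


def simulate_grn(
    cfg: FixtureConfig,
    labels: pd.Series,
    scores: pd.Series | None,
    outdir: str | Path,
) -> dict:
    """Write per-source GRN edge lists plus the truth edge/master tables.

    Master TFs draw child counts from a mean multiplied by
    ``child_multiplier`` and preferentially attach to (and are regulated
    by) high-CIG-score genes. Every true edge is present in at least two
    of the source files; decoy edges appear in exactly one.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))
    genes = list(labels.index)
    if scores is None:
        base = np.where(labels.to_numpy() == "cig", 0.9, 0.2)
        scores = pd.Series(
            np.clip(base + rng.normal(0, 0.05, size=len(genes)), 0.0, 1.0), index=genes
        )

    cig_genes = [g for g in genes if labels.loc[g] == "cig"]
    other_genes = [g for g in genes if labels.loc[g] != "cig"]
    n_masters = min(cfg.n_masters, len(cig_genes))
    masters = sorted(rng.choice(cig_genes, size=n_masters, replace=False))
    controls = sorted(
        rng.choice(other_genes, size=cfg.n_tfs - n_masters, replace=False)
    )
    tfs = list(masters) + list(controls)
    master_set = set(masters)

    weights = scores.loc[genes].to_numpy() ** 3
    weights = weights / weights.sum()
    true_edges: set[tuple[str, str]] = set()
    for tf in tfs:
        is_master = tf in master_set
        lam = cfg.base_children_mean * (cfg.child_multiplier if is_master else 1.0)
        n_children = max(1, int(rng.poisson(lam)))
        if is_master:
            children = rng.choice(genes, size=n_children, replace=False, p=weights)
        else:
            children = rng.choice(genes, size=n_children, replace=False)
        for child in children:
            if child != tf:
                true_edges.add((tf, child))
        lam_p = cfg.parent_mean_master if is_master else cfg.parent_mean_control
        n_parents = int(rng.poisson(lam_p))
        parent_pool = masters if is_master else tfs
        for parent in rng.choice(parent_pool, size=min(n_parents, len(parent_pool)),
                                 replace=False):
            if parent != tf:
                true_edges.add((parent, tf))

    true_list = sorted(true_edges)
    sources: list[list[tuple[str, str]]] = [[] for _ in range(cfg.n_sources)]
    for edge in true_list:
        n_in = 2 if rng.random() < 0.6 else min(3, cfg.n_sources)
        for s in rng.choice(cfg.n_sources, size=n_in, replace=False):
            sources[s].append(edge)

    n_decoys = int(cfg.decoy_fraction * len(true_list))
    decoys: set[tuple[str, str]] = set()
    while len(decoys) < n_decoys:
        reg = tfs[int(rng.integers(len(tfs)))]
        tgt = genes[int(rng.integers(len(genes)))]
        if reg != tgt and (reg, tgt) not in true_edges:
            decoys.add((reg, tgt))
    for i, edge in enumerate(sorted(decoys)):
        sources[i % cfg.n_sources].append(edge)

    paths = {}
    for s, edges in enumerate(sources):
        path = outdir / f"edges_source{s + 1}.tsv"
        df = pd.DataFrame(sorted(edges), columns=["regulator", "target"])
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[f"edges_{s + 1}"] = path

    truth_edges_path = outdir / "truth_edges.tsv"
    pd.DataFrame(true_list, columns=["regulator", "target"]).to_csv(
        truth_edges_path, sep="\t", index=False
    )
    masters_path = outdir / "truth_masters.tsv"
    with open(masters_path, "w") as fh:
        for tf in tfs:
            fh.write(f"{tf}\t{'master' if tf in master_set else 'control'}\n")
    paths.update(
        {
            "truth_edges": truth_edges_path,
            "truth_masters": masters_path,
            "edge_files": [paths[f"edges_{s + 1}"] for s in range(cfg.n_sources)],
            "masters": list(masters),
            "tfs": tfs,
            "scores": scores,
        }
    )
    return paths


def simulate_bundle(cfg: FixtureConfig, outdir: str | Path) -> dict:
    """Generate the complete input bundle (annotation, expression, GRN)."""
    outdir = Path(outdir)
    anno = simulate_genome_annotation(cfg, outdir)
    labels = pd.Series(
        {g.gene_id: g.label for g in anno["genes"]},
        index=[g.gene_id for g in anno["genes"]],
    )
    expr = simulate_expression(cfg, labels, outdir)
    grn = simulate_grn(cfg, labels, None, outdir)
    bundle = {**anno, **expr, **grn, "config": dataclasses.asdict(cfg)}
    return bundle
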