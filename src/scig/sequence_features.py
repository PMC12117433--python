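"""Per-gene genetic-sequence features.

Five ingredient groups are computed from the genome and gene models alone
(no epigenomic data): TF-motif densities over promoter windows and gene
regions, RBP/miRNA binding-site densities, conservation aggregates,
gene-architecture measurements, and composition/codon-usage statistics,
plus the distance from each TSS to its nearest neighbouring TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ConservationTrack,
    GeneModel,
    GenomeStore,
    IntervalTable,
    Motif,
    MotifSet,
    revcomp,
)

log = logging.getLogger(__name__)

# Standard genetic code; stop codons form their own group ("stop").
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "stop", "TAG": "stop",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "stop", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
AA_GROUPS: dict[str, list[str]] = {}
for _codon, _aa in GENETIC_CODE.items():
    AA_GROUPS.setdefault(_aa, []).append(_codon)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

MOTIF_REGIONS = ("gene_body", "utr5", "exons", "introns", "utr3")
RBP_REGIONS = ("utr5", "exons", "introns", "utr3")
MIRNA_REGIONS = ("utr5", "cds", "utr3")
CONS_REGIONS = ("gene_body", "utr5", "exons", "introns", "utr3", "cds")


@dataclass
class SequenceFeatureConfig:
    """Knobs of the sequence-feature inventory.

    ``promoter_windows`` are half-widths w of symmetric promoter windows
    [tss-w, tss+w); ``score_fraction`` is the PWM hit threshold as a fraction
    of each motif's maximal achievable log-odds score.
    """

    promoter_windows: tuple[int, ...] = (500, 1000, 2000, 5000)
    score_fraction: float = 0.8
    per_motif: bool = False
    min_conservation_coverage: float = 0.10


def resolve_region(name: str, model: GeneModel, contig_len: int,
                   config: SequenceFeatureConfig | None = None) -> list[tuple[int, int]]:
    """Resolve a region name to genomic intervals for one gene.

    Returns an empty list when the gene lacks the substructure (e.g. no
    annotated 3'UTR), in which case dependent features are missing.
    """
    cfg = config or SequenceFeatureConfig()
    if name.startswith("promoter_"):
        w = int(name.split("_", 1)[1])
        if w not in cfg.promoter_windows:
            raise ValueError(f"window {w} not in configured set {cfg.promoter_windows}")
        lo = max(0, model.tss - w)
        hi = min(contig_len, model.tss + w)
        return [(lo, hi)] if lo < hi else []
    if name == "gene_body":
        return [model.span]
    if name in ("utr5", "utr3", "cds", "exons", "introns"):
        attr = {"exons": "exons", "introns": "introns"}.get(name, name)
        return list(getattr(model, attr))
    raise ValueError(f"unknown region {name!r}")


def region_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


# ---------------------------------------------------------------------------
# architecture


def architecture_features(g: GeneModel) -> dict[str, float]:
    """Lengths and counts of genomic elements plus the intron/exon ratio."""
    n_exons = len(g.exons)
    n_introns = len(g.introns)
    return {
        "gene_length": float(g.end - g.start),
        "exon_length": float(region_length(g.exons)),
        "intron_length": float(region_length(g.introns)),
        "cds_length": float(region_length(g.cds)),
        "utr5_length": float(region_length(g.utr5)),
        "utr3_length": float(region_length(g.utr3)),
        "n_exons": float(n_exons),
        "n_introns": float(n_introns),
        "intron_exon_ratio": (n_introns / n_exons) if n_exons else np.nan,
    }


# ---------------------------------------------------------------------------
# composition


def _kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    from itertools import product

    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    counts = dict.fromkeys(kmers, 0)
    total = 0
    for i in range(len(seq) - k + 1):
        mer = seq[i : i + k]
        if mer in counts:
            counts[mer] += 1
            total += 1
    if total == 0:
        return {m: np.nan for m in kmers}
    return {m: c / total for m, c in counts.items()}


def nucleotide_composition(seq: str) -> dict[str, float]:
    """Overlapping mono/di/tri-nucleotide frequencies plus AT content.

    k-mers containing N are excluded from numerator and denominator; an
    empty sequence yields all-missing features.
    """
    out: dict[str, float] = {}
    for k in (1, 2, 3):
        for mer, f in _kmer_frequencies(seq, k).items():
            out[f"nt_{mer}"] = f
    a, t = out.get("nt_A", np.nan), out.get("nt_T", np.nan)
    out["at_content"] = a + t
    return out


def codon_bias_features(cds_seq: str) -> dict[str, float]:
    """Amino-acid-grouped codon-usage statistics on a spliced CDS.

    Codon frequencies are relative to the total codon count; per group we
    report the summed proportion of its member codons and the mean, median
    and coefficient of variation (population sd / mean) over those
    member-codon frequencies.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_seq)} not divisible by 3")
    codons = [cds_seq[i : i + 3] for i in range(0, len(cds_seq), 3)]
    codons = [c for c in codons if c in GENETIC_CODE]
    out: dict[str, float] = {}
    n = len(codons)
    freqs = {c: 0.0 for c in GENETIC_CODE}
    if n:
        for c in codons:
            freqs[c] += 1.0 / n
    for aa, members in sorted(AA_GROUPS.items()):
        vals = np.array([freqs[c] for c in members]) if n else np.full(len(members), np.nan)
        mean = float(np.mean(vals))
        out[f"codon_{aa}_total_proportion"] = float(np.sum(vals))
        out[f"codon_{aa}_mean"] = mean
        out[f"codon_{aa}_median"] = float(np.median(vals))
        out[f"codon_{aa}_cv"] = (
            float(np.std(vals) / mean) if n and mean > 0 else np.nan
        )
    return out


def spliced_cds_sequence(g: GeneModel, genome: GenomeStore) -> str:
    parts = [genome.slice(g.chrom, s, e) for s, e in g.cds]
    seq = "".join(parts)
    return revcomp(seq) if g.strand == "-" else seq


def gene_body_sequence(g: GeneModel, genome: GenomeStore) -> str:
    seq = genome.slice(g.chrom, g.start, g.end)
    return revcomp(seq) if g.strand == "-" else seq


# ---------------------------------------------------------------------------
# motif scanning


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return codes


def _logodds(pwm: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    return np.log((pwm + pseudocount) / 0.25)


def _pwm_hits_one_strand(codes: np.ndarray, mat: np.ndarray, threshold: float) -> int:
    L = mat.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return 0
    score = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    for j in range(L):
        col = codes[j : j + n]
        ok &= col >= 0
        score += mat[np.clip(col, 0, 3), j]
    return int(np.count_nonzero(ok & (score >= threshold)))


def _consensus_hits_one_strand(seq: str, consensus: str) -> int:
    count = start = 0
    while True:
        i = seq.find(consensus, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def count_motif_hits(seq: str, motif: Motif, score_fraction: float) -> int:
    """Hits of one motif on both strands of ``seq``.

    A PWM hit is a window whose log-odds score (uniform background,
    pseudocount 1e-6) reaches ``score_fraction`` of the motif's maximal
    achievable score; windows containing N never match. Consensus motifs
    are matched exactly.
    """
    if motif.consensus is not None:
        return _consensus_hits_one_strand(seq, motif.consensus) + _consensus_hits_one_strand(
            seq, revcomp(motif.consensus)
        )
    mat = _logodds(motif.pwm)
    threshold = score_fraction * float(mat.max(axis=0).sum())
    codes = _encode(seq)
    # reverse strand == scanning with the reverse-complemented matrix
    rc_mat = mat[::-1, ::-1]
    return _pwm_hits_one_strand(codes, mat, threshold) + _pwm_hits_one_strand(
        codes, rc_mat, threshold
    )


def motif_scan_counts(
    g: GeneModel,
    genome: GenomeStore,
    motifs: MotifSet,
    regions: list[str],
    score_fraction: float = 0.8,
    config: SequenceFeatureConfig | None = None,
    per_motif: bool = False,
) -> dict[str, float]:
    """Motif-hit density (hits per kb, both strands, all motifs) per region.

    Windows never span the gap between two intervals of a region (e.g. two
    exons). Zero-length regions yield a missing feature.
    """
    cfg = config or SequenceFeatureConfig(score_fraction=score_fraction)
    out: dict[str, float] = {}
    contig_len = genome.contig_length(g.chrom)
    for region in regions:
        ivs = resolve_region(region, g, contig_len, cfg)
        length = region_length(ivs)
        if length == 0:
            if per_motif:
                for m in motifs:
                    out[f"tf_motif_density_{m.name}_{region}"] = np.nan
            else:
                out[f"tf_motif_density_{region}"] = np.nan
            continue
        seqs = [genome.slice(g.chrom, s, e) for s, e in ivs]
        total = 0
        for m in motifs:
            hits = sum(count_motif_hits(s, m, score_fraction) for s in seqs)
            if per_motif:
                out[f"tf_motif_density_{m.name}_{region}"] = hits / length * 1000.0
            total += hits
        if not per_motif:
            out[f"tf_motif_density_{region}"] = total / length * 1000.0
    return out


# ---------------------------------------------------------------------------
# interval-site densities


def _count_overlapping(ivs: list[tuple[int, int]], sites: pd.DataFrame) -> int:
    """Number of site records overlapping any region interval by >= 1 bp;
    a site overlapping two intervals of the region still counts once."""
    if not ivs or sites.empty:
        return 0
    s = sites["start"].to_numpy()
    e = sites["end"].to_numpy()
    hit = np.zeros(len(sites), dtype=bool)
    for a, b in ivs:
        hit |= (s < b) & (e > a)
    return int(hit.sum())


def site_overlap_counts(
    g: GeneModel,
    sites: IntervalTable,
    regions: list[str],
    prefix: str = "site",
    config: SequenceFeatureConfig | None = None,
    contig_len: int | None = None,
) -> dict[str, float]:
    """Binding-site density (overlapping records per kb) per region."""
    cfg = config or SequenceFeatureConfig()
    chrom_sites = sites.on_chrom(g.chrom)
    out: dict[str, float] = {}
    clen = contig_len if contig_len is not None else g.end + max(cfg.promoter_windows)
    for region in regions:
        ivs = resolve_region(region, g, clen, cfg)
        length = region_length(ivs)
        if length == 0:
            out[f"{prefix}_density_{region}"] = np.nan
            continue
        out[f"{prefix}_density_{region}"] = (
            _count_overlapping(ivs, chrom_sites) / length * 1000.0
        )
    return out


# ---------------------------------------------------------------------------
# conservation


def conservation_aggregates(
    g: GeneModel,
    track: ConservationTrack,
    regions: list[str],
    config: SequenceFeatureConfig | None = None,
    contig_len: int | None = None,
) -> dict[str, float]:
    """Mean and median conservation over covered bases of each region.

    A region whose track coverage is below the configured floor (default
    10% of bases) yields missing aggregates rather than a biased estimate.
    """
    cfg = config or SequenceFeatureConfig()
    out: dict[str, float] = {}
    clen = contig_len if contig_len is not None else g.end + max(cfg.promoter_windows)
    for region in regions:
        ivs = resolve_region(region, g, clen, cfg)
        length = region_length(ivs)
        mean = median = np.nan
        if length > 0:
            vals = np.concatenate([track.values(g.chrom, s, e) for s, e in ivs])
            covered = vals[~np.isnan(vals)]
            if covered.size >= cfg.min_conservation_coverage * length and covered.size:
                mean = float(np.mean(covered))
                median = float(np.median(covered))
        out[f"cons_mean_{region}"] = mean
        out[f"cons_median_{region}"] = median
    return out


# ---------------------------------------------------------------------------
# TSS neighbourhood


def tss_distance(g: GeneModel, all_models: list[GeneModel]) -> float:
    """Distance (bp) from this gene's TSS to the closest TSS of another gene
    on the same chromosome; missing when the gene is alone on its contig."""
    others = [
        m.tss for m in all_models if m.chrom == g.chrom and m.gene_id != g.gene_id
    ]
    if not others:
        return np.nan
    return float(min(abs(g.tss - t) for t in others))


def _all_tss_distances(models: list[GeneModel]) -> dict[str, float]:
    out: dict[str, float] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for ms in by_chrom.values():
        tss = np.array([m.tss for m in ms])
        for i, m in enumerate(ms):
            if len(ms) < 2:
                out[m.gene_id] = np.nan
                continue
            d = np.abs(np.delete(tss, i) - m.tss)
            out[m.gene_id] = float(d.min())
    return out


# ---------------------------------------------------------------------------
# assembly


@dataclass
class FeatureTable:
    """Genes x named numeric features with per-feature metadata."""

    df: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.columns.duplicated().any():
            dup = self.df.columns[self.df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup}")


def build_sequence_feature_table(
    models: list[GeneModel],
    genome: GenomeStore,
    motifs: MotifSet | None = None,
    rbp_sites: IntervalTable | None = None,
    mirna_sites: IntervalTable | None = None,
    track: ConservationTrack | None = None,
    config: SequenceFeatureConfig | None = None,
) -> FeatureTable:
    """Assemble the full per-gene sequence-feature table.

    Column order is deterministic and independent of input record order.
    Genes on contigs absent from the genome are dropped with a warning.
    """
    cfg = config or SequenceFeatureConfig()
    contigs = set(genome.contigs())
    usable = []
    for m in sorted(models, key=lambda m: m.gene_id):
        if m.chrom not in contigs:
            log.warning("gene %s dropped: contig %s not in genome", m.gene_id, m.chrom)
            continue
        usable.append(m)

    promoter_regions = [f"promoter_{w}" for w in cfg.promoter_windows]
    motif_regions = promoter_regions + list(MOTIF_REGIONS)
    cons_regions = promoter_regions + list(CONS_REGIONS)
    tssd = _all_tss_distances(usable)

    rows = []
    for g in usable:
        rec: dict[str, float] = {}
        rec.update(architecture_features(g))
        rec.update(nucleotide_composition(gene_body_sequence(g, genome)))
        cds_seq = spliced_cds_sequence(g, genome)
        if cds_seq and len(cds_seq) % 3 == 0:
            rec.update(codon_bias_features(cds_seq))
            comp = nucleotide_composition(cds_seq)
            rec["cds_at_content"] = comp["at_content"]
        else:
            rec.update({k: np.nan for k in _codon_feature_names()})
            rec["cds_at_content"] = np.nan
        clen = genome.contig_length(g.chrom)
        if motifs is not None and len(motifs):
            rec.update(
                motif_scan_counts(
                    g, genome, motifs, motif_regions, cfg.score_fraction, cfg,
                    per_motif=cfg.per_motif,
                )
            )
        if rbp_sites is not None:
            rec.update(
                site_overlap_counts(g, rbp_sites, list(RBP_REGIONS), "rbp_site",
                                    cfg, contig_len=clen)
            )
        if mirna_sites is not None:
            rec.update(
                site_overlap_counts(g, mirna_sites, list(MIRNA_REGIONS), "mirna_site",
                                    cfg, contig_len=clen)
            )
        if track is not None:
            rec.update(conservation_aggregates(g, track, cons_regions, cfg,
                                               contig_len=clen))
        rec["tss_distance"] = tssd[g.gene_id]
        rows.append(pd.Series(rec, name=g.gene_id))

    df = pd.DataFrame(rows)
    df = df[sorted(df.columns)]
    meta = {c: {"category": _feature_category(c)} for c in df.columns}
    return FeatureTable(df=df, metadata=meta)


def _codon_feature_names() -> list[str]:
    names = []
    for aa in sorted(AA_GROUPS):
        names += [
            f"codon_{aa}_total_proportion",
            f"codon_{aa}_mean",
            f"codon_{aa}_median",
            f"codon_{aa}_cv",
        ]
    return names


def _feature_category(name: str) -> str:
    if name.startswith("tf_motif_"):
        return "tf_motif"
    if name.startswith(("rbp_site_", "mirna_site_")):
        return "binding_site"
    if name.startswith(("cons_mean_", "cons_median_")):
        return "conservation"
    if name.startswith("nt_") or name.endswith("at_content"):
        return "composition"
    if name.startswith("codon_"):
        return "codon_bias"
    if name == "tss_distance":
        return "tss_distance"
    return "architecture"
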