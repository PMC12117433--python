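"""Readers and writers for the external formats the pipeline touches.

Every coordinate is converted at the boundary to the single internal
convention: 0-based, half-open intervals. GTF input (1-based, closed) and
BED/bedGraph input (already 0-based, half-open) are normalized here so that
downstream feature code never sees a mixed convention.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
import pyfaidx
from scipy.io import mmread

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement of a DNA sequence (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _merge_sorted(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class GeneModel:
    """One gene's coordinate anatomy on which sequence features are computed.

    All intervals are 0-based half-open on ``chrom``. ``exons`` (and the
    derived ``introns``) describe the selected transcript; ``cds``/``utr5``/
    ``utr3`` may be empty for non-coding or partially annotated genes.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = _merge_sorted(self.exons)
        self.cds = _merge_sorted(self.cds)
        self.utr5 = _merge_sorted(self.utr5)
        self.utr3 = _merge_sorted(self.utr3)
        for name, ivs in (("exon", self.exons), ("cds", self.cds)):
            for s, e in ivs:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(
                        f"{self.gene_id}: {name} [{s},{e}) outside span "
                        f"[{self.start},{self.end})"
                    )

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def tss(self) -> int:
        """Transcription start site (0-based base position)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]


@dataclass
class IntervalTable:
    """BED-like interval records (0-based half-open), e.g. RBP/miRNA sites."""

    df: pd.DataFrame  # columns: chrom, start, end[, name, strand]

    def __post_init__(self) -> None:
        if (self.df["start"] >= self.df["end"]).any():
            bad = self.df[self.df["start"] >= self.df["end"]].iloc[0]
            raise ValueError(f"empty/negative interval: {tuple(bad)}")
        sort_cols = [c for c in ("chrom", "start", "end", "name") if c in self.df]
        self.df = self.df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


class ConservationTrack:
    """Sparse per-base score track (phyloP-like).

    Uncovered positions are "no data" (returned as NaN), never an implicit
    zero. Built from non-overlapping bedGraph records.
    """

    def __init__(self, records: pd.DataFrame):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in records.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts < 0).any():
                raise ValueError(f"{chrom}: negative position in track")
            if (ends[:-1] > starts[1:]).any():
                i = int(np.nonzero(ends[:-1] > starts[1:])[0][0])
                raise ValueError(
                    f"{chrom}: overlapping bedGraph records at "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            self._chroms[chrom] = (starts, ends, sub["value"].to_numpy(dtype=float))

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); NaN where the track has no data."""
        out = np.full(end - start, np.nan)
        if chrom not in self._chroms:
            return out
        starts, ends, vals = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            s = max(starts[i], start)
            e = min(ends[i], end)
            if s < e:
                out[s - start : e - start] = vals[i]
        return out


@dataclass
class Motif:
    """A TF-binding motif: either a PWM (4 x L, rows A,C,G,T) or a consensus."""

    name: str
    pwm: np.ndarray | None = None
    consensus: str | None = None

    def __post_init__(self) -> None:
        if (self.pwm is None) == (self.consensus is None):
            raise ValueError(f"{self.name}: exactly one of pwm/consensus required")
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError(f"{self.name}: PWM must have 4 rows (A,C,G,T)")
            colsums = self.pwm.sum(axis=0)
            if not np.allclose(colsums, 1.0, atol=1e-6):
                raise ValueError(f"{self.name}: PWM columns must sum to 1")
        if self.consensus is not None:
            if not re.fullmatch("[ACGT]+", self.consensus):
                raise ValueError(f"{self.name}: consensus must be over ACGT")

    def __len__(self) -> int:
        return self.pwm.shape[1] if self.pwm is not None else len(self.consensus)


@dataclass
class MotifSet:
    motifs: list[Motif]
    name: str = "motifs"

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


class ExpressionMatrix:
    """Genes x samples/cells matrix with an explicit value-kind flag.

    ``kind`` is one of ``counts``, ``tpm``, ``log2tpm``, ``percell_lognorm``
    and determines which downstream operations will accept the matrix.
    """

    KINDS = ("counts", "tpm", "log2tpm", "percell_lognorm")

    def __init__(self, values: pd.DataFrame, kind: str = "counts"):
        if kind not in self.KINDS:
            raise ValueError(f"unknown matrix kind {kind!r}")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        arr = values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("matrix contains NaN entries")
        if (arr < 0).any():
            raise ValueError("matrix contains negative entries")
        self.values = values.astype(float)
        self.kind = kind

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LabelSet:
    """Gene -> label in {cig, control, housekeeping, unlabeled}."""

    labels: pd.Series  # index: gene_id, values: label strings

    VALID = ("cig", "control", "housekeeping", "unlabeled")

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - set(self.VALID)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.labels.index.duplicated().any():
            raise ValueError("a gene may carry only one label")

    def genes_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


class GenomeStore:
    """Random-access genome sequence backed by a FASTA index."""

    def __init__(self, fasta_path: str):
        self._fa = pyfaidx.Fasta(str(fasta_path), sequence_always_upper=True)

    def contig_length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Uppercase sequence of [start, end) on the forward strand."""
        if chrom not in self._fa:
            raise KeyError(f"contig {chrom!r} not in genome")
        n = len(self._fa[chrom])
        if start < 0 or end > n or start > end:
            raise IndexError(f"slice [{start},{end}) out of bounds for {chrom} (len {n})")
        return str(self._fa[chrom][start:end])

    def contigs(self) -> list[str]:
        return list(self._fa.keys())


# ---------------------------------------------------------------------------
# readers


def read_genome(fasta_path: str) -> GenomeStore:
    return GenomeStore(fasta_path)


def _transcript_exonic_length(db, tx_id: str) -> int:
    return sum(f.end - f.start + 1 for f in db.children(tx_id, featuretype="exon"))


def read_gene_models(
    gtf_path: str,
    longest_transcript_only: bool = True,
    protein_coding_only: str = "auto",
) -> list[GeneModel]:
    """Parse a GTF into one :class:`GeneModel` per gene.

    When ``longest_transcript_only`` is set, the transcript with the maximal
    total exonic length is kept (ties broken by the lexicographically smallest
    transcript_id). ``protein_coding_only="auto"`` filters on a
    gene_biotype/gene_type attribute when one is present and keeps all genes
    otherwise; "always"/"never" force the behaviour.
    """
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: not a 9-column GTF row")
            if 'gene_id "' not in fields[8]:
                raise ValueError(f"{gtf_path}:{lineno}: missing gene_id attribute")

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype = gene.attributes.get("gene_biotype", gene.attributes.get("gene_type"))
        if protein_coding_only == "always" or (
            protein_coding_only == "auto" and biotype is not None
        ):
            if biotype is None or biotype[0] != "protein_coding":
                continue
        txs = list(db.children(gene.id, featuretype="transcript"))
        if not txs:
            continue
        if longest_transcript_only:
            txs.sort(key=lambda t: (-_transcript_exonic_length(db, t.id), t.id))
            txs = txs[:1]
        tx = txs[0]
        span = (tx.start - 1, tx.end)

        def ivs(ftypes) -> list[Interval]:
            return [
                (f.start - 1, f.end)
                for f in db.children(tx.id, featuretype=ftypes)
            ]

        exons = ivs("exon")
        for s, e in exons:
            if not (span[0] <= s and e <= span[1]):
                raise ValueError(
                    f"{gene.id}/{tx.id}: exon [{s},{e}) outside transcript span "
                    f"[{span[0]},{span[1]})"
                )
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=tx.strand,
                start=span[0],
                end=span[1],
                exons=exons,
                cds=ivs("CDS"),
                utr5=ivs(("five_prime_utr", "5UTR")),
                utr3=ivs(("three_prime_utr", "3UTR")),
                transcript_id=tx.id,
            )
        )
    return models


def read_track(bedgraph_path: str) -> ConservationTrack:
    """Load a 4-column bedGraph (0-based half-open) as a conservation track."""
    df = pd.read_csv(
        bedgraph_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if df["value"].isna().any():
        raise ValueError(f"{bedgraph_path}: non-numeric score")
    return ConservationTrack(df)


def read_bed(path: str) -> IntervalTable:
    """Read a BED3+/interval TSV into an IntervalTable (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    return IntervalTable(df)


def read_matrix(path: str, format: str = "tsv", row_names: str | None = None,
                col_names: str | None = None) -> ExpressionMatrix:
    """Read a counts matrix from TSV or MatrixMarket triplet form.

    TSV: first column gene ids, header row of sample ids. MTX: the triplet
    file plus one-id-per-line ``row_names``/``col_names`` files; cells absent
    from the triplet list are zero.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "mtx_triplet":
        if row_names is None or col_names is None:
            raise ValueError("mtx_triplet requires row_names and col_names files")
        mat = mmread(str(path)).toarray()
        rows = [l.strip() for l in open(row_names) if l.strip()]
        cols = [l.strip() for l in open(col_names) if l.strip()]
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match names "
                f"({len(rows)} rows, {len(cols)} cols)"
            )
        df = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return ExpressionMatrix(df, kind="counts")


def read_labels(path: str) -> LabelSet:
    """Read a two-column TSV of gene_id, label."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "label"])
    return LabelSet(pd.Series(df["label"].values, index=df["gene"].astype(str)))


def read_gene_list(path: str) -> list[str]:
    return [l.strip() for l in open(path) if l.strip()]


def read_motifs(path: str) -> MotifSet:
    """Read motifs from a small text format.

    Each motif starts with ``>name``; the body is either four rows
    ``A:``/``C:``/``G:``/``T:`` of per-position counts or weights (normalized
    per column to a PWM), or a single bare ACGT consensus line.
    """
    motifs: list[Motif] = []
    name, body = None, []

    def flush():
        if name is None:
            return
        if not body:
            raise ValueError(f"motif {name}: empty body")
        if body[0][0] in "ACGT" and ":" not in body[0]:
            if len(body) != 1:
                raise ValueError(f"motif {name}: consensus must be a single line")
            motifs.append(Motif(name=name, consensus=body[0]))
        else:
            rows = {}
            for line in body:
                base, _, rest = line.partition(":")
                rows[base.strip()] = [float(x) for x in rest.split()]
            mat = np.array([rows[b] for b in "ACGT"], dtype=float)
            mat = mat / mat.sum(axis=0, keepdims=True)
            motifs.append(Motif(name=name, pwm=mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name, body = line[1:].strip(), []
            else:
                body.append(line)
        flush()
    return MotifSet(motifs)


# ---------------------------------------------------------------------------
# model serialization (versioned JSON; the model class lives in cig_model)

MODEL_SCHEMA_VERSION = 1


def save_model(model, path: str) -> None:
    payload = {"schema_version": MODEL_SCHEMA_VERSION, "model": model.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str):
    from .cig_model import TrainedCIGModel

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} not supported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return TrainedCIGModel.from_dict(payload["model"])
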