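"""Domain types, on-disk formats and coordinate conventions.

All internal coordinates are 0-based half-open.  GFF3 input/output is
1-based closed and converted at the boundary.  Sequences are uppercased on
ingestion and any character outside {A, C, G, T, N} is collapsed to N (the
replacement count is logged); downstream window metrics define explicit N
policies, and the synthetic generator never emits N.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("censcan")

VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Chromosome:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            n_bad = sum(self.seq.count(c) for c in bad)
            logger.info(
                "chromosome %s: replaced %d non-ACGTN characters with N",
                self.name, n_bad,
            )
            self.seq = _NON_ACGTN.sub("N", self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def codes(self) -> np.ndarray:
        """Sequence as int8 codes: A=0 C=1 G=2 T=3, N=-1."""
        return encode_seq(self.seq)


_CODE_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    out = np.full(len(codes), ord("N"), dtype=np.uint8)
    ok = codes >= 0
    out[ok] = _DECODE[codes[ok]]
    return out.tobytes().decode()


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneRecord:
    gene_id: str
    interval: Interval
    is_gc_outlier: bool
    gc3: float | None = None


@dataclass(frozen=True)
class GeneticMarker:
    chrom: str
    bp: int
    cM: float

    def __post_init__(self) -> None:
        if self.cM < 0:
            raise ValueError(f"negative genetic position: {self.cM}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Chromosome]:
    """Read a FASTA file into Chromosome records.

    Sequences are uppercased; non-ACGTN characters become N (logged).
    Raises on an empty file or duplicate record names.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate FASTA record names: {dupes}")
    return [Chromosome(r.id, str(r.seq)) for r in records]


def write_fasta(path: str | Path, chroms: Iterable[Chromosome],
                width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(c.seq), id=c.name, description="") for c in chroms
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# genetic-map markers (TSV: chrom, bp, cM)
# ---------------------------------------------------------------------------

def read_markers(path: str | Path) -> list[GeneticMarker]:
    """Read a marker table; sort by (chrom, bp); collapse duplicate
    (chrom, bp) rows to their mean cM (logged)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "bp", "cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    try:
        df["bp"] = df["bp"].astype(np.int64)
        df["cM"] = df["cM"].astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric bp/cM in {path}: {exc}") from exc
    if (df["cM"] < 0).any():
        raise ValueError("negative cM in marker table")
    n_before = len(df)
    df = (
        df.groupby(["chrom", "bp"], as_index=False)["cM"]
        .mean()
        .sort_values(["chrom", "bp"], kind="stable")
    )
    if len(df) < n_before:
        logger.info("collapsed %d duplicate-position markers",
                    n_before - len(df))
    return [
        GeneticMarker(str(r.chrom), int(r.bp), float(r.cM))
        for r in df.itertuples()
    ]


def write_markers(path: str | Path, markers: Sequence[GeneticMarker]) -> None:
    pd.DataFrame(
        {"chrom": [m.chrom for m in markers],
         "bp": [m.bp for m in markers],
         "cM": [m.cM for m in markers]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genes: GFF3 (1-based closed) or 6-column tabular (0-based half-open)
# ---------------------------------------------------------------------------

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def _attr(attributes: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;){key}=([^;]+)", attributes)
    return m.group(1) if m else None


def read_genes(path: str | Path,
               genome: Sequence[Chromosome] | None = None) -> list[GeneRecord]:
    """Read gene records from GFF3 (``gene`` features) or a 6-column table
    (chrom, start, end, gene_id, is_gc_outlier, gc3).

    GFF3 coordinates are converted to 0-based half-open.  If a genome is
    supplied, intervals outside chromosome bounds raise.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or len(first.rstrip("\n").split("\t")) == 9:
        df = pd.read_csv(path, sep="\t", comment="#", names=_GFF_COLS,
                         dtype=str)
        df = df[df["type"] == "gene"]
        genes = []
        for r in df.itertuples():
            attrs = r.attributes
            gid = _attr(attrs, "ID") or _attr(attrs, "gene_id")
            if gid is None:
                raise ValueError(f"gene feature without ID in {path}")
            outlier = (_attr(attrs, "is_gc_outlier") or "0") in ("1", "true",
                                                                 "True")
            gc3_s = _attr(attrs, "gc3")
            genes.append(GeneRecord(
                gene_id=gid,
                interval=Interval(str(r.seqid), int(r.start) - 1, int(r.end),
                                  r.strand if r.strand in "+-" else "."),
                is_gc_outlier=outlier,
                gc3=float(gc3_s) if gc3_s else None,
            ))
    else:
        df = pd.read_csv(
            path, sep="\t",
            names=["chrom", "start", "end", "gene_id", "is_gc_outlier",
                   "gc3"],
        )
        genes = []
        for r in df.itertuples():
            gc3 = None if (pd.isna(r.gc3) or r.gc3 == ".") else float(r.gc3)
            genes.append(GeneRecord(
                gene_id=str(r.gene_id),
                interval=Interval(str(r.chrom), int(r.start), int(r.end)),
                is_gc_outlier=bool(int(r.is_gc_outlier)),
                gc3=gc3,
            ))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    if genome is not None:
        lengths = {c.name: c.length for c in genome}
        for g in genes:
            L = lengths.get(g.interval.chrom)
            if L is not None and g.interval.end > L:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of "
                    f"{g.interval.chrom} ({g.interval.end} > {L})"
                )
    return genes


def write_genes_tsv(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            gc3 = "." if g.gc3 is None else f"{g.gc3:.4f}"
            fh.write(
                f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t"
                f"{g.gene_id}\t{int(g.is_gc_outlier)}\t{gc3}\n"
            )


def write_genes_gff3(path: str | Path, genes: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};is_gc_outlier={int(g.is_gc_outlier)}"
            if g.gc3 is not None:
                attrs += f";gc3={g.gc3:.4f}"
            fh.write(
                f"{g.interval.chrom}\tcenscan\tgene\t"
                f"{g.interval.start + 1}\t{g.interval.end}\t.\t"
                f"{g.interval.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple]:
    """Read a BED file as raw rows (chrom, start, end, [name, score,
    strand, ...]); coordinates as ints, other columns as written."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return rows


def write_bed(path: str | Path, rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def intervals_to_bed(path: str | Path, intervals: Iterable[Interval],
                     names: Iterable[str] | None = None,
                     scores: Iterable | None = None) -> None:
    ivs = list(intervals)
    names = list(names) if names is not None else ["."] * len(ivs)
    scores = list(scores) if scores is not None else [0] * len(ivs)
    write_bed(path, [
        (iv.chrom, iv.start, iv.end, nm, sc, iv.strand)
        for iv, nm, sc in zip(ivs, names, scores)
    ])


# ---------------------------------------------------------------------------
# configuration & logging
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def setup_logging(level: int = logging.INFO,
                  logfile: str | Path | None = None) -> logging.Logger:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(level)
    return logger
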