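"""Readers and writers for gene annotations, sequences and summary tables.

All gene-matching identifiers are normalized at parse time: symbols are
lowercased, ``ko:`` prefixes stripped, EC numbers kept as dotted strings.
The unbinned fraction of a sample is represented with the reserved genome id
``UNBINNED:<sample_id>`` so the same readers serve the unbinned screen.

Supported dialects
------------------
* ``gff3`` — Prokka-style GFF3; the gene symbol comes from the ``gene=``
  attribute and EC numbers from ``eC_number=``; a trailing ``##FASTA``
  section is ignored.
* ``emapper_tsv`` — eggNOG-mapper v2 annotations: ``##`` comment lines are
  skipped, the header starts with ``#query``; the reader surfaces
  ``Preferred_name``, ``KEGG_ko`` and ``EC``.
* ``simple_tsv`` — two or three columns (genome_id, symbol[, ko]); an
  optional header line starting with ``genome_id`` is allowed.
"""

from __future__ import annotations

import io as _stdlib_io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

UNBINNED_PREFIX = "UNBINNED:"

GENE_TABLE_FORMATS = ("gff3", "emapper_tsv", "simple_tsv")


class AnnotationIOError(ValueError):
    """Raised for malformed annotation, quality or count inputs."""


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().lower()


def normalize_ko(ko: str) -> str:
    ko = ko.strip()
    if ko.lower().startswith("ko:"):
        ko = ko[3:]
    return ko.upper()


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene call on a genome."""

    genome_id: str
    gene_id: str
    symbol: Optional[str] = None
    ko: Optional[str] = None
    ec: tuple[str, ...] = ()
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise AnnotationIOError("genome_id must be non-empty")
        if not self.gene_id:
            raise AnnotationIOError("gene_id must be non-empty")
        if not (self.symbol or self.ko or self.ec or self.product):
            raise AnnotationIOError(
                f"gene {self.gene_id!r} on {self.genome_id!r} carries no identifier"
            )
        if self.symbol is not None:
            object.__setattr__(self, "symbol", normalize_symbol(self.symbol))
        if self.ko is not None:
            object.__setattr__(self, "ko", normalize_ko(self.ko))
        object.__setattr__(self, "ec", tuple(self.ec))


@dataclass
class AnnotatedGenome:
    """A bin/MAG with its gene calls; may be the unbinned pseudo-genome."""

    genome_id: str
    genes: list[GeneAnnotation] = field(default_factory=list)
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationIOError(
                f"genome {self.genome_id!r}: duplicate gene ids {dup[:5]}"
            )

    @property
    def is_unbinned(self) -> bool:
        return self.genome_id.startswith(UNBINNED_PREFIX)


@dataclass(frozen=True)
class QualityRecord:
    genome_id: str
    completeness: float
    contamination: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise AnnotationIOError(
                f"{self.genome_id}: completeness {self.completeness} outside [0, 100]"
            )
        if self.contamination < 0.0:
            raise AnnotationIOError(
                f"{self.genome_id}: contamination {self.contamination} negative"
            )


@dataclass(frozen=True)
class CountRecord:
    genome_id: str
    sample_id: str
    mapped_reads: int
    total_reads_in_sample: int

    def __post_init__(self) -> None:
        if self.total_reads_in_sample <= 0:
            raise AnnotationIOError(
                f"{self.genome_id}: total reads must be positive"
            )
        if not 0 <= self.mapped_reads <= self.total_reads_in_sample:
            raise AnnotationIOError(
                f"{self.genome_id}: mapped reads {self.mapped_reads} outside "
                f"[0, {self.total_reads_in_sample}]"
            )


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

def _group_genomes(genes: Iterable[GeneAnnotation],
                   sample_id: Optional[str]) -> list[AnnotatedGenome]:
    by_genome: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    return [AnnotatedGenome(genome_id=gid, genes=gl, sample_id=sample_id)
            for gid, gl in sorted(by_genome.items())]


def _read_simple_tsv(text: str, path: str) -> list[GeneAnnotation]:
    genes: list[GeneAnnotation] = []
    counter: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].strip().lower() == "genome_id":
            continue
        if len(fields) not in (2, 3):
            raise AnnotationIOError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated columns, "
                f"got {len(fields)}"
            )
        genome_id = fields[0].strip()
        symbol = fields[1].strip()
        ko = fields[2].strip() if len(fields) == 3 and fields[2].strip() else None
        if not genome_id or not symbol:
            raise AnnotationIOError(f"{path}:{lineno}: empty genome_id or symbol")
        counter[genome_id] = counter.get(genome_id, 0) + 1
        genes.append(GeneAnnotation(
            genome_id=genome_id,
            gene_id=f"{genome_id}_{counter[genome_id]:05d}",
            symbol=symbol,
            ko=ko,
        ))
    return genes


_EMAPPER_EMPTY = {"", "-", "nan"}


def _read_emapper_tsv(text: str, path: str, genome_id: str) -> list[GeneAnnotation]:
    header: list[str] | None = None
    genes: list[GeneAnnotation] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if raw.startswith("##") or not raw.strip():
            continue
        if raw.startswith("#"):
            header = raw.lstrip("#").rstrip("\n").split("\t")
            continue
        if header is None:
            raise AnnotationIOError(
                f"{path}:{lineno}: data before the '#query' header line"
            )
        fields = raw.rstrip("\n").split("\t")
        row = dict(zip(header, fields))
        query = row.get("query", "").strip()
        if not query:
            raise AnnotationIOError(f"{path}:{lineno}: missing query id")
        name = row.get("Preferred_name", "").strip()
        ko_field = row.get("KEGG_ko", "").strip()
        ec_field = row.get("EC", "").strip()
        symbol = None if name in _EMAPPER_EMPTY else name
        ko = None
        if ko_field not in _EMAPPER_EMPTY:
            ko = normalize_ko(ko_field.split(",")[0])
        ecs: tuple[str, ...] = ()
        if ec_field not in _EMAPPER_EMPTY:
            ecs = tuple(e.strip() for e in ec_field.split(",") if e.strip())
        if not (symbol or ko or ecs):
            continue  # annotation row with no usable identifier
        genes.append(GeneAnnotation(
            genome_id=genome_id, gene_id=query, symbol=symbol, ko=ko, ec=ecs,
            product=row.get("Description") or None,
        ))
    return genes


def _read_gff3(text: str, path: str, genome_id: str) -> list[GeneAnnotation]:
    # Strip the Prokka ##FASTA tail before feeding gffutils.
    fasta_at = text.find("##FASTA")
    if fasta_at != -1:
        text = text[:fasta_at]
    from gffutils.iterators import DataIterator

    genes: list[GeneAnnotation] = []
    counter = 0
    for feat in DataIterator(text, from_string=True):
        if feat.featuretype not in ("CDS", "gene"):
            continue
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
        counter += 1
        if gene_id is None:
            gene_id = f"{genome_id}_{counter:05d}"
        symbol = (attrs.get("gene") or [None])[0]
        ecs = tuple(attrs.get("eC_number") or ())
        product = (attrs.get("product") or [None])[0]
        ko = (attrs.get("KO") or attrs.get("ko") or [None])[0]
        if not (symbol or ko or ecs or product):
            continue
        genes.append(GeneAnnotation(
            genome_id=genome_id, gene_id=gene_id, symbol=symbol,
            ko=ko, ec=ecs, product=product,
        ))
    return genes


def read_gene_table(path: str | Path, format: str,
                    genome_id: Optional[str] = None,
                    sample_id: Optional[str] = None) -> list[AnnotatedGenome]:
    """Read a gene-annotation table into one AnnotatedGenome per genome id.

    For the per-genome dialects (``gff3``, ``emapper_tsv``) the genome id
    defaults to the file stem; ``simple_tsv`` carries genome ids in its
    first column.  Duplicate gene symbols are preserved as separate genes.
    """
    if format not in GENE_TABLE_FORMATS:
        raise AnnotationIOError(
            f"unknown gene-table format {format!r}; expected one of "
            f"{GENE_TABLE_FORMATS}"
        )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene table not found: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        warnings.warn(f"{path}: empty gene table", stacklevel=2)
        return []
    gid = genome_id or path.stem
    if format == "simple_tsv":
        genes = _read_simple_tsv(text, str(path))
    elif format == "emapper_tsv":
        genes = _read_emapper_tsv(text, str(path), gid)
    else:
        genes = _read_gff3(text, str(path), gid)
    return _group_genomes(genes, sample_id)


def write_simple_tsv(genomes: Sequence[AnnotatedGenome], path: str | Path) -> None:
    """Write genomes as a simple three-column TSV (genome_id, symbol, ko)."""
    lines = ["genome_id\tsymbol\tko"]
    for genome in genomes:
        for gene in genome.genes:
            if gene.symbol is None:
                continue
            lines.append(f"{genome.genome_id}\t{gene.symbol}\t{gene.ko or ''}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_IUPAC = set("ACGTUNRYSWKMBDHV")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (contig_id, uppercase sequence) pairs, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AnnotationIOError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise AnnotationIOError(f"{path}: contig {rec.id!r} has empty sequence")
        bad = set(seq) - _IUPAC
        if bad:
            raise AnnotationIOError(
                f"{path}: contig {rec.id!r} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(contigs: Sequence[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Quality and count tables
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationIOError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    return df


def _parse_percent(value: str, where: str) -> float:
    value = str(value).strip().rstrip("%").strip()
    if "," in value:
        raise AnnotationIOError(
            f"{where}: number {value!r} contains a comma; use plain decimals"
        )
    try:
        out = float(value)
    except ValueError as exc:
        raise AnnotationIOError(f"{where}: cannot parse number {value!r}") from exc
    if math.isnan(out):
        raise AnnotationIOError(f"{where}: missing numeric value")
    return out


def read_quality_table(path: str | Path) -> list[QualityRecord]:
    """Read a CheckM-style TSV with columns genome_id, completeness, contamination."""
    df = _read_table(path, ["genome_id", "completeness", "contamination"])
    records = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        records.append(QualityRecord(
            genome_id=str(row["genome_id"]).strip(),
            completeness=_parse_percent(row["completeness"], where),
            contamination=_parse_percent(row["contamination"], where),
        ))
    return records


def _parse_int(value: str, where: str) -> int:
    value = str(value).strip()
    if "," in value:
        raise AnnotationIOError(
            f"{where}: number {value!r} contains a comma; use plain integers"
        )
    try:
        return int(value)
    except ValueError as exc:
        raise AnnotationIOError(f"{where}: cannot parse integer {value!r}") from exc


def read_count_table(path: str | Path) -> list[CountRecord]:
    """Read a mapped-read count TSV with columns genome_id, sample_id,
    mapped_reads, total_reads."""
    df = _read_table(path, ["genome_id", "sample_id", "mapped_reads", "total_reads"])
    records = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        records.append(CountRecord(
            genome_id=str(row["genome_id"]).strip(),
            sample_id=str(row["sample_id"]).strip(),
            mapped_reads=_parse_int(row["mapped_reads"], where),
            total_reads_in_sample=_parse_int(row["total_reads"], where),
        ))
    return records


def write_quality_table(records: Sequence[QualityRecord], path: str | Path) -> None:
    lines = ["genome_id\tcompleteness\tcontamination"]
    for r in records:
        lines.append(f"{r.genome_id}\t{r.completeness:.2f}\t{r.contamination:.2f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_count_table(records: Sequence[CountRecord], path: str | Path) -> None:
    lines = ["genome_id\tsample_id\tmapped_reads\ttotal_reads"]
    for r in records:
        lines.append(f"{r.genome_id}\t{r.sample_id}\t{r.mapped_reads}"
                     f"\t{r.total_reads_in_sample}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
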