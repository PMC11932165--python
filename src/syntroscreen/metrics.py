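"""MAG quality tiering, relative abundance and assembly statistics.

The tier rule follows the CheckM-style convention: high quality needs
completeness >= 90% with contamination <= 10%; otherwise any bin with
completeness >= 70% is medium; everything else is low.  The literal
published cut-offs leave gaps (a bin at 80% completeness / 5% contamination
satisfies neither the printed "medium" nor "low" definition); this rule
totalizes them while reproducing the printed tiers wherever they apply.

Relative abundance is mapped reads over total reads in the same sample.
GC content is 100*(G+C)/(A+C+G+T): ambiguity codes are excluded from both
numerator and denominator (total length still counts them).  Percentages
are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .io import CountRecord, UNBINNED_PREFIX


class MetricsError(ValueError):
    pass


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


TIERS = ("high", "medium", "low")


def quality_tier(completeness: float, contamination: float) -> str:
    """Classify a bin as high/medium/low from completeness and contamination."""
    if not 0.0 <= completeness <= 100.0:
        raise MetricsError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0.0:
        raise MetricsError(f"contamination {contamination} negative")
    if completeness >= 90.0 and contamination <= 10.0:
        return "high"
    if completeness >= 70.0:
        return "medium"
    return "low"


@dataclass(frozen=True)
class AbundanceRecord:
    genome_id: str
    sample_id: str
    fraction: float

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.fraction)


def relative_abundance(counts: Sequence[CountRecord]
                       ) -> dict[str, AbundanceRecord]:
    """Per-genome fraction of its sample's total reads.

    All records of one sample must agree on the sample total, and the mapped
    reads of a sample must not exceed that total.
    """
    totals: dict[str, int] = {}
    mapped_sums: dict[str, int] = {}
    for rec in counts:
        prev = totals.get(rec.sample_id)
        if prev is not None and prev != rec.total_reads_in_sample:
            raise MetricsError(
                f"sample {rec.sample_id!r}: inconsistent totals "
                f"{prev} vs {rec.total_reads_in_sample}"
            )
        totals[rec.sample_id] = rec.total_reads_in_sample
        mapped_sums[rec.sample_id] = (
            mapped_sums.get(rec.sample_id, 0) + rec.mapped_reads)
    for sample, mapped in mapped_sums.items():
        if mapped > totals[sample]:
            raise MetricsError(
                f"sample {sample!r}: mapped reads across genomes ({mapped}) "
                f"exceed the sample total ({totals[sample]})"
            )
    out: dict[str, AbundanceRecord] = {}
    for rec in counts:
        if rec.genome_id in out:
            raise MetricsError(f"duplicate count record for {rec.genome_id!r}")
        out[rec.genome_id] = AbundanceRecord(
            genome_id=rec.genome_id,
            sample_id=rec.sample_id,
            fraction=rec.mapped_reads / rec.total_reads_in_sample,
        )
    return out


def unbinned_fraction(abundances: Mapping[str, AbundanceRecord],
                      sample_id: str) -> float:
    """Remainder of a sample's reads not mapped to any binned genome."""
    binned = sum(rec.fraction for rec in abundances.values()
                 if rec.sample_id == sample_id
                 and not rec.genome_id.startswith(UNBINNED_PREFIX))
    return 1.0 - binned


@dataclass(frozen=True)
class AssemblyStats:
    genome_id: str
    total_length: int
    n_contigs: int
    gc_percent: float
    n50: int


def assembly_stats(contigs: Sequence[tuple[str, str]],
                   genome_id: str = "",
                   gc_denominator: str = "acgt") -> AssemblyStats:
    """Total length, contig count, GC% and N50 for one assembly.

    ``gc_denominator`` selects whether ambiguity codes enter the GC
    denominator: ``acgt`` (default, excluded) or ``all`` (full length).
    """
    if not contigs:
        raise MetricsError("assembly_stats requires at least one contig")
    if gc_denominator not in ("acgt", "all"):
        raise MetricsError(f"unknown gc_denominator {gc_denominator!r}")
    lengths = []
    gc = at = 0
    for _, seq in contigs:
        s = seq.upper()
        if not s:
            raise MetricsError("empty contig sequence")
        lengths.append(len(s))
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    total = sum(lengths)
    denom = (gc + at) if gc_denominator == "acgt" else total
    if denom == 0:
        raise MetricsError("no unambiguous bases; GC content undefined")
    gc_percent = round_half_up(100.0 * gc / denom)

    half = total / 2.0
    acc = 0
    n50 = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= half:
            n50 = length
            break
    return AssemblyStats(
        genome_id=genome_id,
        total_length=total,
        n_contigs=len(lengths),
        gc_percent=gc_percent,
        n50=n50,
    )
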