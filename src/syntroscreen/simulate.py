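"""Ground-truthed synthetic cohorts for exercising every screening stage.

Six guild archetypes mirror the functional groups of a thermophilic
high-ammonia digester community:

* ``true_acetogen`` — complete WLP, acetate activation couple, no pntAB;
* ``saob_wlp`` — complete WLP plus grd, pntAB, Ech hydrogenase and F-type
  ATPase (the pattern of WLP-carrying syntrophic acetate oxidisers);
* ``wlp_gcs_hybrid`` — methyl-branch WLP genes only (no metF, no CODH/ACS)
  with a full GSRP, pntAB and Rnf complex (the pattern of candidates that
  replace the carbonyl branch with the glycine cleavage system);
* ``fermenter`` — acetate activation and housekeeping genes only;
* ``hydrogenotrophic_methanogen`` / ``acetoclastic_methanogen`` — MCR,
  F420 biosynthesis and potassium-regulation genes, the acetoclast adding
  the cdhABCDE complex.

Each genome starts from its archetype complement plus a background draw of
housekeeping genes; dropout removes each gene independently (mimicking an
incomplete bin), and contaminant genes sampled from the other archetypes
are injected (mimicking a contaminated bin).  Realized dropout and
injection rates are written into the quality records, so quality tiering
operates on the same ground truth.  Every draw flows from one
``numpy.random.default_rng(seed)``, and a cohort regenerates byte-for-byte
from its manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import json

import numpy as np

from .catalog import builtin_gsrp, builtin_markers, builtin_methanogenesis, builtin_wlp
from .io import (
    AnnotatedGenome,
    CountRecord,
    GeneAnnotation,
    QualityRecord,
    UNBINNED_PREFIX,
    write_count_table,
    write_fasta,
    write_quality_table,
    write_simple_tsv,
)

GUILDS = (
    "true_acetogen",
    "saob_wlp",
    "wlp_gcs_hybrid",
    "fermenter",
    "hydrogenotrophic_methanogen",
    "acetoclastic_methanogen",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GuildArchetype:
    name: str
    gene_complement: tuple[str, ...]  # sorted symbols
    expected_label: str
    expected_saob_support: bool


def _marker_symbols(name: str) -> list[str]:
    for m in builtin_markers():
        if m.name == name:
            return [s.symbol for s in m.subunits]
    raise KeyError(name)


def _methano_symbols(name: str) -> list[str]:
    for m in builtin_methanogenesis():
        if m.name == name:
            return [s.symbol for s in m.subunits]
    raise KeyError(name)


def build_archetypes() -> dict[str, GuildArchetype]:
    """The guild gene complements, cross-checked against the classifier."""
    wlp = builtin_wlp()
    gsrp = builtin_gsrp()
    wlp_all = [s.symbol for e in wlp.enzymes for s in e.subunits]
    methyl = [s.symbol for e in wlp.branch_enzymes("methyl") for s in e.subunits]
    activation = [s.symbol for e in wlp.branch_enzymes("activation")
                  for s in e.subunits]
    gsrp_all = [s.symbol for e in gsrp.enzymes for s in e.subunits]
    pnt = _marker_symbols("pntAB")
    rnf = _marker_symbols("Rnf complex")
    ech = _marker_symbols("Ech hydrogenase")
    potassium = _marker_symbols("potassium regulation")
    f_atp = _marker_symbols("F-type ATPase")
    va_atp = _marker_symbols("V/A-type ATPase")
    mcr = _methano_symbols("MCR complex")
    cdh = _methano_symbols("CDH complex (acetoclastic)")
    f420 = _methano_symbols("F420 biosynthesis")

    # methyl-branch genes of the hybrid pattern: fhs/fdhA/folD but no metF
    hybrid_methyl = [s for s in methyl if s != "metF"]

    specs = {
        "true_acetogen": (
            wlp_all + ["grd"] + va_atp, "acetogen_candidate", False),
        "saob_wlp": (
            wlp_all + ["grd"] + pnt + ech + f_atp, "acetogen_candidate", True),
        "wlp_gcs_hybrid": (
            hybrid_methyl + activation + gsrp_all + pnt + rnf + f_atp,
            "wlp_gcs_hybrid", True),
        "fermenter": (
            activation + f_atp, "non_candidate", False),
        "hydrogenotrophic_methanogen": (
            mcr + f420 + potassium + va_atp, "non_candidate", False),
        "acetoclastic_methanogen": (
            mcr + cdh + f420 + potassium + activation + va_atp,
            "non_candidate", False),
    }
    out: dict[str, GuildArchetype] = {}
    for name, (genes, label, saob) in specs.items():
        arch = GuildArchetype(
            name=name,
            gene_complement=tuple(sorted(set(genes))),
            expected_label=label,
            expected_saob_support=saob,
        )
        _check_archetype(arch)
        out[name] = arch
    return out


def _check_archetype(arch: GuildArchetype) -> None:
    """Verify at build time that the classifier reproduces the expected label."""
    from .screening import classify_candidate, profile_pathway, score_enzyme

    genome = _genome_from_symbols("ARCHETYPE", arch.gene_complement)
    wlp_p = profile_pathway(genome, builtin_wlp())
    gsrp_p = profile_pathway(genome, builtin_gsrp())
    markers = {m.name: score_enzyme(genome, m) for m in builtin_markers()}
    call = classify_candidate(wlp_p, gsrp_p, markers)
    if call.label != arch.expected_label:
        raise SimulationError(
            f"archetype {arch.name!r}: classifier yields {call.label!r}, "
            f"expected {arch.expected_label!r}"
        )
    if call.saob_support != arch.expected_saob_support:
        raise SimulationError(
            f"archetype {arch.name!r}: saob_support "
            f"{call.saob_support} != expected {arch.expected_saob_support}"
        )


def _genome_from_symbols(genome_id: str, symbols: Sequence[str],
                         sample_id: Optional[str] = None) -> AnnotatedGenome:
    genes = [
        GeneAnnotation(genome_id=genome_id,
                       gene_id=f"{genome_id}_{i:05d}", symbol=sym)
        for i, sym in enumerate(symbols, start=1)
    ]
    return AnnotatedGenome(genome_id=genome_id, genes=genes, sample_id=sample_id)


@dataclass
class CohortManifest:
    seed: int
    n_per_guild: int
    dropout_p: float
    contamination_rate: float
    background_pool_size: int = 500
    background_per_genome: int = 200
    total_reads: int = 1_000_000
    binned_fraction: float = 0.6
    sample_id: str = "S1"
    guilds: tuple[str, ...] = GUILDS


@dataclass
class SyntheticCohort:
    genomes: list[AnnotatedGenome]
    truth_labels: dict[str, str]        # genome_id -> expected label
    truth_saob: dict[str, bool]
    quality: list[QualityRecord]
    counts: list[CountRecord]
    manifest: CohortManifest


def generate_cohort(n_per_guild: int, dropout_p: float = 0.0,
                    contamination_rate: float = 0.0, seed: int = 0,
                    background_pool_size: int = 500,
                    background_per_genome: int = 200,
                    total_reads: int = 1_000_000,
                    binned_fraction: float = 0.6,
                    sample_id: str = "S1") -> SyntheticCohort:
    """Generate a ground-truthed cohort of annotated genomes.

    Each genome carries its archetype complement plus housekeeping
    background genes, degraded by i.i.d. dropout and salted with contaminant
    genes from the other guilds.  Completeness in the quality record is
    ``100 * (1 - realized dropout fraction)`` and contamination is
    ``100 * injected / original gene count``.
    """
    if not 0.0 <= dropout_p <= 1.0:
        raise SimulationError(f"dropout_p {dropout_p} outside [0, 1]")
    if not 0.0 <= contamination_rate < 1.0:
        raise SimulationError(
            f"contamination_rate {contamination_rate} outside [0, 1)")
    if n_per_guild < 0:
        raise SimulationError("n_per_guild must be non-negative")

    manifest = CohortManifest(
        seed=seed, n_per_guild=n_per_guild, dropout_p=dropout_p,
        contamination_rate=contamination_rate,
        background_pool_size=background_pool_size,
        background_per_genome=background_per_genome,
        total_reads=total_reads, binned_fraction=binned_fraction,
        sample_id=sample_id,
    )
    rng = np.random.default_rng(seed)
    archetypes = build_archetypes()
    pool = np.array([f"hyp_{i:04d}" for i in range(background_pool_size)])

    genomes: list[AnnotatedGenome] = []
    truth_labels: dict[str, str] = {}
    truth_saob: dict[str, bool] = {}
    quality: list[QualityRecord] = []

    for guild in manifest.guilds:
        arch = archetypes[guild]
        foreign = sorted(
            set().union(*(archetypes[g].gene_complement
                          for g in manifest.guilds if g != guild))
            - set(arch.gene_complement)
        )
        for i in range(1, n_per_guild + 1):
            gid = f"SYN.{guild}.{i:03d}"
            n_bg = min(background_per_genome, background_pool_size)
            background = rng.choice(pool, size=n_bg, replace=False)
            original = list(arch.gene_complement) + sorted(background.tolist())
            n_original = len(original)
            keep_mask = rng.random(n_original) >= dropout_p
            kept = [g for g, keep in zip(original, keep_mask) if keep]
            n_contam = rng.binomial(n_original, contamination_rate)
            n_contam = min(n_contam, len(foreign))
            injected = (sorted(rng.choice(np.array(foreign), size=n_contam,
                                          replace=False).tolist())
                        if n_contam else [])
            symbols = kept + injected
            genomes.append(_genome_from_symbols(gid, symbols, sample_id))
            truth_labels[gid] = arch.expected_label
            truth_saob[gid] = arch.expected_saob_support
            realized_dropout = 1.0 - (len(kept) / n_original)
            quality.append(QualityRecord(
                genome_id=gid,
                completeness=100.0 * (1.0 - realized_dropout),
                contamination=100.0 * len(injected) / n_original,
            ))

    counts: list[CountRecord] = []
    if genomes:
        raw = rng.dirichlet(np.ones(len(genomes)))
        proportions = {
            g.genome_id: float(p * binned_fraction)
            for g, p in zip(genomes, raw)
        }
        counts = generate_counts(proportions, total_reads,
                                 seed=int(rng.integers(0, 2**31 - 1)),
                                 sample_id=sample_id)
    return SyntheticCohort(
        genomes=genomes, truth_labels=truth_labels, truth_saob=truth_saob,
        quality=quality, counts=counts, manifest=manifest,
    )


def regenerate_cohort(manifest: CohortManifest) -> SyntheticCohort:
    """Rebuild a cohort byte-for-byte from its manifest."""
    return generate_cohort(
        n_per_guild=manifest.n_per_guild,
        dropout_p=manifest.dropout_p,
        contamination_rate=manifest.contamination_rate,
        seed=manifest.seed,
        background_pool_size=manifest.background_pool_size,
        background_per_genome=manifest.background_per_genome,
        total_reads=manifest.total_reads,
        binned_fraction=manifest.binned_fraction,
        sample_id=manifest.sample_id,
    )


def generate_counts(proportions: dict[str, float], total_reads: int,
                    seed: int = 0, sample_id: str = "S1") -> list[CountRecord]:
    """Multinomial read counts; the remainder goes to the unbinned fraction."""
    total_p = sum(proportions.values())
    if total_p > 1.0 + 1e-9:
        raise SimulationError(f"proportions sum to {total_p} > 1")
    if any(p < 0 for p in proportions.values()):
        raise SimulationError("proportions must be non-negative")
    rng = np.random.default_rng(seed)
    ids = sorted(proportions)
    pvals = np.array([proportions[g] for g in ids] + [max(0.0, 1.0 - total_p)])
    pvals = pvals / pvals.sum()
    draws = rng.multinomial(total_reads, pvals)
    records = [
        CountRecord(genome_id=gid, sample_id=sample_id,
                    mapped_reads=int(n), total_reads_in_sample=total_reads)
        for gid, n in zip(ids, draws[:-1])
    ]
    records.append(CountRecord(
        genome_id=f"{UNBINNED_PREFIX}{sample_id}", sample_id=sample_id,
        mapped_reads=int(draws[-1]), total_reads_in_sample=total_reads))
    return records


@dataclass(frozen=True)
class MutatedPair:
    """A random genome and a point-mutated copy at a known divergence."""

    sequence: str
    mutated: str
    substitution_rate: float
    realized_divergence: float
    seed: int


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def mutate_genome(length: int, substitution_rate: float,
                  seed: int = 0) -> MutatedPair:
    """Draw a uniform random genome and apply i.i.d. substitutions.

    Each substituted site switches to one of the three other bases with
    equal probability; the realized divergence (fraction of sites changed)
    is recorded alongside the nominal rate.
    """
    if not 0.0 <= substitution_rate < 0.5:
        raise SimulationError(
            f"substitution_rate {substitution_rate} outside [0, 0.5)")
    if length < 1:
        raise SimulationError("length must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length)
    seq = _BASES[idx]
    hit = rng.random(length) < substitution_rate
    # shift by 1..3 (mod 4) guarantees a different base at every hit site
    shifts = rng.integers(1, 4, size=length)
    mutated_idx = np.where(hit, (idx + shifts) % 4, idx)
    mutated = _BASES[mutated_idx]
    realized = float(np.count_nonzero(hit)) / length
    return MutatedPair(
        sequence=seq.tobytes().decode("ascii"),
        mutated=mutated.tobytes().decode("ascii"),
        substitution_rate=substitution_rate,
        realized_divergence=realized,
        seed=seed,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as the plain-text inputs the screen consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "quality": out / "quality.tsv",
        "counts": out / "counts.tsv",
        "manifest": out / "manifest.json",
        "truth": out / "truth_labels.tsv",
    }
    write_simple_tsv(cohort.genomes, paths["genes"])
    write_quality_table(cohort.quality, paths["quality"])
    write_count_table(cohort.counts, paths["counts"])
    paths["manifest"].write_text(
        json.dumps(asdict(cohort.manifest), indent=2), encoding="utf-8")
    lines = ["genome_id\texpected_label\texpected_saob_support"]
    for gid in sorted(cohort.truth_labels):
        lines.append(f"{gid}\t{cohort.truth_labels[gid]}"
                     f"\t{str(cohort.truth_saob[gid]).lower()}")
    paths["truth"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    return paths


def read_manifest(path: str | Path) -> CohortManifest:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    doc["guilds"] = tuple(doc.get("guilds", GUILDS))
    return CohortManifest(**doc)
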