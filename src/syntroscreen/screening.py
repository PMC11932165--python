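"""The core genome screen: enzyme recovery, pathway profiles, candidate calls.

Screening rules
---------------
* An enzyme is *fully recovered* when every required subunit has a matching
  gene call in the genome; *partially recovered* when one or more required
  subunits are missing but at least one is present; *absent* otherwise.
  A subunit matches on its KO accession, its symbol or any synonym, or an EC
  number (precedence for reporting: KO > symbol/synonym > EC).  Multiple
  copies of a gene count once.
* The WLP carries a gate gene (``fhs``): genomes without any ``fhs`` match
  are not screened further and the whole pathway is reported absent.
* Candidate classification: a complete or nearly complete WLP (at most
  ``near_complete_max_missing`` required methyl/carbonyl genes absent, with
  the carbonyl branch not entirely missing) marks an acetogen candidate; a
  methyl branch without any carbonyl gene, combined with a complete GSRP,
  marks a WLP–GCS hybrid.  The ``pntAB`` transhydrogenase flags SAOB support
  independently of the label, since known SAOB carry it and homoacetogens
  do not.  The acetate-activation couple (pta/ackA) is reported as evidence
  but never enters the WLP-state arithmetic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .catalog import (
    EnzymeDefinition,
    GeneIdentifier,
    PathwayDefinition,
    builtin_gsrp,
    builtin_markers,
    builtin_wlp,
    enzyme_to_dict,
    pathway_to_dict,
)
from .io import AnnotatedGenome, CountRecord, QualityRecord
from .metrics import quality_tier, relative_abundance

WLP_STATES = ("complete", "near_complete", "methyl_only", "partial", "absent")
GSRP_STATES = ("complete", "partial", "absent")
LABELS = ("acetogen_candidate", "wlp_gcs_hybrid", "non_candidate")

#: Branches whose required subunits drive the WLP state.  The activation
#: couple (pta/ackA) is catalogued and reported but kept out of the
#: completeness arithmetic.
WLP_CORE_BRANCHES = ("methyl", "carbonyl")


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class EnzymeStatus:
    """Full/partial/absent verdict for one enzyme on one genome."""

    enzyme_name: str
    branch: str
    status: str  # full | partial | absent
    present_subunits: frozenset[str]
    missing_subunits: frozenset[str]

    def __post_init__(self) -> None:
        if self.status not in ("full", "partial", "absent"):
            raise ScreeningError(f"invalid enzyme status {self.status!r}")


@dataclass
class PathwayProfile:
    """Per-genome recovery profile for one pathway.

    ``branch_completeness`` maps each branch to the fraction of its
    non-optional enzymes with status ``full``.  ``n_missing_genes`` counts
    required methyl/carbonyl subunits absent (the WLP core) for gated
    pathways, and all required subunits otherwise.
    """

    genome_id: str
    pathway_name: str
    statuses: list[EnzymeStatus]
    branch_completeness: dict[str, float]
    n_missing_genes: int
    gate_passed: bool

    def status_of(self, enzyme_name: str) -> EnzymeStatus:
        for st in self.statuses:
            if st.enzyme_name == enzyme_name:
                return st
        raise KeyError(enzyme_name)


@dataclass
class CandidateCall:
    """Classification verdict for one genome, with evidence strings."""

    genome_id: str
    wlp_state: str
    gsrp_state: str
    label: str
    saob_support: bool
    evidence: list[str] = field(default_factory=list)


@dataclass
class _GenomeIndex:
    """Lookup sets for matching subunits against a genome's gene calls."""

    symbols: set[str]
    kos: set[str]
    ecs: set[str]

    @classmethod
    def build(cls, genome: AnnotatedGenome) -> "_GenomeIndex":
        symbols, kos, ecs = set(), set(), set()
        for g in genome.genes:
            if g.symbol:
                symbols.add(g.symbol)
            if g.ko:
                kos.add(g.ko)
            for ec in g.ec:
                ecs.add(ec)
        return cls(symbols=symbols, kos=kos, ecs=ecs)

    def match(self, ident: GeneIdentifier) -> Optional[str]:
        """Return the identifier that matched (KO > symbol/synonym > EC)."""
        if ident.ko and ident.ko in self.kos:
            return ident.ko
        hit = self.symbols & ident.all_symbols
        if hit:
            return sorted(hit)[0]
        if ident.ec and ident.ec in self.ecs:
            return ident.ec
        return None


def score_enzyme(genome: AnnotatedGenome, enzyme: EnzymeDefinition,
                 index: Optional[_GenomeIndex] = None) -> EnzymeStatus:
    """Score one enzyme against one genome.

    Full iff every required subunit matches; optional subunits never affect
    the verdict.
    """
    idx = index or _GenomeIndex.build(genome)
    present, missing = set(), set()
    for sub in enzyme.required_subunits:
        if idx.match(sub) is not None:
            present.add(sub.symbol)
        else:
            missing.add(sub.symbol)
    if not missing and present:
        status = "full"
    elif present:
        status = "partial"
    else:
        status = "absent"
    if not enzyme.required_subunits:
        # all-optional enzyme: informational only
        status = "full" if any(idx.match(s) for s in enzyme.subunits) else "absent"
    return EnzymeStatus(
        enzyme_name=enzyme.name,
        branch=enzyme.branch,
        status=status,
        present_subunits=frozenset(present),
        missing_subunits=frozenset(missing),
    )


def _core_branches(pathway: PathwayDefinition) -> tuple[str, ...]:
    if pathway.gate_gene is not None:
        return WLP_CORE_BRANCHES
    return tuple(dict.fromkeys(e.branch for e in pathway.enzymes))


def profile_pathway(genome: AnnotatedGenome,
                    pathway: PathwayDefinition) -> PathwayProfile:
    """Score every enzyme of a pathway, honouring the gate gene."""
    idx = _GenomeIndex.build(genome)
    gate_passed = True
    if pathway.gate_gene is not None:
        gate_passed = idx.match(pathway.gate_gene) is not None

    statuses: list[EnzymeStatus] = []
    for enzyme in pathway.enzymes:
        if gate_passed:
            statuses.append(score_enzyme(genome, enzyme, idx))
        else:
            statuses.append(EnzymeStatus(
                enzyme_name=enzyme.name,
                branch=enzyme.branch,
                status="absent",
                present_subunits=frozenset(),
                missing_subunits=frozenset(
                    s.symbol for s in enzyme.required_subunits),
            ))

    branch_completeness: dict[str, float] = {}
    for branch in dict.fromkeys(e.branch for e in pathway.enzymes):
        scored = [st for st, e in zip(statuses, pathway.enzymes)
                  if e.branch == branch and not e.is_optional]
        if scored:
            branch_completeness[branch] = (
                sum(st.status == "full" for st in scored) / len(scored))
        else:
            branch_completeness[branch] = 0.0

    core = _core_branches(pathway)
    n_missing = sum(len(st.missing_subunits) for st, e in
                    zip(statuses, pathway.enzymes)
                    if e.branch in core and not e.is_optional)
    return PathwayProfile(
        genome_id=genome.genome_id,
        pathway_name=pathway.name,
        statuses=statuses,
        branch_completeness=branch_completeness,
        n_missing_genes=n_missing,
        gate_passed=gate_passed,
    )


def _branch_statuses(profile: PathwayProfile, branch: str) -> list[EnzymeStatus]:
    return [st for st in profile.statuses if st.branch == branch]


def classify_candidate(wlp: PathwayProfile, gsrp: PathwayProfile,
                       markers: Mapping[str, EnzymeStatus] | None = None,
                       near_complete_max_missing: int = 1) -> CandidateCall:
    """Combine WLP/GSRP profiles and marker hits into a candidate call."""
    if wlp.genome_id != gsrp.genome_id:
        raise ScreeningError(
            f"profile genome ids differ: {wlp.genome_id!r} vs {gsrp.genome_id!r}"
        )
    markers = markers or {}
    evidence: list[str] = []

    carbonyl = _branch_statuses(wlp, "carbonyl")
    carbonyl_all_absent = all(st.status == "absent" for st in carbonyl)
    methyl_frac = wlp.branch_completeness.get("methyl", 0.0)
    n_missing = wlp.n_missing_genes
    any_core_present = any(
        st.present_subunits for st in wlp.statuses
        if st.branch in WLP_CORE_BRANCHES)

    if not wlp.gate_passed:
        wlp_state = "absent"
        evidence.append("gate gene fhs not detected; WLP not screened")
    elif n_missing == 0:
        wlp_state = "complete"
        evidence.append("all required WLP methyl+carbonyl genes present")
    elif n_missing <= near_complete_max_missing and not carbonyl_all_absent:
        wlp_state = "near_complete"
        evidence.append(
            f"WLP missing {n_missing} required gene(s) "
            f"(<= {near_complete_max_missing}) with carbonyl branch evidence")
    elif methyl_frac > 0 and carbonyl_all_absent:
        wlp_state = "methyl_only"
        evidence.append("WLP methyl branch present, carbonyl branch absent")
    elif any_core_present:
        wlp_state = "partial"
        evidence.append(f"WLP partial: {n_missing} required core gene(s) missing")
    else:
        wlp_state = "absent"
        evidence.append("no WLP core genes detected")

    # An all-optional enzyme carries neither present nor missing required
    # subunits, so this filter keeps exactly the required GSRP genes.
    gsrp_required = [st for st in gsrp.statuses
                     if st.missing_subunits or st.present_subunits]
    if gsrp_required and all(st.status == "full" for st in gsrp_required):
        gsrp_state = "complete"
        evidence.append("all required GSRP genes present")
    elif any(st.present_subunits for st in gsrp_required):
        gsrp_state = "partial"
        evidence.append("GSRP partially recovered")
    else:
        gsrp_state = "absent"

    if wlp_state in ("complete", "near_complete"):
        label = "acetogen_candidate"
    elif wlp_state == "methyl_only" and gsrp_state == "complete":
        label = "wlp_gcs_hybrid"
        evidence.append("methyl-branch WLP with complete GSRP (WLP-GCS hybrid)")
    else:
        label = "non_candidate"

    pnt = markers.get("pntAB")
    saob_support = pnt is not None and pnt.status == "full"
    if saob_support:
        evidence.append("pntAB transhydrogenase present (SAOB support)")

    activation = [st for st in wlp.statuses if st.branch == "activation"]
    if activation and all(st.status == "full" for st in activation):
        evidence.append("pta-ackA acetate activation couple present")

    return CandidateCall(
        genome_id=wlp.genome_id,
        wlp_state=wlp_state,
        gsrp_state=gsrp_state,
        label=label,
        saob_support=saob_support,
        evidence=evidence,
    )


def screen_unbinned(unbinned: AnnotatedGenome,
                    targets: Sequence[GeneIdentifier]
                    ) -> list[tuple[str, str]]:
    """Report every unbinned gene call matching any target identifier.

    Used to check whether carbonyl-branch (codh/acs) genes exist in the
    assembly but escaped binning.
    """
    if not unbinned.is_unbinned:
        raise ScreeningError(
            f"genome {unbinned.genome_id!r} is not the unbinned pseudo-genome"
        )
    hits: list[tuple[str, str]] = []
    for gene in unbinned.genes:
        for target in targets:
            matched = None
            if target.ko and gene.ko == target.ko:
                matched = target.ko
            elif gene.symbol and target.matches_symbol(gene.symbol):
                matched = gene.symbol
            elif target.ec and target.ec in gene.ec:
                matched = target.ec
            if matched is not None:
                hits.append((gene.gene_id, matched))
                break
    return hits


@dataclass
class ScreenReport:
    """Everything one screening run produces."""

    calls: list[CandidateCall]
    profiles: dict[str, dict[str, PathwayProfile]]  # genome -> pathway -> profile
    marker_statuses: dict[str, dict[str, EnzymeStatus]]
    tiers: dict[str, str]
    abundances: dict[str, float]  # genome -> fraction of sample reads
    matrix: str  # Figure-1-style presence matrix, TSV
    unbinned_hits: dict[str, list[tuple[str, str]]]
    warnings: list[str]
    provenance: dict


def catalog_hash(pathways: Sequence[PathwayDefinition],
                 markers: Sequence[EnzymeDefinition]) -> str:
    doc = {
        "pathways": [pathway_to_dict(p) for p in pathways],
        "markers": [enzyme_to_dict(m) for m in markers],
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_screen(genomes: Sequence[AnnotatedGenome],
               catalogs: tuple[Sequence[PathwayDefinition],
                               Sequence[EnzymeDefinition]] | None = None,
               quality: Sequence[QualityRecord] = (),
               counts: Sequence[CountRecord] = (),
               near_complete_max_missing: int = 1) -> ScreenReport:
    """Run the full screen over a cohort of annotated genomes.

    Genomes are processed in sorted id order; unbinned pseudo-genomes are
    screened for carbonyl-branch genes only.  A genome without a quality
    record gets tier ``unknown`` and a warning.
    """
    from .report import render_matrix

    if catalogs is None:
        pathways: list[PathwayDefinition] = [builtin_wlp(), builtin_gsrp()]
        markers: list[EnzymeDefinition] = builtin_markers()
    else:
        pathways = list(catalogs[0])
        markers = list(catalogs[1])
    by_name = {p.name: p for p in pathways}
    wlp_def = by_name.get("wood-ljungdahl") or pathways[0]
    gsrp_def = by_name.get("gsrp") or (pathways[1] if len(pathways) > 1 else None)

    warnings_log: list[str] = []
    quality_by_id = {q.genome_id: q for q in quality}
    abundances = {gid: rec.fraction
                  for gid, rec in relative_abundance(counts).items()} if counts else {}

    carbonyl_targets = [s for e in wlp_def.branch_enzymes("carbonyl")
                        for s in e.subunits]

    calls: list[CandidateCall] = []
    profiles: dict[str, dict[str, PathwayProfile]] = {}
    marker_statuses: dict[str, dict[str, EnzymeStatus]] = {}
    unbinned_hits: dict[str, list[tuple[str, str]]] = {}
    tiers: dict[str, str] = {}

    for genome in sorted(genomes, key=lambda g: g.genome_id):
        if genome.is_unbinned:
            unbinned_hits[genome.genome_id] = screen_unbinned(
                genome, carbonyl_targets)
            continue
        wlp_profile = profile_pathway(genome, wlp_def)
        genome_profiles = {wlp_def.name: wlp_profile}
        if gsrp_def is not None:
            gsrp_profile = profile_pathway(genome, gsrp_def)
            genome_profiles[gsrp_def.name] = gsrp_profile
        else:
            gsrp_profile = PathwayProfile(
                genome_id=genome.genome_id, pathway_name="gsrp", statuses=[],
                branch_completeness={}, n_missing_genes=0, gate_passed=True)
        idx = _GenomeIndex.build(genome)
        mstat = {m.name: score_enzyme(genome, m, idx) for m in markers}
        profiles[genome.genome_id] = genome_profiles
        marker_statuses[genome.genome_id] = mstat
        calls.append(classify_candidate(
            wlp_profile, gsrp_profile, mstat,
            near_complete_max_missing=near_complete_max_missing))
        qrec = quality_by_id.get(genome.genome_id)
        if qrec is None:
            tiers[genome.genome_id] = "unknown"
            warnings_log.append(
                f"no quality record for {genome.genome_id}; tier unknown")
        else:
            tiers[genome.genome_id] = quality_tier(
                qrec.completeness, qrec.contamination)

    flat_profiles = [p for gp in profiles.values() for p in gp.values()]
    matrix = render_matrix(flat_profiles)
    provenance = {
        "catalog_sha256": catalog_hash(pathways, markers),
        "near_complete_max_missing": near_complete_max_missing,
        "n_genomes": len(calls),
        "n_unbinned": len(unbinned_hits),
    }
    return ScreenReport(
        calls=calls,
        profiles=profiles,
        marker_statuses=marker_statuses,
        tiers=tiers,
        abundances=abundances,
        matrix=matrix,
        unbinned_hits=unbinned_hits,
        warnings=warnings_log,
        provenance=provenance,
    )
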