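"""Curated gene catalogs for the acetogen/SAOB genome screen.

The screen rests on three curated gene sets:

* the Wood–Ljungdahl pathway (WLP), split into a methyl branch
  (``fdhA``, ``fhs``, ``folD``, ``metF``), a carbonyl branch (the CODH/ACS
  complex with subunits ``acsA``/``cooS``, ``acsB``, ``acsC``, ``acsD``,
  ``acsE``) and the two-step acetate activation couple (``pta``, ``ackA``),
  gated on the key functional marker ``fhs``;
* the glycine synthase reductase pathway (GSRP), whose required genes are
  ``grd``, ``gcvPA``, ``gcvT`` and ``lpdA`` (``gcvPB`` and ``gcvH`` complete
  the four-protein glycine cleavage system and are catalogued but optional);
* discriminating marker complexes — the NAD(P) transhydrogenase ``pntAB``
  (present in known SAOB, absent from homoacetogens), the Rnf and Ech
  energy-conserving complexes, the potassium-regulation gene set
  (``trkA``, ``kefC``, ``kch``, ``msc``) and the F-type and V/A-type ATPases.

Gene symbols are matched case-insensitively.  Each symbol carries a KEGG
orthology (KO) accession and an EC number chosen from the standard KEGG
assignments; both are recorded in the serialized default catalog and can be
overridden through :func:`load_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import yaml

BRANCHES = ("methyl", "carbonyl", "activation", "gsrp", "marker")


class CatalogError(ValueError):
    """Raised when a catalog definition or override document is invalid."""


def _norm(symbol: str) -> str:
    return symbol.strip().lower()


@dataclass(frozen=True)
class GeneIdentifier:
    """One gene symbol with its synonyms and database accessions.

    ``optional`` marks subunits that are catalogued for completeness but do
    not enter full/partial/absent arithmetic (e.g. ``gcvH`` in the GSRP).
    """

    symbol: str
    synonyms: frozenset[str] = frozenset()
    ko: Optional[str] = None
    ec: Optional[str] = None
    optional: bool = False

    def __post_init__(self) -> None:
        if not self.symbol or not self.symbol.strip():
            raise CatalogError("gene symbol must be non-empty")
        syns = frozenset(_norm(s) for s in self.synonyms)
        if _norm(self.symbol) in syns:
            raise CatalogError(
                f"synonyms of {self.symbol!r} must not contain the primary symbol"
            )
        object.__setattr__(self, "synonyms", syns)

    @property
    def all_symbols(self) -> frozenset[str]:
        """Primary symbol plus synonyms, normalized."""
        return self.synonyms | {_norm(self.symbol)}

    def matches_symbol(self, symbol: str) -> bool:
        return _norm(symbol) in self.all_symbols


@dataclass(frozen=True)
class EnzymeDefinition:
    """An enzyme or complex: an ordered list of subunit gene identifiers."""

    name: str
    subunits: tuple[GeneIdentifier, ...]
    branch: str

    def __post_init__(self) -> None:
        if not self.subunits:
            raise CatalogError(f"enzyme {self.name!r} must have at least one subunit")
        if self.branch not in BRANCHES:
            raise CatalogError(
                f"enzyme {self.name!r}: branch {self.branch!r} not in {BRANCHES}"
            )
        object.__setattr__(self, "subunits", tuple(self.subunits))

    @property
    def required_subunits(self) -> tuple[GeneIdentifier, ...]:
        return tuple(s for s in self.subunits if not s.optional)

    @property
    def is_optional(self) -> bool:
        """True when every subunit is optional (enzyme never gates completeness)."""
        return not self.required_subunits


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway with an optional gate gene.

    When ``gate_gene`` is set (``fhs`` for the WLP), a genome that lacks any
    match for it is not screened further: the whole pathway is reported
    absent.
    """

    name: str
    enzymes: tuple[EnzymeDefinition, ...]
    gate_gene: Optional[GeneIdentifier] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        names = [e.name for e in self.enzymes]
        if len(set(names)) != len(names):
            raise CatalogError(f"pathway {self.name!r}: enzyme names must be unique")
        seen: dict[str, str] = {}
        for enz in self.enzymes:
            for sub in enz.required_subunits:
                for sym in sub.all_symbols:
                    if sym in seen and seen[sym] != enz.name:
                        raise CatalogError(
                            f"pathway {self.name!r}: required subunit {sym!r} shared "
                            f"by enzymes {seen[sym]!r} and {enz.name!r}"
                        )
                    seen[sym] = enz.name
        if self.gate_gene is not None:
            gate_syms = self.gate_gene.all_symbols
            if not any(
                gate_syms & sub.all_symbols
                for enz in self.enzymes
                for sub in enz.subunits
            ):
                raise CatalogError(
                    f"pathway {self.name!r}: gate gene {self.gate_gene.symbol!r} "
                    "does not appear among the enzyme subunits"
                )

    def branch_enzymes(self, branch: str) -> tuple[EnzymeDefinition, ...]:
        return tuple(e for e in self.enzymes if e.branch == branch)

    @property
    def gene_identifiers(self) -> tuple[GeneIdentifier, ...]:
        return tuple(s for e in self.enzymes for s in e.subunits)


def _g(symbol: str, ko: str | None = None, ec: str | None = None,
       synonyms: Iterable[str] = (), optional: bool = False) -> GeneIdentifier:
    return GeneIdentifier(symbol=symbol, synonyms=frozenset(synonyms),
                          ko=ko, ec=ec, optional=optional)


def _single(symbol: str, branch: str, ko: str | None = None,
            ec: str | None = None, optional: bool = False) -> EnzymeDefinition:
    return EnzymeDefinition(name=symbol,
                            subunits=(_g(symbol, ko, ec, optional=optional),),
                            branch=branch)


def builtin_wlp() -> PathwayDefinition:
    """The Wood–Ljungdahl pathway catalog.

    Eleven gene identifiers across three branches; ``fhs`` is the screening
    gate.  ``acsA`` and ``cooS`` are synonyms for the catalytic CO
    dehydrogenase subunit.  KO/EC accessions are the standard KEGG choices
    for the anaerobic (reductive acetyl-CoA) pathway.
    """
    codh_acs = EnzymeDefinition(
        name="CODH/ACS complex",
        subunits=(
            _g("acsA", ko="K00198", ec="1.2.7.4", synonyms=("cooS",)),
            _g("acsB", ko="K14138", ec="2.3.1.169"),
            _g("acsC", ko="K00197"),
            _g("acsD", ko="K00194"),
            _g("acsE", ko="K15023", ec="2.1.1.258"),
        ),
        branch="carbonyl",
    )
    return PathwayDefinition(
        name="wood-ljungdahl",
        enzymes=(
            _single("fdhA", "methyl", ko="K05299", ec="1.17.1.9"),
            _single("fhs", "methyl", ko="K01938", ec="6.3.4.3"),
            _single("folD", "methyl", ko="K01491", ec="1.5.1.5"),
            _single("metF", "methyl", ko="K00297", ec="1.5.1.20"),
            codh_acs,
            _single("pta", "activation", ko="K00625", ec="2.3.1.8"),
            _single("ackA", "activation", ko="K00925", ec="2.7.2.1"),
        ),
        gate_gene=_g("fhs", ko="K01938", ec="6.3.4.3"),
    )


def builtin_gsrp() -> PathwayDefinition:
    """The glycine synthase reductase pathway catalog.

    The required set is {grd, gcvPA, gcvT, lpdA}; gcvPB and gcvH are part of
    the four-protein glycine cleavage system and are catalogued but optional,
    so their absence never affects completeness.
    """
    return PathwayDefinition(
        name="gsrp",
        enzymes=(
            _single("grd", "gsrp", ko="K10670", ec="1.21.4.2"),
            _single("gcvPA", "gsrp", ko="K00282", ec="1.4.4.2"),
            _single("gcvPB", "gsrp", ko="K00283", ec="1.4.4.2", optional=True),
            _single("gcvT", "gsrp", ko="K00605", ec="2.1.2.10"),
            _single("gcvH", "gsrp", ko="K02437", optional=True),
            _single("lpdA", "gsrp", ko="K00382", ec="1.8.1.4"),
        ),
    )


def builtin_markers() -> list[EnzymeDefinition]:
    """Discriminating marker complexes outside the two pathways.

    ``pntAB`` is the SAOB-support marker: known syntrophic acetate oxidisers
    carry the NAD(P) transhydrogenase while homoacetogens lack it.  The
    potassium-regulation set (trkA, kefC, kch, msc) tracks ammonia-stress
    response; Rnf/Ech and the ATPases document energy conservation.
    """
    return [
        EnzymeDefinition(
            name="pntAB",
            subunits=(_g("pntA", ko="K00324", ec="1.6.1.2"),
                      _g("pntB", ko="K00325", ec="1.6.1.2")),
            branch="marker",
        ),
        EnzymeDefinition(
            name="Rnf complex",
            subunits=tuple(_g(f"rnf{c}") for c in "ABCDEG"),
            branch="marker",
        ),
        EnzymeDefinition(
            name="Ech hydrogenase",
            subunits=tuple(_g(f"ech{c}") for c in "ABCDEF"),
            branch="marker",
        ),
        EnzymeDefinition(
            name="potassium regulation",
            subunits=(_g("trkA"), _g("kefC"), _g("kch"), _g("msc")),
            branch="marker",
        ),
        EnzymeDefinition(
            name="F-type ATPase",
            subunits=tuple(_g(f"atp{c}") for c in "ABCDEFGH"),
            branch="marker",
        ),
        EnzymeDefinition(
            name="V/A-type ATPase",
            subunits=tuple(_g(f"ntp{c}") for c in "ABCDEFGIK"),
            branch="marker",
        ),
    ]


def builtin_methanogenesis() -> list[EnzymeDefinition]:
    """Optional methanogenesis marker modules (not used for classification).

    Covers methyl-coenzyme M reductase, the acetoclastic CO dehydrogenase /
    acetyl-CoA decarbonylase (cdhABCDE), methylamine methyltransferases and
    cofactor F420 biosynthesis.  Gene lists are implementer-curated.
    """
    return [
        EnzymeDefinition(
            name="MCR complex",
            subunits=(_g("mcrA", ko="K00399", ec="2.8.4.1"),
                      _g("mcrB", ko="K00401"), _g("mcrG", ko="K00402")),
            branch="marker",
        ),
        EnzymeDefinition(
            name="CDH complex (acetoclastic)",
            subunits=tuple(_g(f"cdh{c}") for c in "ABCDE"),
            branch="marker",
        ),
        EnzymeDefinition(
            name="methylamine methyltransferase",
            subunits=(_g("mtaA"), _g("mtaB"), _g("mtaC")),
            branch="marker",
        ),
        EnzymeDefinition(
            name="F420 biosynthesis",
            subunits=tuple(_g(f"cof{c}") for c in "CDEGH"),
            branch="marker",
        ),
    ]


# ---------------------------------------------------------------------------
# Serialization: a YAML document mirroring the dataclasses, plus a small
# gene_overrides section that patches accessions on the builtin catalogs.
# ---------------------------------------------------------------------------

_GENE_KEYS = {"symbol", "synonyms", "ko", "ec", "optional"}
_ENZYME_KEYS = {"name", "branch", "subunits"}
_PATHWAY_KEYS = {"name", "gate_gene", "enzymes"}
_TOP_KEYS = {"pathways", "markers", "gene_overrides"}


def gene_to_dict(g: GeneIdentifier) -> dict:
    d: dict = {"symbol": g.symbol}
    if g.synonyms:
        d["synonyms"] = sorted(g.synonyms)
    if g.ko:
        d["ko"] = g.ko
    if g.ec:
        d["ec"] = g.ec
    if g.optional:
        d["optional"] = True
    return d


def enzyme_to_dict(e: EnzymeDefinition) -> dict:
    return {
        "name": e.name,
        "branch": e.branch,
        "subunits": [gene_to_dict(s) for s in e.subunits],
    }


def pathway_to_dict(p: PathwayDefinition) -> dict:
    d: dict = {"name": p.name, "enzymes": [enzyme_to_dict(e) for e in p.enzymes]}
    if p.gate_gene is not None:
        d["gate_gene"] = gene_to_dict(p.gate_gene)
    return d


def serialize_catalog(pathways: Sequence[PathwayDefinition],
                      markers: Sequence[EnzymeDefinition]) -> str:
    """Render pathways + markers as the catalog YAML document."""
    doc = {
        "pathways": [pathway_to_dict(p) for p in pathways],
        "markers": [enzyme_to_dict(m) for m in markers],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _gene_from_dict(d: Mapping, path: str) -> GeneIdentifier:
    if not isinstance(d, Mapping):
        raise CatalogError(f"{path}: expected a mapping, got {type(d).__name__}")
    unknown = set(d) - _GENE_KEYS
    if unknown:
        raise CatalogError(f"{path}: unknown keys {sorted(unknown)}")
    if "symbol" not in d:
        raise CatalogError(f"{path}: missing 'symbol'")
    return GeneIdentifier(
        symbol=str(d["symbol"]),
        synonyms=frozenset(str(s) for s in d.get("synonyms", ())),
        ko=d.get("ko"),
        ec=str(d["ec"]) if d.get("ec") is not None else None,
        optional=bool(d.get("optional", False)),
    )


def _enzyme_from_dict(d: Mapping, path: str) -> EnzymeDefinition:
    if not isinstance(d, Mapping):
        raise CatalogError(f"{path}: expected a mapping, got {type(d).__name__}")
    unknown = set(d) - _ENZYME_KEYS
    if unknown:
        raise CatalogError(f"{path}: unknown keys {sorted(unknown)}")
    for key in ("name", "branch"):
        if key not in d:
            raise CatalogError(f"{path}: missing {key!r}")
    subs = d.get("subunits")
    if not subs:
        raise CatalogError(f"{path}: enzyme {d['name']!r} has no subunits")
    try:
        return EnzymeDefinition(
            name=str(d["name"]),
            subunits=tuple(_gene_from_dict(s, f"{path}.subunits[{i}]")
                           for i, s in enumerate(subs)),
            branch=str(d["branch"]),
        )
    except CatalogError:
        raise
    except (TypeError, ValueError) as exc:
        raise CatalogError(f"{path}: {exc}") from exc


def _pathway_from_dict(d: Mapping, path: str) -> PathwayDefinition:
    if not isinstance(d, Mapping):
        raise CatalogError(f"{path}: expected a mapping, got {type(d).__name__}")
    unknown = set(d) - _PATHWAY_KEYS
    if unknown:
        raise CatalogError(f"{path}: unknown keys {sorted(unknown)}")
    if "name" not in d:
        raise CatalogError(f"{path}: missing 'name'")
    enzymes = d.get("enzymes")
    if not enzymes:
        raise CatalogError(f"{path}: pathway {d['name']!r} has no enzymes")
    gate = d.get("gate_gene")
    return PathwayDefinition(
        name=str(d["name"]),
        enzymes=tuple(_enzyme_from_dict(e, f"{path}.enzymes[{i}]")
                      for i, e in enumerate(enzymes)),
        gate_gene=_gene_from_dict(gate, f"{path}.gate_gene") if gate else None,
    )


def _apply_gene_overrides(pathways: list[PathwayDefinition],
                          markers: list[EnzymeDefinition],
                          overrides: Mapping, path: str
                          ) -> tuple[list[PathwayDefinition], list[EnzymeDefinition]]:
    if not isinstance(overrides, Mapping):
        raise CatalogError(f"{path}: expected a mapping of symbol -> fields")
    allowed = {"ko", "ec", "synonyms"}
    norm_over = {}
    for sym, fields in overrides.items():
        if not isinstance(fields, Mapping):
            raise CatalogError(f"{path}.{sym}: expected a mapping of fields")
        unknown = set(fields) - allowed
        if unknown:
            raise CatalogError(f"{path}.{sym}: unknown keys {sorted(unknown)}")
        norm_over[_norm(str(sym))] = fields

    def patch(g: GeneIdentifier) -> GeneIdentifier:
        fields = norm_over.get(_norm(g.symbol))
        if fields is None:
            return g
        kwargs: dict = {}
        if "ko" in fields:
            kwargs["ko"] = fields["ko"]
        if "ec" in fields:
            kwargs["ec"] = str(fields["ec"]) if fields["ec"] is not None else None
        if "synonyms" in fields:
            kwargs["synonyms"] = frozenset(str(s) for s in fields["synonyms"])
        return replace(g, **kwargs)

    def patch_enzyme(e: EnzymeDefinition) -> EnzymeDefinition:
        return replace(e, subunits=tuple(patch(s) for s in e.subunits))

    new_pathways = [
        PathwayDefinition(
            name=p.name,
            enzymes=tuple(patch_enzyme(e) for e in p.enzymes),
            gate_gene=patch(p.gate_gene) if p.gate_gene else None,
        )
        for p in pathways
    ]
    return new_pathways, [patch_enzyme(m) for m in markers]


def load_catalog(config_text: str | None
                 ) -> tuple[list[PathwayDefinition], list[EnzymeDefinition]]:
    """Parse a catalog YAML document into (pathways, markers).

    An empty document yields the builtin catalogs.  A document may replace
    ``pathways`` and/or ``markers`` wholesale, or patch accessions on the
    builtins through ``gene_overrides: {symbol: {ko|ec|synonyms: ...}}``.
    Unknown keys anywhere are rejected with the offending path named.
    """
    pathways = [builtin_wlp(), builtin_gsrp()]
    markers = builtin_markers()
    if config_text is None or not config_text.strip():
        return pathways, markers
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise CatalogError(f"catalog document is not valid YAML: {exc}") from exc
    if doc is None:
        return pathways, markers
    if not isinstance(doc, Mapping):
        raise CatalogError("catalog document must be a mapping at the top level")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise CatalogError(f"top level: unknown keys {sorted(unknown)}")
    if "pathways" in doc:
        pw = doc["pathways"]
        if not isinstance(pw, Sequence) or isinstance(pw, str):
            raise CatalogError("pathways: expected a list")
        pathways = [_pathway_from_dict(p, f"pathways[{i}]") for i, p in enumerate(pw)]
    if "markers" in doc:
        mk = doc["markers"]
        if not isinstance(mk, Sequence) or isinstance(mk, str):
            raise CatalogError("markers: expected a list")
        markers = [_enzyme_from_dict(m, f"markers[{i}]") for i, m in enumerate(mk)]
    if "gene_overrides" in doc:
        pathways, markers = _apply_gene_overrides(
            pathways, markers, doc["gene_overrides"], "gene_overrides")
    return pathways, markers
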