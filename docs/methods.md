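# Methods

## Scope and model

`syntroscreen` implements a presence/absence screen over curated gene
catalogs. It makes no claim about pathway direction: the Wood–Ljungdahl
pathway (WLP) is reversible, and a genome carrying it may be an acetogen
(reductive use) or a syntrophic acetate oxidiser (oxidative use). The
screen therefore reports *candidates* with evidence — pathway states,
marker hits — rather than physiology. Copy number is ignored (multiple
calls of a gene count once), and free-text product descriptions are never
used for matching; a subunit counts as present only on a KO accession,
gene symbol/synonym, or EC number match (reporting precedence
KO > symbol > EC, KO assignments being the least ambiguous).

## Catalogs

The builtin WLP catalog has 11 gene identifiers in three branches —
methyl (*fdhA*, *fhs*, *folD*, *metF*), carbonyl (the CODH/ACS complex:
*acsA*/*cooS* as synonyms, *acsB*–*acsE*) and activation (*pta*, *ackA*)
— gated on *fhs*. The activation couple is catalogued and reported as
evidence but excluded from the completeness arithmetic, since acetate
activation is an adjunct to the pathway proper. The GSRP catalog requires
*grd*, *gcvPA*, *gcvT* and *lpdA*; *gcvPB* and *gcvH* complete the
four-protein glycine cleavage system and are included as optional, never
affecting completeness. Marker catalogs cover *pntAB* (the SAOB-support
discriminator), Rnf, Ech, the potassium-regulation set
(*trkA*, *kefC*, *kch*, *msc*) and the F-type and V/A-type ATPases; an
optional methanogenesis catalog (MCR, acetoclastic cdhABCDE, methylamine
methyltransferases, F420 biosynthesis) ships through the same mechanism
but never enters classification.

KO and EC accessions behind each symbol are curated choices from the
standard KEGG orthology; they are serialized into the default catalog
YAML and overridable per gene (`gene_overrides`), so a user who prefers
different accessions — or an entirely different gene set — can supply
them without code changes. Reports embed the SHA-256 of the effective
catalog.

## Classification rules

With `m` the number of required methyl+carbonyl subunits absent:

| wlp_state | condition |
| --- | --- |
| absent | *fhs* gate failed, or no core gene present |
| complete | m = 0 |
| near_complete | 1 ≤ m ≤ `near_complete_max_missing` and carbonyl branch not entirely absent |
| methyl_only | some methyl gene full, carbonyl branch entirely absent |
| partial | anything else with ≥ 1 core gene present |

`near_complete_max_missing` defaults to 1 ("missing only one gene") and
is exposed as a flag because "nearly complete" is a soft notion in
practice; raising it trades sensitivity for specificity on fragmented
bins. Labels: `acetogen_candidate` for complete/near-complete WLP;
`wlp_gcs_hybrid` for methyl-only WLP with complete GSRP;
`non_candidate` otherwise. SAOB support (full *pntAB*) is orthogonal to
the label: the hybrid and WLP-carrying patterns are *candidate* SAOB
when it is present. Genomes and enzymes are always processed in
lexicographic/catalog order, so outputs are byte-stable.

## Quality, abundance, assembly statistics

The published high/medium/low bin-quality cut-offs do not cover the whole
(completeness, contamination) plane (e.g. 80 % complete / 5 % contaminated
matches neither the literal "medium" nor "low" definition). The tier
function totalizes them — high iff completeness ≥ 90 and contamination
≤ 10; else medium iff completeness ≥ 70; else low — preserving the
printed rules wherever they apply; a property test sweeps a dense grid
for totality and monotonicity.

Relative abundance is mapped reads over the sample total (single reads,
full-sample denominator; the unbinned remainder closes the sum to 1
within 1e-12). GC% is 100·(G+C)/(A+C+G+T): ambiguity codes are excluded
from numerator and denominator (total length still counts them); a
`gc_denominator="all"` flag switches to the full-length denominator since
upstream tools differ on the convention. Percentages are rounded half-up
to two decimals. N50 is the standard largest-contig-first cumulative
definition.

## ANI estimation and delineation

ANI uses bottom-s MinHash over canonical k-mers (minimum of the 2-bit
encodings of a k-mer and its reverse complement; k-mers containing
non-ACGT bases are skipped). Hashing is the splitmix64 finalizer applied
to the packed k-mer XORed with a seeded mixing constant — deterministic
per (k, seed), with k = 21, s = 10000, seed = 42 by default. The Jaccard
is estimated over the merged sketch (the s smallest union hashes), the
Mash distance is `D = -(1/k)·ln(2j/(1+j))`, and ANI = 100·(1−D) clipped
to [0, 100]; disjoint sketches yield an undefined ANI flagged as such.
At these defaults, 1 Mb pairs across divergences 0.002–0.05 estimate ANI
within ±0.5 points of 100·(1−d), and the sketch Jaccard stays within
±0.02 of the exact k-mer Jaccard (both verified against a brute-force
string-based oracle in the test suite).

Delineation: same species iff ANI ≥ 95 % (inclusive — the conventional
"95 % ANI" phrasing does not fix the boundary, so the inclusive reading
is documented here) or a user-supplied dDDH ≥ 70 %; dDDH is accepted as
external input only, never computed. ANI < 74 % adds a new-genus
*advisory* — genus assignment requires phylogenetic placement, which is
out of scope. Below ~85 % identity the sketch estimator diverges from
alignment-based ANI, so such values carry a "below reliable range" note
and should be read qualitatively.

## Synthetic data

The generator emulates the statistical structure of reactor bins, not
their sequences. Six guild archetypes (true acetogen, WLP-carrying SAOB,
WLP–GCS hybrid, fermenter, hydrogenotrophic and acetoclastic methanogen)
are gene complements drawn from the catalogs; each is verified against
the classifier at build time, so ground truth and rule table cannot
drift apart. Each genome adds 200 housekeeping genes sampled from a
500-symbol background pool — large enough that dropout hits pathway and
background genes at realistic relative rates. Dropout removes each gene
independently with probability p (an incomplete bin); contamination
injects a Binomial(n, rate) draw of genes from the other guilds.
Realized rates are written into the quality records
(completeness = 100·(1 − realized dropout)). Read counts are one
multinomial draw over Dirichlet-distributed genome proportions scaled to
a 0.6 binned fraction (mid-range for short-read binning of such
communities), default 10⁶ reads per sample; the remainder is the
unbinned pseudo-genome. Every draw flows from one
`numpy.random.default_rng(seed)` and a cohort regenerates byte-for-byte
from its manifest.

What passing tests on these cohorts shows: the screening logic is exact
with respect to its rules and degrades monotonically under missingness.
What it does not show: robustness to annotation noise (wrong symbols,
chimeric contigs, diverged orthologs below annotation sensitivity),
which real bins have and the generator deliberately does not model.

## Problem sizes and numerical choices

The test suite enumerates all 4096 subsets of a reduced 12-gene catalog
against an independently written rule oracle; label-recovery runs use
204 genomes (34 per guild) at dropout 0–0.2; ANI validation uses 1 Mb
pairs, with exact-Jaccard oracle comparisons on 1 Mb and 200 kb
sequences. These sizes make the full suite and the acceptance script
each complete in well under a minute while keeping sampling error far
from every decision boundary (at s = 10⁴ the Jaccard standard error is
~0.005, i.e. ~0.1 ANI point at 5 % divergence).

## Known limitations

* Presence/absence only — no copy number, synteny, operon structure or
  expression; direction of pathway use is undecidable from gene content.
* Symbol/KO/EC matching inherits the upstream annotator's vocabulary;
  diverged genes the annotator missed are invisible to the screen.
* The Mash ANI substitutes for alignment-based ANI; below ~85 % identity
  it is advisory only, and dDDH must come from an external tool.
* CheckM-style completeness/contamination are trusted inputs; the package
  does not recompute them.
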