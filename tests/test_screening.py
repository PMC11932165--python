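"""Enzyme scoring, pathway profiling, candidate classification and the
full-screen driver."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GSRP_REQUIRED, WLP_ALL, WLP_CORE, genome_from_symbols
from syntroscreen.catalog import builtin_gsrp, builtin_markers, builtin_wlp
from syntroscreen.io import GeneAnnotation, AnnotatedGenome
from syntroscreen.screening import (
    ScreeningError,
    classify_candidate,
    profile_pathway,
    run_screen,
    score_enzyme,
    screen_unbinned,
)

WLP = builtin_wlp()
GSRP = builtin_gsrp()
CODH_ACS = WLP.branch_enzymes("carbonyl")[0]
MARKERS = builtin_markers()


def _markers_for(genome):
    return {m.name: score_enzyme(genome, m) for m in MARKERS}


def _call(symbols, near_complete_max_missing=1):
    genome = genome_from_symbols("g", symbols)
    return classify_candidate(
        profile_pathway(genome, WLP),
        profile_pathway(genome, GSRP),
        _markers_for(genome),
        near_complete_max_missing=near_complete_max_missing,
    )


class TestScoreEnzyme:
    @pytest.mark.parametrize("symbols,status,missing", [
        (["acsA", "acsB", "acsC", "acsD", "acsE"], "full", set()),
        (["acsB", "acsC"], "partial", {"acsA", "acsD", "acsE"}),
        (["fhs", "pta"], "absent", {"acsA", "acsB", "acsC", "acsD", "acsE"}),
        (["cooS", "acsB", "acsC", "acsD", "acsE"], "full", set()),  # synonym
    ])
    def test_codh_acs_recovery(self, symbols, status, missing):
        genome = genome_from_symbols("g", symbols)
        result = score_enzyme(genome, CODH_ACS)
        assert result.status == status
        assert result.missing_subunits == missing

    def test_match_by_ko_and_ec(self):
        by_ko = AnnotatedGenome("g", [
            GeneAnnotation("g", "g_1", ko="K01938")])
        by_ec = AnnotatedGenome("g", [
            GeneAnnotation("g", "g_2", ec=("6.3.4.3",), product="ligase")])
        fhs_enzyme = next(e for e in WLP.enzymes if e.name == "fhs")
        assert score_enzyme(by_ko, fhs_enzyme).status == "full"
        assert score_enzyme(by_ec, fhs_enzyme).status == "full"

    def test_multiple_copies_count_once(self):
        genome = genome_from_symbols("g", ["acsB"] * 4)
        result = score_enzyme(genome, CODH_ACS)
        assert result.status == "partial"
        assert result.present_subunits == {"acsB"}

    def test_optional_subunits_do_not_affect_status(self):
        gcvh = next(e for e in GSRP.enzymes if e.name == "gcvH")
        genome = genome_from_symbols("g", ["grd"])
        assert score_enzyme(genome, gcvh).status == "absent"
        # absence of gcvH leaves every required GSRP enzyme untouched
        full = genome_from_symbols("g", GSRP_REQUIRED)
        prof = profile_pathway(full, GSRP)
        assert all(prof.status_of(n).status == "full" for n in GSRP_REQUIRED)


class TestProfilePathway:
    def test_gate_only_genome(self):
        prof = profile_pathway(genome_from_symbols("g", ["fhs"]), WLP)
        assert prof.gate_passed
        assert prof.status_of("fhs").status == "full"
        assert prof.branch_completeness["methyl"] == 0.25
        assert prof.status_of("CODH/ACS complex").status == "absent"

    def test_gate_failure_blanks_profile(self):
        prof = profile_pathway(genome_from_symbols("g", ["acsB"]), WLP)
        assert not prof.gate_passed
        assert all(st.status == "absent" for st in prof.statuses)
        assert prof.n_missing_genes == len(WLP_CORE)

    def test_complete_genome(self, complete_wlp_genome):
        prof = profile_pathway(complete_wlp_genome, WLP)
        assert all(st.status == "full" for st in prof.statuses)
        assert set(prof.branch_completeness.values()) == {1.0}
        assert prof.n_missing_genes == 0

    def test_activation_branch_outside_core_missing_count(self):
        prof = profile_pathway(genome_from_symbols("g", WLP_CORE), WLP)
        assert prof.n_missing_genes == 0  # pta/ackA absent but not core
        assert prof.branch_completeness["activation"] == 0.0


class TestClassifyCandidate:
    def test_schinkii_pattern_near_complete_with_pntab(self):
        symbols = [s for s in WLP_ALL if s != "fdhA"] + ["grd", "pntA", "pntB"]
        call = _call(symbols)
        assert call.wlp_state == "near_complete"
        assert call.label == "acetogen_candidate"
        assert call.saob_support is True
        assert call.gsrp_state == "partial"

    def test_acetovorans_pattern_hybrid(self):
        symbols = (["fhs", "fdhA", "folD", "pta", "ackA"]
                   + ["grd", "gcvPA", "gcvPB", "gcvT", "gcvH", "lpdA"]
                   + ["pntA", "pntB"])
        call = _call(symbols)
        assert call.wlp_state == "methyl_only"
        assert call.gsrp_state == "complete"
        assert call.label == "wlp_gcs_hybrid"
        assert call.saob_support is True

    def test_gate_failure_forces_non_candidate(self):
        symbols = [s for s in WLP_ALL if s != "fhs"] + GSRP_REQUIRED
        call = _call(symbols)
        assert call.wlp_state == "absent"
        assert call.label == "non_candidate"

    def test_homoacetogen_pattern_no_saob_support(self):
        call = _call(WLP_ALL)
        assert call.wlp_state == "complete"
        assert call.label == "acetogen_candidate"
        assert call.saob_support is False

    def test_near_complete_threshold_is_configurable(self):
        symbols = [s for s in WLP_ALL if s not in ("fdhA", "metF")]
        assert _call(symbols).wlp_state == "partial"
        assert _call(symbols, near_complete_max_missing=2).wlp_state == (
            "near_complete")

    def test_mismatched_genomes_rejected(self):
        a = profile_pathway(genome_from_symbols("a", ["fhs"]), WLP)
        b = profile_pathway(genome_from_symbols("b", ["grd"]), GSRP)
        with pytest.raises(ScreeningError, match="genome ids differ"):
            classify_candidate(a, b)


class TestScreenUnbinned:
    TARGETS = [s for s in CODH_ACS.subunits]

    def test_hit_reported(self):
        unbinned = genome_from_symbols("UNBINNED:S1", ["acsB", "hyp_0001"])
        hits = screen_unbinned(unbinned, self.TARGETS)
        assert len(hits) == 1
        assert hits[0][1] == "acsb"

    def test_empty_and_miss(self):
        assert screen_unbinned(
            genome_from_symbols("UNBINNED:S1", []), self.TARGETS) == []
        assert screen_unbinned(
            genome_from_symbols("UNBINNED:S1", ["fhs"]), self.TARGETS) == []

    def test_rejects_binned_genome(self):
        with pytest.raises(ScreeningError, match="not the unbinned"):
            screen_unbinned(genome_from_symbols("R1.8", ["acsB"]),
                            self.TARGETS)


class TestRunScreen:
    def test_empty_cohort(self):
        report = run_screen([])
        assert report.calls == []
        assert report.matrix.startswith("genome_id")

    def test_no_fhs_cohort_all_non_candidates(self):
        genomes = [genome_from_symbols(f"g{i}", ["acsB", "pta", "grd"])
                   for i in range(3)]
        report = run_screen(genomes)
        assert all(c.label == "non_candidate" for c in report.calls)

    def test_missing_quality_yields_unknown_tier_and_warning(self):
        report = run_screen([genome_from_symbols("g1", ["fhs"])])
        assert report.tiers["g1"] == "unknown"
        assert any("g1" in w for w in report.warnings)

    def test_genomes_processed_in_sorted_order(self):
        genomes = [genome_from_symbols(g, ["fhs"]) for g in ("b", "a", "c")]
        report = run_screen(genomes)
        assert [c.genome_id for c in report.calls] == ["a", "b", "c"]

    def test_unbinned_screened_for_carbonyl_targets_only(self):
        genomes = [
            genome_from_symbols("g1", WLP_ALL),
            genome_from_symbols("UNBINNED:S1", ["acsB", "fhs"]),
        ]
        report = run_screen(genomes)
        assert [c.genome_id for c in report.calls] == ["g1"]
        assert [h[1] for h in report.unbinned_hits["UNBINNED:S1"]] == ["acsb"]


ALL_SYMBOLS = sorted(set(WLP_ALL) | set(GSRP_REQUIRED) | {"gcvPB", "gcvH"})


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    base=st.sets(st.sampled_from(ALL_SYMBOLS)),
    extra=st.sets(st.sampled_from(ALL_SYMBOLS), min_size=1),
)
def test_adding_genes_is_monotone(base, extra):
    """Adding annotations can only move statuses toward full and never
    demotes the WLP state toward absent."""
    order = {"absent": 0, "partial": 1, "full": 2}
    wlp_order = {"absent": 0, "partial": 1, "methyl_only": 1,
                 "near_complete": 2, "complete": 3}
    before = genome_from_symbols("g", sorted(base))
    after = genome_from_symbols("g", sorted(base | extra))
    prof_before = profile_pathway(before, WLP)
    prof_after = profile_pathway(after, WLP)
    for st_b, st_a in zip(prof_before.statuses, prof_after.statuses):
        assert order[st_a.status] >= order[st_b.status]
    call_b = classify_candidate(prof_before,
                                profile_pathway(before, GSRP), {})
    call_a = classify_candidate(prof_after,
                                profile_pathway(after, GSRP), {})
    assert wlp_order[call_a.wlp_state] >= wlp_order[call_b.wlp_state]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(genes=st.sets(st.sampled_from(
    [s for s in ALL_SYMBOLS if s != "fhs"] + ["hyp_0001", "hyp_0002"])))
def test_gate_soundness_without_fhs(genes):
    """Any genome without an fhs match is a non-candidate."""
    call = _call(sorted(genes))
    assert call.label == "non_candidate"
    assert call.wlp_state == "absent"
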