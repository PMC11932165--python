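"""The synthetic-cohort generator: ground truth, dropout limits, determinism."""

import math

import numpy as np
import pytest

from syntroscreen.io import UNBINNED_PREFIX
from syntroscreen.screening import run_screen
from syntroscreen.simulate import (
    GUILDS,
    SimulationError,
    build_archetypes,
    generate_cohort,
    generate_counts,
    mutate_genome,
    read_manifest,
    regenerate_cohort,
    write_cohort,
)


def _agreement(cohort):
    report = run_screen(cohort.genomes, quality=cohort.quality)
    return np.mean([c.label == cohort.truth_labels[c.genome_id]
                    for c in report.calls])


class TestArchetypes:
    def test_six_guilds_with_consistent_labels(self):
        archetypes = build_archetypes()
        assert set(archetypes) == set(GUILDS)
        # consistency with the classifier is asserted inside build_archetypes;
        # spot-check the headline patterns here
        assert archetypes["true_acetogen"].expected_label == "acetogen_candidate"
        assert not archetypes["true_acetogen"].expected_saob_support
        assert archetypes["wlp_gcs_hybrid"].expected_label == "wlp_gcs_hybrid"
        assert archetypes["saob_wlp"].expected_saob_support

    def test_one_genome_per_guild_recovers_labels(self):
        cohort = generate_cohort(n_per_guild=1, dropout_p=0.0,
                                 contamination_rate=0.0, seed=7)
        assert len(cohort.genomes) == 6
        assert _agreement(cohort) == 1.0


class TestGenerateCohort:
    def test_full_dropout_empties_all_genomes(self):
        cohort = generate_cohort(n_per_guild=2, dropout_p=1.0, seed=3)
        assert all(not g.genes for g in cohort.genomes)
        report = run_screen(cohort.genomes, quality=cohort.quality)
        assert all(c.label == "non_candidate" for c in report.calls)
        assert all(q.completeness == 0.0 for q in cohort.quality)

    def test_determinism_and_manifest_regeneration(self):
        a = generate_cohort(n_per_guild=3, dropout_p=0.1,
                            contamination_rate=0.05, seed=11)
        b = regenerate_cohort(a.manifest)
        assert [g.genome_id for g in a.genomes] == [g.genome_id for g in b.genomes]
        assert all(x.genes == y.genes for x, y in zip(a.genomes, b.genomes))
        assert a.quality == b.quality
        assert a.counts == b.counts

    def test_completeness_tracks_realized_dropout(self):
        cohort = generate_cohort(n_per_guild=2, dropout_p=0.3, seed=5)
        by_id = {g.genome_id: g for g in cohort.genomes}
        for q in cohort.quality:
            genome = by_id[q.genome_id]
            # at contamination 0 every kept gene is original
            n_original = round(len(genome.genes) / (q.completeness / 100)) \
                if q.completeness else None
            if n_original is not None:
                assert math.isclose(
                    100.0 * len(genome.genes) / n_original, q.completeness,
                    abs_tol=1e-9)

    def test_contamination_injects_foreign_genes(self):
        clean = generate_cohort(n_per_guild=2, seed=9)
        dirty = generate_cohort(n_per_guild=2, contamination_rate=0.2, seed=9)
        assert sum(q.contamination for q in dirty.quality) > 0
        assert all(q.contamination == 0 for q in clean.quality)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(SimulationError):
            generate_cohort(1, dropout_p=1.5)
        with pytest.raises(SimulationError):
            generate_cohort(1, contamination_rate=-0.1)

    def test_write_cohort_round_trips_manifest(self, tmp_path):
        cohort = generate_cohort(n_per_guild=1, seed=13)
        paths = write_cohort(cohort, tmp_path / "cohort")
        manifest = read_manifest(paths["manifest"])
        again = regenerate_cohort(manifest)
        assert [g.genome_id for g in again.genomes] == [
            g.genome_id for g in cohort.genomes]
        assert paths["genes"].read_text().startswith("genome_id\tsymbol\tko")


class TestMutateGenome:
    def test_rate_zero_identity(self):
        pair = mutate_genome(10_000, 0.0, seed=1)
        assert pair.sequence == pair.mutated
        assert pair.realized_divergence == 0.0

    def test_realized_divergence_near_nominal(self):
        n, rate = 1_000_000, 0.02
        pair = mutate_genome(n, rate, seed=1)
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(pair.realized_divergence - rate) <= 3 * se
        # every flagged site really differs
        diffs = sum(a != b for a, b in zip(pair.sequence[:5000],
                                           pair.mutated[:5000]))
        assert diffs > 0

    def test_deterministic(self):
        assert mutate_genome(5000, 0.05, seed=2) == mutate_genome(
            5000, 0.05, seed=2)

    def test_invalid_rate_rejected(self):
        with pytest.raises(SimulationError):
            mutate_genome(100, 0.5)


class TestGenerateCounts:
    def test_single_genome_gets_all_reads(self):
        records = generate_counts({"g1": 1.0}, 10_000, seed=1)
        by_id = {r.genome_id: r for r in records}
        assert by_id["g1"].mapped_reads == 10_000
        assert by_id[f"{UNBINNED_PREFIX}S1"].mapped_reads == 0

    def test_unbinned_receives_remainder(self):
        total = 1_000_000
        records = generate_counts({"g1": 0.35, "g2": 0.25}, total, seed=2)
        unbinned = next(r for r in records if r.genome_id.startswith(
            UNBINNED_PREFIX))
        p = 0.4
        se = math.sqrt(p * (1 - p) / total)
        assert abs(unbinned.mapped_reads / total - p) <= 3 * se
        assert sum(r.mapped_reads for r in records) == total

    def test_overcommitted_proportions_rejected(self):
        with pytest.raises(SimulationError, match="> 1"):
            generate_counts({"g1": 0.7, "g2": 0.6}, 1000)

    def test_fixed_seed_reproducible(self):
        assert generate_counts({"a": 0.3, "b": 0.3}, 1000, seed=9) == \
            generate_counts({"a": 0.3, "b": 0.3}, 1000, seed=9)
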