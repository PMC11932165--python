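"""MinHash sketching, Mash ANI and taxon delineation.

The independent oracle for the sketch estimator is an exact canonical
k-mer Jaccard computed by brute force from the sequences themselves.
"""

import math

import numpy as np
import pytest

from syntroscreen.ani import (
    AniError,
    Thresholds,
    delineate,
    load_sketch,
    mash_ani,
    save_sketch,
    sketch,
)
from syntroscreen.simulate import mutate_genome

_RC = str.maketrans("ACGT", "TGCA")


def exact_canonical_jaccard(seq_a: str, seq_b: str, k: int = 21) -> float:
    """Brute-force Jaccard over all canonical k-mers (strings, no hashing)."""
    def kmers(seq):
        rc = seq.translate(_RC)[::-1]
        n = len(seq)
        out = set()
        for i in range(n - k + 1):
            fwd = seq[i:i + k]
            rev = rc[n - i - k:n - i]
            out.add(fwd if fwd <= rev else rev)
        return out
    a, b = kmers(seq_a), kmers(seq_b)
    return len(a & b) / len(a | b)


class TestSketch:
    def test_reverse_complement_gives_identical_sketch(self):
        seq = mutate_genome(5000, 0.0, seed=5).sequence
        rc = seq.translate(_RC)[::-1]
        a = sketch([("f", seq)])
        b = sketch([("r", rc)])
        assert np.array_equal(a.hashes, b.hashes)

    def test_small_genome_keeps_all_kmers(self):
        seq = mutate_genome(200, 0.0, seed=1).sequence
        sk = sketch([("c", seq)], s=10000)
        n_distinct = len({min(seq[i:i + 21],
                              seq.translate(_RC)[::-1][200 - i - 21:200 - i])
                          for i in range(180)})
        assert sk.hashes.size == n_distinct

    def test_deterministic_per_seed(self):
        seq = mutate_genome(3000, 0.0, seed=2).sequence
        assert np.array_equal(sketch([("c", seq)], seed=42).hashes,
                              sketch([("c", seq)], seed=42).hashes)
        assert not np.array_equal(sketch([("c", seq)], seed=42).hashes,
                                  sketch([("c", seq)], seed=43).hashes)

    def test_ambiguous_kmers_skipped(self):
        seq = mutate_genome(1000, 0.0, seed=3).sequence
        with_n = seq[:400] + "N" + seq[401:]
        sk_clean = sketch([("c", seq)])
        sk_n = sketch([("c", with_n)])
        # the N removes at most k k-mers, everything else is shared
        assert len(np.intersect1d(sk_clean.hashes, sk_n.hashes)) >= (
            sk_clean.hashes.size - 21)

    def test_too_short_input_rejected(self):
        with pytest.raises(AniError, match="shorter than k"):
            sketch([("c", "ACGT")])

    def test_save_load_round_trip(self, tmp_path):
        sk = sketch([("c", mutate_genome(2000, 0.0, seed=4).sequence)],
                    genome_id="g")
        path = tmp_path / "g.sketch.json"
        save_sketch(sk, path)
        back = load_sketch(path)
        assert back.genome_id == "g"
        assert back.k == sk.k and back.genome_length == sk.genome_length
        assert np.array_equal(back.hashes, sk.hashes)


class TestMashAni:
    def test_identical_sketches(self):
        sk = sketch([("c", mutate_genome(50_000, 0.0, seed=6).sequence)])
        result = mash_ani(sk, sk)
        assert result.jaccard == 1.0
        assert result.mash_distance == 0.0
        assert result.ani_percent == 100.0

    def test_disjoint_sketches_undefined(self):
        a = sketch([("a", mutate_genome(5000, 0.0, seed=7).sequence)])
        b = sketch([("b", mutate_genome(5000, 0.0, seed=8).sequence)], s=10000)
        result = mash_ani(a, b)
        # unrelated random genomes share essentially nothing
        if result.shared_hashes == 0:
            assert result.undefined
            assert math.isinf(result.mash_distance)
        else:
            assert result.ani_percent < 85

    def test_symmetry(self):
        pair = mutate_genome(100_000, 0.01, seed=9)
        a = sketch([("a", pair.sequence)], genome_id="a")
        b = sketch([("b", pair.mutated)], genome_id="b")
        ab, ba = mash_ani(a, b), mash_ani(b, a)
        assert ab.jaccard == ba.jaccard
        assert ab.mash_distance == ba.mash_distance

    def test_mismatched_k_rejected(self):
        seq = mutate_genome(5000, 0.0, seed=10).sequence
        with pytest.raises(AniError, match="k mismatch"):
            mash_ani(sketch([("c", seq)], k=21), sketch([("c", seq)], k=17))

    def test_two_percent_divergence_pair(self):
        """The worked divergence example: a 1 Mb pair at 2% substitutions."""
        pair = mutate_genome(1_000_000, 0.02, seed=1)
        a = sketch([("a", pair.sequence)])
        b = sketch([("b", pair.mutated)])
        result = mash_ani(a, b)
        assert 97.5 <= result.ani_percent <= 98.5
        exact = exact_canonical_jaccard(pair.sequence[:200_000],
                                        pair.mutated[:200_000])
        sk_a = sketch([("a", pair.sequence[:200_000])])
        sk_b = sketch([("b", pair.mutated[:200_000])])
        assert abs(mash_ani(sk_a, sk_b).jaccard - exact) <= 0.02


class TestDelineate:
    def _result(self, ani_percent):
        j = None
        if ani_percent is not None:
            d = 1 - ani_percent / 100
            w = math.exp(-21 * d)
            j = w / (2 - w)
        from syntroscreen.ani import AniResult
        return AniResult(pair=("a", "b"), jaccard=j or 0.0,
                         mash_distance=(1 - ani_percent / 100)
                         if ani_percent is not None else math.inf,
                         ani_percent=ani_percent,
                         shared_hashes=100 if ani_percent else 0)

    def test_same_species_at_9984(self):
        call = delineate(self._result(99.84))
        assert call.same_species
        assert not call.new_genus_advisory

    def test_new_genus_at_7228_with_ddh(self):
        call = delineate(self._result(72.28), ddh_input=14.8)
        assert not call.same_species
        assert call.new_genus_advisory
        assert "reliable range" in call.note

    def test_species_threshold_inclusive(self):
        assert delineate(self._result(95.0)).same_species
        assert not delineate(self._result(94.99)).same_species

    def test_ddh_alone_supports_call(self):
        call = delineate(None, ddh_input=85.0)
        assert call.same_species
        call = delineate(None, ddh_input=30.0)
        assert not call.same_species

    def test_neither_source_rejected(self):
        with pytest.raises(AniError, match="needs"):
            delineate(None)

    def test_custom_thresholds_respected(self):
        strict = Thresholds(ani_species=98.0)
        assert not delineate(self._result(96.0), thresholds=strict).same_species
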