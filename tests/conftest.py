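"""Shared fixtures and small helpers for the test suite."""

from __future__ import annotations

import pytest

from syntroscreen.io import AnnotatedGenome, GeneAnnotation


def genome_from_symbols(genome_id: str, symbols, sample_id=None) -> AnnotatedGenome:
    """Build an AnnotatedGenome with symbol-only gene calls."""
    genes = [
        GeneAnnotation(genome_id=genome_id, gene_id=f"{genome_id}_{i:05d}",
                       symbol=sym)
        for i, sym in enumerate(symbols, start=1)
    ]
    return AnnotatedGenome(genome_id=genome_id, genes=genes, sample_id=sample_id)


WLP_ALL = ["fdhA", "fhs", "folD", "metF",
           "acsA", "acsB", "acsC", "acsD", "acsE", "pta", "ackA"]
WLP_CORE = ["fdhA", "fhs", "folD", "metF", "acsA", "acsB", "acsC", "acsD", "acsE"]
GSRP_REQUIRED = ["grd", "gcvPA", "gcvT", "lpdA"]


@pytest.fixture
def complete_wlp_genome():
    return genome_from_symbols("g_complete", WLP_ALL)
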