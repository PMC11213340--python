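"""Shared fixtures: small toy genomes and one cached default simulation."""

from __future__ import annotations

import numpy as np
import pytest

from ltspevo.core_io import GeneModel
from ltspevo.synthetic_data import SimConfig, SimResult, generate_toy_genome, simulate_ltsp


@pytest.fixture(scope="session")
def toy_genome():
    """Deterministic 12-gene toy genome (genes, genome string)."""
    return generate_toy_genome(n_genes=12, codons_per_gene=40, seed=7)


@pytest.fixture(scope="session")
def sim_default() -> SimResult:
    """One full default-condition simulation, shared across tests."""
    return simulate_ltsp(SimConfig(seed=1))


@pytest.fixture()
def hand_genes() -> list[GeneModel]:
    """Two hand-built single-codon-resolution genes on opposite strands.

    geneP (+): positions 11..19, CDS ATG TTT TAA.
    geneM (-): positions 31..39, same CDS after reverse complement.
    """
    cds = "ATGTTTTAA"
    comp = str.maketrans("ACGT", "TGCA")
    return [
        GeneModel("geneP", "+", [(11, 19)], cds),
        GeneModel("geneM", "-", [(31, 39)], cds),
    ]


@pytest.fixture()
def hand_genome(hand_genes) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    cds = "ATGTTTTAA"
    minus = cds[::-1].translate(comp)
    return "A" * 10 + cds + "C" * 11 + minus + "G" * 10
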