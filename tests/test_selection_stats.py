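"""Site counting, effect classification, dN/dS and the chi-square test."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest

from ltspevo.core_io import GeneModel, MutationRecord, SiteCounts
from ltspevo.selection_stats import (
    GeneIndex,
    MutationCounts,
    chi_square_neutrality,
    classify_snp_effect,
    compute_dnds,
    count_syn_nonsyn_sites,
    nonsyn_fraction_by_timepoint,
)

_CODE = {
    "".join(c): aa
    for c, aa in zip(
        product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
    )
}


def brute_force_sites(codon: str) -> tuple[float, float]:
    """Enumerate all 9 substitutions of a codon; 1/3 site weight each."""
    n = s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODE[alt] == _CODE[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return n, s


@pytest.mark.parametrize("codon,expected", [
    ("ATG", (3.0, 0.0)),        # Met: nothing synonymous
    ("TTT", (8 / 3, 1 / 3)),    # Phe: only TTT->TTC synonymous
])
def test_site_counts_known_codons(codon, expected):
    assert brute_force_sites(codon) == pytest.approx((expected[0], expected[1]))
    gene = GeneModel("g", "+", [(1, 6)], codon + "TAA")
    counts = count_syn_nonsyn_sites([gene])["g"]
    assert (counts.n_sites, counts.s_sites) == pytest.approx(expected)


def test_site_counts_match_enumeration_oracle(toy_genome):
    """Per-gene totals equal codon-by-codon brute-force enumeration."""
    genes, _ = toy_genome
    counts = count_syn_nonsyn_sites(genes)
    for gene in genes:
        n = s = 0.0
        for i in range(0, gene.coding_length - 3, 3):  # stop codon excluded
            dn, ds = brute_force_sites(gene.sequence[i : i + 3])
            n, s = n + dn, s + ds
        assert counts[gene.gene_id].n_sites == pytest.approx(n)
        assert counts[gene.gene_id].s_sites == pytest.approx(s)


def test_site_count_conservation(toy_genome):
    """syn + nonsyn site totals equal counted coding positions, every gene."""
    genes, _ = toy_genome
    counts = count_syn_nonsyn_sites(genes)
    for gene in genes:
        c = counts[gene.gene_id]
        assert c.n_sites + c.s_sites == pytest.approx(gene.coding_length - 3)
    genome = counts["genome"]
    assert genome.n_sites + genome.s_sites == pytest.approx(
        sum(g.coding_length - 3 for g in genes)
    )


def test_internal_stop_gene_skipped(caplog):
    gene = GeneModel("bad", "+", [(1, 9)], "ATGTAATAA")
    with caplog.at_level("WARNING"):
        counts = count_syn_nonsyn_sites([gene])
    assert "bad" not in counts
    assert counts["genome"].n_sites == 0


def test_classify_plus_strand_synonymous(hand_genes):
    index = GeneIndex(hand_genes)
    # third position of TTT codon (genomic position 16), T->C: Phe->Phe
    rec = MutationRecord("c", "1", 0, 16, "T", "C", "SNP")
    assert classify_snp_effect(rec, index) == "synonymous"
    rec = MutationRecord("c", "1", 0, 14, "T", "G", "SNP")
    assert classify_snp_effect(rec, index) == "nonsynonymous"


def test_classify_minus_strand_hand_case(hand_genes, hand_genome):
    """Minus-strand gene: genomic T>C at CDS wobble position is synonymous.

    geneM occupies 31..39 with genomic sequence TTAAAACAT; its 5'->3' CDS is
    ATG TTT TAA. CDS offset of genomic position p is 39 - p; the TTT codon's
    third position (CDS offset 5) is genomic position 34, genomic base A,
    and CDS base T. Genomic A>G there is CDS T>C: synonymous.
    """
    index = GeneIndex(hand_genes)
    assert hand_genome[33] == "A"
    rec = MutationRecord("c", "1", 0, 34, "A", "G", "SNP")
    assert classify_snp_effect(rec, index) == "synonymous"
    # same substitution type at CDS position 3 (genomic 36) changes Phe
    rec = MutationRecord("c", "1", 0, 36, "A", "C", "SNP")
    assert classify_snp_effect(rec, index) == "nonsynonymous"


def test_classify_strand_invariance(toy_genome):
    """The same CDS-level change classifies identically on either strand.

    For each single-interval gene, a minus-strand twin with the same stored
    5'->3' CDS is built; a genomic substitution at position p on the plus
    copy corresponds to the complementary substitution at the mirrored
    position start+end-p on the minus copy (same CDS offset, same base
    change), so the two classifications must agree.
    """
    genes, _ = toy_genome
    comp = str.maketrans("ACGT", "TGCA")
    rng = np.random.default_rng(3)
    checked = 0
    for g in genes:
        start, end = g.intervals[0]
        plus = GeneModel(g.gene_id, "+", [(start, end)], g.sequence)
        minus = GeneModel(g.gene_id, "-", [(start, end)], g.sequence)
        pindex, mindex = GeneIndex([plus]), GeneIndex([minus])
        for position in rng.integers(start, end + 1, size=8):
            position = int(position)
            off = position - start
            ref = g.sequence[off]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rec = MutationRecord("c", "1", 0, position, ref, alt, "SNP")
            mirror = MutationRecord(
                "c", "1", 0, start + end - position,
                ref.translate(comp), alt.translate(comp), "SNP",
            )
            assert classify_snp_effect(rec, pindex) == classify_snp_effect(mirror, mindex)
            checked += 1
    assert checked > 50


def test_classify_intergenic(hand_genes):
    index = GeneIndex(hand_genes)
    rec = MutationRecord("c", "1", 0, 25, "C", "T", "SNP")
    assert classify_snp_effect(rec, index) == "noncoding"


def test_dnds_values():
    sites = SiteCounts(8.0, 2.0, "g")
    assert compute_dnds(MutationCounts(0, 5), sites) == 0
    assert compute_dnds(MutationCounts(8, 2), sites) == pytest.approx(1.0)
    assert math.isinf(compute_dnds(MutationCounts(3, 0), sites))
    assert math.isnan(compute_dnds(MutationCounts(0, 0), sites))
    with pytest.raises(ValueError):
        compute_dnds(MutationCounts(1, 1), SiteCounts(0.0, 2.0))


def test_chi_square_hand_example():
    """(30, 0) against a 3:1 site split: chi2 = 7.5^2/22.5 + 7.5^2/7.5 = 10."""
    sites = SiteCounts(3.0, 1.0)
    chi2, p = chi_square_neutrality(MutationCounts(30, 0), sites)
    assert chi2 == pytest.approx(10.0)
    chi2_double, _ = chi_square_neutrality(MutationCounts(60, 0), sites)
    assert chi2_double == pytest.approx(20.0)  # 2-cell chi2 scales linearly
    chi2_null, p_null = chi_square_neutrality(MutationCounts(30, 10), sites)
    assert chi2_null == pytest.approx(0.0)
    assert p_null == pytest.approx(1.0)


def test_nonsyn_fraction_by_timepoint():
    from ltspevo.core_io import Clone

    def clone(cid, day, effects):
        c = Clone(cid, "1", day)
        for i, eff in enumerate(effects):
            rec = MutationRecord(cid, "1", day, 100 + i, "A", "G", "SNP")
            rec.coding_effect = eff
            c.mutations.append(rec)
        return c

    clones = [
        clone("a", 11, ["nonsynonymous", "nonsynonymous", "nonsynonymous", "synonymous"]),
        clone("b", 22, []),
    ]
    sites = SiteCounts(3.0, 1.0)
    df = nonsyn_fraction_by_timepoint(clones, sites)
    assert df.loc[df.day == 11, "nonsyn_fraction"].iloc[0] == pytest.approx(0.75)
    assert np.allclose(df["neutral_expectation"], 0.75)
    assert 22 not in set(df.day)  # empty window omitted
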