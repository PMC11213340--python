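"""Synonymous/non-synonymous site counting, SNP effect classification and dN/dS.

Site counting follows the per-position likelihood convention: at every coding
position each of the 3 possible substitutions contributes 1/3 of a site to the
synonymous or non-synonymous total, under a uniform substitution model.
dN/dS is then (n_obs / n_sites) / (s_obs / s_sites). Stop codons are excluded
from the site totals; substitutions that create a stop codon count as
non-synonymous (Nei-Gojobori-style convention).
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core_io import Clone, GeneModel, MutationRecord, SiteCounts

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial
_STOPS = set(_TABLE.stop_codons)
_AA = dict(_TABLE.forward_table)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _AA[codon]


@dataclass
class MutationCounts:
    """Observed non-synonymous and synonymous SNP counts within some scope."""

    n_obs: int
    s_obs: int
    scope: str = "all"


def count_syn_nonsyn_sites(genes: Iterable[GeneModel]) -> dict[str, SiteCounts]:
    """Expected synonymous / non-synonymous site counts per gene and genome-wide.

    Every coding position (terminal stop codon excluded) contributes exactly
    one site split across the two classes, so per gene
    ``n_sites + s_sites == coding_length - 3``. Genes containing an internal
    stop codon are skipped with a warning.
    """
    out: dict[str, SiteCounts] = {}
    total = SiteCounts(0.0, 0.0, "genome")
    for gene in genes:
        seq = gene.sequence
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in _STOPS:
            codons = codons[:-1]
        if any(c in _STOPS for c in codons):
            logger.warning("skipping gene %s: internal stop codon", gene.gene_id)
            continue
        n = s = 0.0
        for codon in codons:
            ref_aa = _aa(codon)
            for pos in range(3):
                for base in _BASES:
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1 :]
                    if _aa(alt) == ref_aa:
                        s += 1 / 3
                    else:
                        n += 1 / 3
        counts = SiteCounts(n, s, gene.gene_id)
        out[gene.gene_id] = counts
        total = total + counts
    out["genome"] = total
    return out


class GeneIndex:
    """Position -> gene lookup over non-overlapping-interval gene models."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        spans = []
        for gi, gene in enumerate(self.genes):
            for s, e in gene.intervals:
                spans.append((s, e, gi))
        spans.sort()
        self._starts = [s for s, _, _ in spans]
        self._spans = spans

    def find(self, position: int) -> GeneModel | None:
        i = bisect_right(self._starts, position) - 1
        # walk back over any earlier intervals that still span the position
        while i >= 0:
            s, e, gi = self._spans[i]
            if s <= position <= e:
                return self.genes[gi]
            if e < position and s < position - 10_000:
                break
            i -= 1
        return None

    def cds_offset(self, gene: GeneModel, position: int) -> int:
        """0-based offset of a genomic position within the 5'->3' CDS."""
        off = 0
        for s, e in gene.intervals:
            if s <= position <= e:
                off += position - s
                break
            off += e - s + 1
        else:
            raise ValueError(f"position {position} not in CDS of {gene.gene_id}")
        if gene.strand == "-":
            off = gene.coding_length - 1 - off
        return off


def classify_snp_effect(record: MutationRecord, index: GeneIndex) -> str:
    """Classify a SNP as synonymous / nonsynonymous / noncoding (strand-aware)."""
    if record.mutation_class != "SNP":
        return "indel_or_structural"
    gene = index.find(record.position)
    if gene is None:
        return "noncoding"
    off = index.cds_offset(gene, record.position)
    alt = record.alt_allele
    if gene.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    codon_i, codon_pos = divmod(off, 3)
    codon = gene.sequence[3 * codon_i : 3 * codon_i + 3]
    mutated = codon[:codon_pos] + alt + codon[codon_pos + 1 :]
    return "synonymous" if _aa(mutated) == _aa(codon) else "nonsynonymous"


def classify_all(records: Iterable[MutationRecord], genes: Sequence[GeneModel]) -> None:
    """Set ``coding_effect`` on every record in place."""
    index = GeneIndex(genes)
    for rec in records:
        rec.coding_effect = classify_snp_effect(rec, index)


def observed_counts(records: Iterable[MutationRecord], scope: str = "all") -> MutationCounts:
    recs = list(records)
    n = sum(1 for r in recs if r.coding_effect == "nonsynonymous")
    s = sum(1 for r in recs if r.coding_effect == "synonymous")
    return MutationCounts(n, s, scope)


def compute_dnds(obs: MutationCounts, sites: SiteCounts) -> float:
    """dN/dS = (n_obs / n_sites) / (s_obs / s_sites).

    Returns ``inf`` when no synonymous mutations were observed but
    non-synonymous ones were, and ``nan`` when both observed counts are 0.
    """
    if sites.n_sites <= 0 or sites.s_sites <= 0:
        raise ValueError("site counts must be positive")
    if obs.s_obs == 0:
        return math.inf if obs.n_obs > 0 else math.nan
    return (obs.n_obs / sites.n_sites) / (obs.s_obs / sites.s_sites)


def chi_square_neutrality(obs: MutationCounts, sites: SiteCounts) -> tuple[float, float]:
    """1-df goodness-of-fit of observed N/S counts against the site split.

    Returns (chi2, p). The expected split allocates the observed total in
    proportion to (n_sites, s_sites).
    """
    total = obs.n_obs + obs.s_obs
    if total == 0:
        return math.nan, math.nan
    site_total = sites.n_sites + sites.s_sites
    expected = [total * sites.n_sites / site_total, total * sites.s_sites / site_total]
    chi2, p = stats.chisquare([obs.n_obs, obs.s_obs], f_exp=expected)
    return float(chi2), float(p)


def mutation_first_day(clones: Iterable[Clone]) -> dict[tuple, int]:
    """Map each mutation key to the earliest sampling day it is observed."""
    first: dict[tuple, int] = {}
    for clone in clones:
        for m in clone.mutations:
            if m.key not in first or clone.day < first[m.key]:
                first[m.key] = clone.day
    return first


def nonsyn_fraction_by_timepoint(
    clones: Sequence[Clone], sites: SiteCounts, include_mutators: bool = False
) -> pd.DataFrame:
    """Per-time-point fraction of non-synonymous SNPs plus the neutral line.

    Each mutation is dated by the earliest sampling day at which any clone
    carries it, and counted once. The neutral expectation
    ``n_sites / (n_sites + s_sites)`` depends only on the genome.
    """
    pool = [c for c in clones if include_mutators or not c.is_mutator]
    first = mutation_first_day(pool)
    effects: dict[tuple, str] = {}
    for clone in pool:
        for m in clone.mutations:
            if m.coding_effect in ("synonymous", "nonsynonymous"):
                effects[m.key] = m.coding_effect
    by_day: dict[int, list[int]] = {}
    for key, eff in effects.items():
        by_day.setdefault(first[key], []).append(1 if eff == "nonsynonymous" else 0)
    neutral = sites.n_sites / (sites.n_sites + sites.s_sites)
    rows = []
    for day in sorted(by_day):
        vals = by_day[day]
        rows.append({
            "day": day,
            "n_obs": int(sum(vals)),
            "s_obs": int(len(vals) - sum(vals)),
            "nonsyn_fraction": float(np.mean(vals)),
            "neutral_expectation": neutral,
        })
    return pd.DataFrame(rows, columns=["day", "n_obs", "s_obs", "nonsyn_fraction", "neutral_expectation"])


def dnds_table(
    clones: Sequence[Clone],
    site_counts: Mapping[str, SiteCounts],
    include_mutators: bool = False,
) -> pd.DataFrame:
    """Genome-wide dN/dS summary over unique mutations of (non-mutator) clones."""
    pool = [c for c in clones if include_mutators or not c.is_mutator]
    uniq: dict[tuple, MutationRecord] = {}
    for clone in pool:
        for m in clone.mutations:
            uniq.setdefault(m.key, m)
    obs = observed_counts(list(uniq.values()), scope="non-mutator" if not include_mutators else "all")
    sites = site_counts["genome"]
    chi2, p = chi_square_neutrality(obs, sites)
    return pd.DataFrame([{
        "scope": obs.scope,
        "n_obs": obs.n_obs,
        "s_obs": obs.s_obs,
        "n_sites": sites.n_sites,
        "s_sites": sites.s_sites,
        "dnds": compute_dnds(obs, sites),
        "chi2": chi2,
        "p": p,
    }])
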