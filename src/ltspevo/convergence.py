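"""Locus assignment and convergent-mutation statistics.

A locus is either a protein-coding gene or the promoter (upstream intergenic
region) of a gene. Convergence is measured as the number of independent
units — populations, or lineages plus pseudo-lineages — in which a locus is
mutated in at least one non-mutator clone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import Clone, GeneModel, MutationRecord
from .selection_stats import GeneIndex, mutation_first_day

logger = logging.getLogger(__name__)


def promoter_id(gene_id: str) -> str:
    return f"{gene_id}_promoter"


class LocusIndex:
    """Maps genomic positions to gene or promoter loci.

    Intergenic positions are assigned to the promoter locus of the gene whose
    upstream intergenic interval contains them (strand-aware): a plus-strand
    gene claims the gap to its left, a minus-strand gene the gap to its
    right. Between divergent genes both claim the gap and the nearer gene
    wins; exact ties go to the lexicographically smaller gene id.
    """

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = sorted(genes, key=lambda g: g.start)
        self._gene_index = GeneIndex(self.genes)
        # claims: list of (start, end, gene_id, anchor) where anchor is the
        # genomic coordinate of the gene boundary the promoter abuts
        self._claims: list[tuple[int, int, str, int]] = []
        bounds = [(g.start, g.end) for g in self.genes]
        for i, gene in enumerate(self.genes):
            if gene.strand == "+":
                left_end = bounds[i - 1][1] if i > 0 else 0
                lo, hi = left_end + 1, gene.start - 1
                anchor = gene.start
            else:
                right_start = bounds[i + 1][0] if i + 1 < len(self.genes) else None
                if right_start is None:
                    continue
                lo, hi = gene.end + 1, right_start - 1
                anchor = gene.end
            if lo <= hi:
                self._claims.append((lo, hi, gene.gene_id, anchor))
                gene.upstream_interval = (lo, hi)

    def assign(self, position: int) -> str:
        gene = self._gene_index.find(position)
        if gene is not None:
            return gene.gene_id
        claimants = [
            (abs(position - anchor), gid)
            for lo, hi, gid, anchor in self._claims
            if lo <= position <= hi
        ]
        if not claimants:
            return "unassigned"
        claimants.sort()
        if len(claimants) > 1 and claimants[0][0] == claimants[1][0]:
            logger.debug("position %d equidistant between promoters; assigned to %s",
                         position, claimants[0][1])
        return promoter_id(claimants[0][1])


def assign_loci(records: Iterable[MutationRecord], genes: Sequence[GeneModel]) -> None:
    """Set ``locus_id`` on every record in place."""
    index = LocusIndex(genes)
    for rec in records:
        rec.locus_id = index.assign(rec.position)


@dataclass
class ConvergenceSummary:
    level: str  # "population" or "lineage"
    min_units: int
    unit_counts: dict[str, int]  # locus -> number of units mutated in
    convergent_loci: set[str]
    fraction_in_convergent: float
    n_units: int = 0
    extra: dict = field(default_factory=dict)


def _mutation_events(clones: Iterable[Clone]) -> set[tuple[str, tuple, str]]:
    """Distinct (population, mutation key, locus) events among given clones."""
    events = set()
    for clone in clones:
        for m in clone.mutations:
            events.add((str(clone.population), m.key, m.locus_id or "unassigned"))
    return events


def convergent_loci(
    clones: Sequence[Clone],
    level: str = "population",
    min_units: int = 2,
    include_mutators: bool = False,
) -> ConvergenceSummary:
    """Loci mutated in >= ``min_units`` independent units (non-mutator clones).

    At ``level="population"`` the units are populations; at ``level="lineage"``
    they are lineages plus pseudo-lineages (requires lineage assignment).
    Also reports the fraction of all non-mutator mutation events (distinct
    (population, mutation) pairs) that fall within the convergent loci.
    """
    pool = [c for c in clones if include_mutators or not c.is_mutator]
    if level == "population":
        unit_of = lambda c: str(c.population)
    elif level == "lineage":
        if any(c.lineage_id is None for c in pool):
            raise ValueError("lineage-level convergence requires lineage assignment")
        unit_of = lambda c: c.lineage_id
    else:
        raise ValueError(f"unknown level {level!r}")

    locus_units: dict[str, set[str]] = {}
    units = set()
    for clone in pool:
        u = unit_of(clone)
        units.add(u)
        for locus in clone.loci:
            locus_units.setdefault(locus, set()).add(u)
    unit_counts = {locus: len(us) for locus, us in locus_units.items()}
    convergent = {locus for locus, n in unit_counts.items() if n >= min_units}

    events = _mutation_events(pool)
    in_conv = sum(1 for _, _, locus in events if locus in convergent)
    frac = in_conv / len(events) if events else float("nan")
    return ConvergenceSummary(
        level=level,
        min_units=min_units,
        unit_counts=unit_counts,
        convergent_loci=convergent,
        fraction_in_convergent=frac,
        n_units=len(units),
    )


def convergence_fraction_by_timepoint(
    clones: Sequence[Clone], summary: ConvergenceSummary, include_mutators: bool = False
) -> pd.DataFrame:
    """Per-day fraction of mutation events by number of units their locus hits.

    Mutations are dated by their first observation. Fractions over the
    categories 1..n_units sum to 1 for every day with events.
    """
    pool = [c for c in clones if include_mutators or not c.is_mutator]
    first = mutation_first_day(pool)
    events = _mutation_events(pool)
    max_cat = summary.n_units
    counts: dict[int, list[int]] = {}
    key_day: dict[tuple, int] = first
    for pop, key, locus in events:
        day = key_day[key]
        cat = min(summary.unit_counts.get(locus, 1), max_cat)
        counts.setdefault(day, [0] * (max_cat + 1))[cat] += 1
    rows = []
    for day in sorted(counts):
        total = sum(counts[day])
        for cat in range(1, max_cat + 1):
            rows.append({
                "day": day,
                "n_units": cat,
                "fraction": counts[day][cat] / total,
            })
    return pd.DataFrame(rows, columns=["day", "n_units", "fraction"])


def convergence_table(summary: ConvergenceSummary) -> pd.DataFrame:
    rows = [
        {"locus": locus, "n_units": n, "convergent": n >= summary.min_units}
        for locus, n in sorted(summary.unit_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["locus", "n_units", "convergent"])


def mean_mutations_per_clone(clones: Sequence[Clone], include_mutators: bool = False) -> pd.DataFrame:
    """Mean (and SD) mutation count per clone per sampling day."""
    pool = [c for c in clones if include_mutators or not c.is_mutator]
    rows = []
    by_day: dict[int, list[int]] = {}
    for c in pool:
        by_day.setdefault(c.day, []).append(len(c.mutations))
    for day in sorted(by_day):
        vals = pd.Series(by_day[day], dtype=float)
        rows.append({"day": day, "mean_mutations": vals.mean(),
                     "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                     "n_clones": len(vals)})
    return pd.DataFrame(rows)
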