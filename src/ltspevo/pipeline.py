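"""End-to-end orchestration: from a mutation table + annotation to all results."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import contingency_screen as cs
from . import convergence as conv
from . import lineage_inference as li
from . import selection_stats as ss
from .core_io import Clone, FunctionalPairTable, GeneModel, MutationRecord, flag_mutators
from .core_io import DEFAULT_MUTATOR_GENES


@dataclass
class PipelineResult:
    phylogenies: dict[str, li.PopulationPhylogeny]
    units: dict[str, list[Clone]]
    convergence_population: conv.ConvergenceSummary
    convergence_lineage: conv.ConvergenceSummary
    candidate_pairs: list[tuple[str, str]]
    association: pd.DataFrame
    reliable: pd.DataFrame
    directionality: dict[tuple[str, str], cs.DirectionEvidence]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(
    records: Sequence[MutationRecord],
    clones: Sequence[Clone],
    genes: Sequence[GeneModel],
    mutator_genes: Sequence[str] = DEFAULT_MUTATOR_GENES,
    exclude_loci: Sequence[str] = cs.DEFAULT_EXCLUDED_LOCI,
    functional: FunctionalPairTable | None = None,
    alpha: float = 0.05,
    q_cutoff: float = 0.8,
    y_cutoff: float = 0.5,
    frequency_threshold: float = li.FREQUENCY_THRESHOLD,
) -> PipelineResult:
    """Run locus assignment, lineage reconstruction, convergence statistics,
    the contingency screen and directionality inference.

    ``q_cutoff`` / ``y_cutoff`` are the consensus thresholds; when a
    functional pair table is supplied they are re-derived by maximizing the
    functional fraction of above-cutoff significant pairs.
    """
    ss.classify_all(records, genes)
    conv.assign_loci(records, genes)
    flag_mutators(clones, mutator_genes)
    site_counts = ss.count_syn_nonsyn_sites(genes)

    phylos = li.reconstruct_all(clones, frequency_threshold)
    units = cs.screen_units(clones, phylos)

    conv_pop = conv.convergent_loci(clones, "population")
    conv_lin = conv.convergent_loci(clones, "lineage")
    candidate_loci = sorted(
        (conv_pop.convergent_loci | conv_lin.convergent_loci) - set(exclude_loci) - {"unassigned"}
    )
    pairs = cs.enumerate_candidate_pairs(candidate_loci, units, exclude_loci=exclude_loci)
    tables = [cs.build_pair_table(p, units) for p in pairs]
    association = cs.test_association(tables, alpha=alpha)

    if functional is not None and len(functional) > 0:
        cutoffs = cs.select_thresholds(association, functional)
        q_cutoff = cutoffs.get("Q", q_cutoff)
        y_cutoff = cutoffs.get("Y", y_cutoff)
    reliable = cs.consensus_reliable_pairs(association, q_cutoff, y_cutoff)

    evidence: dict[tuple[str, str], cs.DirectionEvidence] = {}
    for row in reliable.itertuples(index=False):
        pair = (row.locus_a, row.locus_b)
        evidence[pair] = cs.infer_directionality(pair, units, phylos, clones)

    muller = li.muller_table(phylos, clones)
    dnds = ss.dnds_table(clones, site_counts)
    direction_df = cs.directionality_table(list(evidence.values()))
    network = cs.contingency_network(reliable, evidence)

    result = PipelineResult(
        phylogenies=phylos,
        units=units,
        convergence_population=conv_pop,
        convergence_lineage=conv_lin,
        candidate_pairs=pairs,
        association=association,
        reliable=reliable,
        directionality=evidence,
        tables={
            "lineages": li.lineage_table(phylos),
            "muller": muller,
            "convergence_population": conv.convergence_table(conv_pop),
            "convergence_lineage": conv.convergence_table(conv_lin),
            "association": association,
            "directionality": direction_df,
            "network": network,
            "dnds": dnds,
            "nonsyn_fraction": ss.nonsyn_fraction_by_timepoint(clones, site_counts["genome"]),
        },
    )
    n_lineages = sum(
        1 for p in phylos.values() for l in p.lineages if not l.is_pseudo
    )
    directed = [e for e in evidence.values() if e.call in ("A_first", "B_first")]
    result.summary = {
        "n_clones": len(clones),
        "n_lineages": n_lineages,
        "assigned_fraction": li.assignment_fraction(phylos),
        "n_units": len(units),
        "n_convergent_loci_population": len(conv_pop.convergent_loci),
        "n_convergent_loci_lineage": len(conv_lin.convergent_loci),
        "fraction_in_convergent_population": conv_pop.fraction_in_convergent,
        "fraction_in_convergent_lineage": conv_lin.fraction_in_convergent,
        "n_candidate_pairs": len(pairs),
        "n_phi_significant": int(association["sig_phi"].sum()) if not association.empty else 0,
        "n_reliable_pairs": len(reliable),
        "n_directed": len(directed),
        "dnds_nonmutator": float(dnds["dnds"].iloc[0]) if not dnds.empty else float("nan"),
        "q_cutoff": q_cutoff,
        "y_cutoff": y_cutoff,
    }
    return result
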