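"""Seeded generator of toy genomes and LTSP-like clone samples.

The generator emulates the sampling design of a long-term stationary phase
(LTSP) evolution experiment: several populations founded from single clones,
sampled at fixed days with ~10 sequenced colonies each. Within each
population a small number of lineages is established at day 0 by a founding
("RNA-polymerase-like") mutation; lineage frequencies follow a renormalized
geometric random walk; each lineage carries a single heritable "trunk" of
mutations accumulating over time (neutral background plus gains at a shared
pool of adaptive loci), from which sampled clones inherit a prefix plus a
short private branch. Mutator lineages multiply the neutral rate. Planted
contingent loci pairs suppress the second locus's gain rate by a factor
(1 - strength) until the first locus is mutated on the same background.

Every run is fully determined by the seed and emits machine-readable ground
truth alongside the mutation table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import Clone, GeneModel, MutationRecord
from .selection_stats import GeneIndex, classify_snp_effect

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic LTSP experiment.

    Rates are per day. Defaults mirror the design of a six-year, five
    population experiment sampled at 12 time points with ten clones each.
    """

    n_populations: int = 5
    sampling_days: tuple[int, ...] = (11, 22, 32, 42, 64, 127, 374, 730, 1095, 1460, 1816, 2191)
    clones_per_sample: int = 10
    #: per-lineage founding frequencies; the remainder of the simplex holds
    #: clones that never join any lineage (the pseudo-lineage pool)
    founding_frequencies: tuple[float, ...] = (0.40, 0.31, 0.26)
    #: per-sampling-step log-scale noise of lineage weights
    frequency_walk_sigma: float = 0.25
    #: mean reversion of log-weights towards their founding values, per step;
    #: established LTSP lineages coexist stably over years, so weights
    #: fluctuate around the founding composition rather than random-walk away
    frequency_reversion: float = 0.5
    # toy genome
    n_genes: int = 100
    codons_per_gene: int = 120
    spacer_length: int = 60
    # mutation process
    adaptive_pool_size: int = 24
    adaptive_gain_rate: float = 3e-4     # per pool locus per trunk per day
    pair_gain_rate: float = 6e-4         # arrival rate of a pair's first locus
    #: full acquisition propensity of a pair's second locus once the first is
    #: mutated on the same background (contingent mutations follow fast under
    #: strong selection); backgrounds lacking the first locus see this
    #: propensity scaled by (1 - strength)
    pair_followup_rate: float = 1e-2
    neutral_rate: float = 1.5e-3         # per genome per day, heritable trunk
    divergence_lag: float = 150.0        # mean days of a clone's private branch
    indel_fraction: float = 0.1          # neutral events emitted as 1-bp deletions
    #: (pool_index_a, pool_index_b, strength): locus B's gain propensity is
    #: multiplied by (1 - strength) on backgrounds lacking a locus-A mutation
    contingent_pairs: tuple[tuple[int, int, float], ...] = tuple(
        (2 * i, 2 * i + 1, 0.995) for i in range(8)
    )
    #: populations (1-based) whose first founding variant defines a mutator lineage
    mutator_populations: tuple[int, ...] = (2, 3, 4)
    mutator_fold: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.founding_frequencies) > 1 + 1e-9:
            raise ValueError("founding frequencies must sum to <= 1")
        if len(self.founding_frequencies) > self.clones_per_sample:
            raise ValueError("more lineages than clones sampled per day")
        for a, b, s in self.contingent_pairs:
            if not 0 <= s <= 1:
                raise ValueError(f"pair strength {s} outside [0, 1]")
            if max(a, b) >= self.adaptive_pool_size or a == b:
                raise ValueError(f"invalid planted pair ({a}, {b})")


@dataclass
class GroundTruth:
    """Machine-readable truth for a simulated experiment."""

    lineage_of_clone: dict[str, str | None]
    planted_pairs: list[tuple[str, str, float]]  # (locus_A, locus_B, strength); B contingent on A
    acquisition_history: dict[str, list[str]]    # clone -> mutation labels in order
    founding_gene_ids: list[str]
    mutator_gene_id: str
    adaptive_pool: list[str]
    mutator_lineages: list[str]


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    genome: str
    records: list[MutationRecord]
    clones: list[Clone]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# toy genome

def generate_toy_genome(
    n_genes: int, codons_per_gene: int, seed: int | np.random.Generator, spacer_length: int = 60
) -> tuple[list[GeneModel], str]:
    """Random toy genome: plus/minus-strand genes separated by intergenic spacers.

    Genes start with ATG, end with a stop codon and contain no internal
    stops; spacers (>= 20 bp) provide promoter loci.
    """
    if n_genes < 1 or codons_per_gene < 2:
        raise ValueError("need n_genes >= 1 and codons_per_gene >= 2")
    if spacer_length < 20:
        raise ValueError("intergenic spacers must be >= 20 bp")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    non_stop = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS and a + b + c != "ATG"]
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0
    comp = str.maketrans("ACGT", "TGCA")
    for gi in range(n_genes):
        spacer = "".join(rng.choice(list(_BASES), size=spacer_length))
        parts.append(spacer)
        pos += spacer_length
        body = [non_stop[i] for i in rng.integers(0, len(non_stop), size=codons_per_gene - 2)]
        cds = "ATG" + "".join(body) + "TAA"
        strand = "+" if gi % 3 != 2 else "-"
        start, end = pos + 1, pos + len(cds)
        genomic = cds if strand == "+" else cds[::-1].translate(comp)
        parts.append(genomic)
        pos += len(cds)
        genes.append(GeneModel(
            gene_id=f"g{gi:03d}", strand=strand, intervals=[(start, end)], sequence=cds,
        ))
    parts.append("".join(rng.choice(list(_BASES), size=spacer_length)))
    return genes, "".join(parts)


def write_genome(genes: Sequence[GeneModel], genome: str, outdir: str | Path) -> tuple[Path, Path]:
    """Write the toy genome as FASTA + minimal GFF3 (CDS features)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "genome.fasta"
    with open(fasta, "w") as fh:
        fh.write(">toy\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")
    gff = outdir / "genome.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            for s, e in g.intervals:
                fh.write(f"toy\tltspevo\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tID=cds-{g.gene_id};gene={g.gene_id}\n")
    return fasta, gff


# ---------------------------------------------------------------------------
# mutation draws

_COMP = str.maketrans("ACGT", "TGCA")


def _random_nonsyn_snp(gene: GeneModel, index: GeneIndex, rng: np.random.Generator) -> tuple[int, str, str]:
    """A random non-synonymous SNP inside a gene's CDS (rejection sampling)."""
    start, end = gene.intervals[0]
    for _ in range(200):
        position = int(rng.integers(start, end + 1))
        # genomic reference base
        off = index.cds_offset(gene, position)
        ref = gene.sequence[off]
        if gene.strand == "-":
            ref = ref.translate(_COMP)
        alt = _BASES[int(rng.integers(0, 4))]
        if alt == ref:
            continue
        probe = MutationRecord("probe", "0", 0, position, ref, alt, "SNP")
        if classify_snp_effect(probe, index) == "nonsynonymous":
            return position, ref, alt
    raise RuntimeError(f"could not draw a nonsynonymous SNP in {gene.gene_id}")


def draw_neutral_snps(
    genome: str, n: int, rng: np.random.Generator
) -> list[tuple[int, str, str]]:
    """``n`` SNPs at uniform genome positions with uniform alternative bases."""
    out = []
    positions = rng.integers(1, len(genome) + 1, size=n)
    for position in positions:
        ref = genome[position - 1]
        alts = [b for b in _BASES if b != ref]
        out.append((int(position), ref, alts[int(rng.integers(0, 3))]))
    return out


# ---------------------------------------------------------------------------
# simulation

def _sample_truncated_exp(rng: np.random.Generator, rate: float, horizon: float) -> float | None:
    """Waiting time of a constant-rate process, or None past the horizon."""
    if rate <= 0:
        return None
    t = rng.exponential(1.0 / rate)
    return t if t <= horizon else None


def simulate_ltsp(config: SimConfig) -> SimResult:
    """Run the generator; see module docstring for the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, genome = generate_toy_genome(
        config.n_genes, config.codons_per_gene, rng, config.spacer_length
    )
    index = GeneIndex(genes)
    horizon = float(max(config.sampling_days))
    n_lineages = len(config.founding_frequencies)

    # gene roles: first two genes host the founding variants; the adaptive
    # pool follows; the last gene is the mutator (mismatch-repair stand-in)
    founding_genes = [genes[0], genes[1]]
    pool_genes = genes[2 : 2 + config.adaptive_pool_size]
    mutator_gene = genes[-1]
    pair_members: dict[int, tuple[int, int, float]] = {}
    pair_rates = {}
    for pi, (ia, ib, s) in enumerate(config.contingent_pairs):
        pair_members[ia] = (pi, 0, s)
        pair_members[ib] = (pi, 1, s)
        pair_rates[ia] = config.pair_gain_rate
        pair_rates[ib] = config.pair_followup_rate

    # founding variants: exact same (position, ref, alt) across populations
    n_variants = max(4, n_lineages + 1)
    variants = []
    for vi in range(n_variants):
        gene = founding_genes[vi % 2]
        variants.append(_random_nonsyn_snp(gene, index, rng))
    mutator_variant = _random_nonsyn_snp(mutator_gene, index, rng)

    records: list[MutationRecord] = []
    clones: list[Clone] = []
    truth = GroundTruth(
        lineage_of_clone={},
        planted_pairs=[
            (pool_genes[ia].gene_id, pool_genes[ib].gene_id, s)
            for ia, ib, s in config.contingent_pairs
        ],
        acquisition_history={},
        founding_gene_ids=[g.gene_id for g in founding_genes],
        mutator_gene_id=mutator_gene.gene_id,
        adaptive_pool=[g.gene_id for g in pool_genes],
        mutator_lineages=[],
    )

    # neutral background avoids the founding, adaptive-pool and mutator
    # genes, so locus-level ground truth (e.g. "B never without A" at
    # strength 1) is exact by construction
    reserved = [g.intervals[0] for g in founding_genes + pool_genes + [mutator_gene]]

    def neutral_event(time: float) -> tuple[float, tuple[int, str, str], str]:
        while True:
            position, ref, alt = draw_neutral_snps(genome, 1, rng)[0]
            if not any(s <= position <= e for s, e in reserved):
                break
        if rng.random() < config.indel_fraction:
            return time, (int(position), ref, ""), "small_indel"
        return time, (position, ref, alt), "SNP"

    for pop_i in range(1, config.n_populations + 1):
        pop = str(pop_i)
        is_mutator_pop = pop_i in config.mutator_populations
        # variant roster: mutator populations receive variant 0 first
        order = list(range(n_variants))
        if not is_mutator_pop:
            order = order[1:] + order[:1]
        lineage_variants = order[:n_lineages]

        # --- heritable trunks
        trunks: list[list[tuple[float, tuple[int, str, str], str]]] = []
        lineage_ids = []
        for li in range(n_lineages):
            lid = f"P{pop}/T{li + 1}"
            lineage_ids.append(lid)
            vi = lineage_variants[li]
            is_mut = is_mutator_pop and vi == 0
            if is_mut:
                truth.mutator_lineages.append(lid)
            fold = config.mutator_fold if is_mut else 1.0
            events: list[tuple[float, tuple[int, str, str], str]] = [
                (0.0, variants[vi], "SNP")
            ]
            if is_mut:
                events.append((0.0, mutator_variant, "SNP"))
            # adaptive pool gains
            pair_b_pending: dict[int, tuple[float, float]] = {}
            gain_time: dict[int, float | None] = {}
            for gi, gene in enumerate(pool_genes):
                rate = pair_rates.get(gi, config.adaptive_gain_rate)
                if gi in pair_members and pair_members[gi][1] == 1:
                    continue  # second members handled after their partner
                gain_time[gi] = _sample_truncated_exp(rng, rate, horizon)
            for gi, gene in enumerate(pool_genes):
                if gi not in pair_members or pair_members[gi][1] != 1:
                    continue
                pi, _, s = pair_members[gi]
                ia = config.contingent_pairs[pi][0]
                rate = pair_rates.get(gi, config.adaptive_gain_rate)
                t_a = gain_time.get(ia)
                t_a = math_inf if t_a is None else t_a
                # piecewise-constant hazard: (1-s)*rate before t_a, rate after
                t1 = rng.exponential(1.0 / ((1 - s) * rate)) if (1 - s) * rate > 0 else float("inf")
                if t1 <= t_a:
                    t_b = t1
                else:
                    t_b = t_a + rng.exponential(1.0 / rate)
                gain_time[gi] = t_b if t_b <= horizon else None
            for gi, t in gain_time.items():
                if t is None:
                    continue
                position, ref, alt = _random_nonsyn_snp(pool_genes[gi], index, rng)
                events.append((t, (position, ref, alt), "SNP"))
            # neutral trunk mutations
            n_neutral = rng.poisson(config.neutral_rate * fold * horizon)
            for t in np.sort(rng.uniform(0, horizon, size=n_neutral)):
                events.append(neutral_event(float(t)))
            events.sort(key=lambda e: e[0])
            trunks.append(events)

        # --- lineage frequency trajectories: renormalized mean-reverting
        # (log-OU) geometric walk around the founding composition
        base = np.log(np.array(list(config.founding_frequencies)
                               + [max(1 - sum(config.founding_frequencies), 1e-6)]))
        logw = base.copy()
        freq_path = []
        for _ in config.sampling_days:
            w = np.exp(logw)
            freq_path.append(w / w.sum())
            logw = logw + config.frequency_reversion * (base - logw) + rng.normal(
                0, config.frequency_walk_sigma, size=logw.size
            )

        # --- sample clones
        for di, day in enumerate(config.sampling_days):
            counts = rng.multinomial(config.clones_per_sample, freq_path[di])
            ci = 0
            for li in range(n_lineages + 1):
                for _ in range(counts[li]):
                    ci += 1
                    clone_id = f"P{pop}D{day}C{ci:02d}"
                    if li < n_lineages:
                        lid = lineage_ids[li]
                        fold = config.mutator_fold if lid in truth.mutator_lineages else 1.0
                        t_div = max(0.0, day - rng.exponential(config.divergence_lag))
                        inherited = [e for e in trunks[li] if e[0] <= t_div]
                        n_priv = rng.poisson(config.neutral_rate * fold * (day - t_div))
                        private = sorted(
                            (neutral_event(float(t)) for t in rng.uniform(t_div, day, size=n_priv)),
                            key=lambda e: e[0],
                        )
                        history = inherited + private
                        truth.lineage_of_clone[clone_id] = lid
                    else:
                        # unassigned background: an independent genotype that
                        # replays the same gain process on its own
                        history = _pseudo_history(
                            rng, day, config, pool_genes, pair_members, pair_rates, index, neutral_event
                        )
                        truth.lineage_of_clone[clone_id] = None
                    clone = Clone(clone_id, pop, int(day))
                    seen_keys = set()
                    labels = []
                    for t, key, mclass in history:
                        if key in seen_keys:
                            continue
                        seen_keys.add(key)
                        rec = MutationRecord(
                            clone_id=clone_id, population=pop, day=int(day),
                            position=key[0], ref_allele=key[1], alt_allele=key[2],
                            mutation_class=mclass,
                        )
                        clone.mutations.append(rec)
                        records.append(rec)
                        labels.append(rec.label)
                    truth.acquisition_history[clone_id] = labels
                    clones.append(clone)

    return SimResult(config, genes, genome, records, clones, truth)


math_inf = float("inf")


def _pseudo_history(rng, day, config, pool_genes, pair_members, pair_rates, index, neutral_event):
    """Independent single-clone genotype for the unassigned background."""
    events = []
    gain_time: dict[int, float | None] = {}
    for gi in range(len(pool_genes)):
        if gi in pair_members and pair_members[gi][1] == 1:
            continue
        rate = pair_rates.get(gi, config.adaptive_gain_rate)
        gain_time[gi] = _sample_truncated_exp(rng, rate, day)
    for gi in range(len(pool_genes)):
        if gi not in pair_members or pair_members[gi][1] != 1:
            continue
        pi, _, s = pair_members[gi]
        ia = config.contingent_pairs[pi][0]
        rate = pair_rates.get(gi, config.adaptive_gain_rate)
        t_a = gain_time.get(ia)
        t_a = math_inf if t_a is None else t_a
        t1 = rng.exponential(1.0 / ((1 - s) * rate)) if (1 - s) * rate > 0 else math_inf
        t_b = t1 if t1 <= t_a else t_a + rng.exponential(1.0 / rate)
        gain_time[gi] = t_b if t_b <= day else None
    for gi, t in gain_time.items():
        if t is None:
            continue
        position, ref, alt = _random_nonsyn_snp(pool_genes[gi], index, rng)
        events.append((t, (position, ref, alt), "SNP"))
    n_neutral = rng.poisson(config.neutral_rate * day)
    for t in rng.uniform(0, day, size=n_neutral):
        events.append(neutral_event(float(t)))
    events.sort(key=lambda e: e[0])
    return events


# ---------------------------------------------------------------------------
# serialization

def write_mutation_table(result: SimResult, path: str | Path) -> None:
    """Emit the mutation-table TSV dialect consumed by core_io."""
    with open(path, "w") as fh:
        fh.write("clone_id\tpopulation\tday\tposition\tref\talt\tclass\n")
        for rec in result.records:
            fh.write(
                f"{rec.clone_id}\t{rec.population}\t{rec.day}\t{rec.position}\t"
                f"{rec.ref_allele}\t{rec.alt_allele}\t{rec.mutation_class}\n"
            )


def write_clone_manifest(result: SimResult, path: str | Path) -> None:
    """Emit the clone manifest (keeps mutation-free clones discoverable)."""
    with open(path, "w") as fh:
        fh.write("clone_id\tpopulation\tday\n")
        for clone in result.clones:
            fh.write(f"{clone.clone_id}\t{clone.population}\t{clone.day}\n")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        data = json.load(fh)
    data["planted_pairs"] = [tuple(p) for p in data["planted_pairs"]]
    return GroundTruth(**data)
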