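"""Clonal lineage reconstruction within LTSP populations.

The method treats each clone's (frequency-filtered) mutation list as a string
of single characters in a canonical order, measures genetic distance between
clones with the Levenshtein metric, attaches each clone to its closest
earlier-or-same-day clone, and cuts the resulting per-population phylogeny
into lineages founded by mutations that reached at least 30% frequency at
some sampling day. Clones outside every lineage are collected in a
per-population pseudo-lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Clone

FREQUENCY_THRESHOLD = 0.30

MutKey = tuple[int, str, str]


def pseudo_lineage_id(population: str) -> str:
    return f"{population}/pseudo"


@dataclass
class Lineage:
    lineage_id: str
    population: str
    founding_key: MutKey | None
    founding_label: str
    member_clone_ids: list[str] = field(default_factory=list)
    first_day: int | None = None
    last_day: int | None = None
    is_pseudo: bool = False


@dataclass
class PhylogenyEdge:
    parent_id: str  # clone id, or the population root
    child_id: str
    distance: int


def population_root(population: str) -> str:
    return f"{population}/root"


def mutation_frequencies(clones: Sequence[Clone]) -> pd.DataFrame:
    """Per (population, day, mutation) carrier frequency among sequenced clones."""
    rows = []
    by_pop_day: dict[tuple[str, int], list[Clone]] = {}
    for c in clones:
        by_pop_day.setdefault((c.population, c.day), []).append(c)
    for (pop, day), group in sorted(by_pop_day.items()):
        n = len(group)
        counts: dict[MutKey, int] = {}
        for c in group:
            for key in c.mutation_keys:
                counts[key] = counts.get(key, 0) + 1
        for key, k in counts.items():
            rows.append({"population": pop, "day": day, "position": key[0],
                         "ref": key[1], "alt": key[2], "frequency": k / n})
    return pd.DataFrame(rows, columns=["population", "day", "position", "ref", "alt", "frequency"])


def qualifying_mutations(
    freqs: pd.DataFrame, threshold: float = FREQUENCY_THRESHOLD
) -> dict[str, set[MutKey]]:
    """Mutations reaching ``threshold`` frequency at any day, per population."""
    out: dict[str, set[MutKey]] = {}
    if freqs.empty:
        return out
    hi = freqs[freqs["frequency"] >= threshold]
    for row in hi.itertuples(index=False):
        out.setdefault(str(row.population), set()).add((int(row.position), str(row.ref), str(row.alt)))
    return out


def canonical_symbols(keys: Iterable[MutKey]) -> dict[MutKey, int]:
    """Stable mutation -> symbol mapping, ordered by (position, alt allele)."""
    ordered = sorted(set(keys), key=lambda k: (k[0], k[2], k[1]))
    return {k: i for i, k in enumerate(ordered)}


def to_symbol_string(mutations: Iterable[MutKey], symbols: Mapping[MutKey, int]) -> list[int]:
    return sorted(symbols[k] for k in mutations if k in symbols)


def levenshtein(a: Sequence[int], b: Sequence[int]) -> int:
    """Edit distance (unit-cost insert/delete/substitute) between symbol strings."""
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    b_arr = np.asarray(b)
    idx = np.arange(len(b) + 1)
    prev = idx.copy()
    for i, ca in enumerate(a, start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        cur[1:] = np.minimum(prev[:-1] + (b_arr != ca), prev[1:] + 1)
        # close under deletions: cur[j] = min_{k<=j} cur[k] + (j - k)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


def clone_symbol_strings(
    clones: Sequence[Clone], filtered: set[MutKey]
) -> tuple[dict[str, list[int]], dict[MutKey, int]]:
    """Canonical symbol strings of each clone, restricted to filtered mutations."""
    symbols = canonical_symbols(filtered)
    strings = {c.clone_id: to_symbol_string(c.mutation_keys & filtered, symbols) for c in clones}
    return strings, symbols


def infer_parents(
    clones: Sequence[Clone], strings: Mapping[str, list[int]]
) -> list[PhylogenyEdge]:
    """Attach each clone to its Levenshtein-closest earlier clone.

    Candidates are clones of the same population ordered strictly before the
    focal clone by (day, clone id); the ordering keeps parent-child edges
    day-monotone and the graph acyclic. Ties are broken by earlier day, then
    larger shared-mutation count, then lexicographic clone id. Clones with no
    candidates attach to the population root (empty mutation set).
    """
    ordered = sorted(clones, key=lambda c: (c.day, c.clone_id))
    sets = {cid: frozenset(s) for cid, s in strings.items()}
    edges: list[PhylogenyEdge] = []
    for i, clone in enumerate(ordered):
        s = strings[clone.clone_id]
        s_set = sets[clone.clone_id]
        root = population_root(clone.population)
        # the root is the population's day-0 ancestor (empty genotype); at
        # equal distance the earlier-day rule makes it win over any clone
        best_key: tuple = (len(s), 0, 0, "")
        best_id = root
        for cand in ordered[:i]:
            t = strings[cand.clone_id]
            t_set = sets[cand.clone_id]
            if t_set <= s_set or s_set <= t_set:
                # canonical order: containment => distance = size difference
                d = abs(len(s) - len(t))
            else:
                d = levenshtein(s, t)
            key = (d, cand.day, -len(s_set & t_set), cand.clone_id)
            if key < best_key:
                best_key = key
                best_id = cand.clone_id
        edges.append(PhylogenyEdge(best_id, clone.clone_id, best_key[0]))
    return edges


def define_lineages(
    clones: Sequence[Clone],
    edges: Sequence[PhylogenyEdge],
    qualifying: set[MutKey],
    strings: Mapping[str, list[int]],
    symbols: Mapping[MutKey, int],
    freqs: pd.DataFrame,
    population: str,
) -> tuple[list[Lineage], dict[str, str]]:
    """Cut one population's phylogeny into lineages.

    Walking down from the population root, the first edge that introduces a
    qualifying (>= 30% peak frequency) mutation opens a lineage comprising the
    whole subtree below it; deeper qualifying acquisitions inside an open
    lineage do not spawn sub-lineages. Lineages whose members span fewer than
    two distinct sampling days are dissolved (their clones become eligible
    for deeper lineage starts, or fall to the pseudo-lineage). When several
    qualifying mutations are introduced on the same founding edge, the one
    with the highest peak frequency (ties: smallest (position, alt)) names
    the lineage and the rest are co-founders.
    """
    clone_by_id = {c.clone_id: c for c in clones}
    children: dict[str, list[str]] = {}
    for e in edges:
        children.setdefault(e.parent_id, []).append(e.child_id)

    sym_to_key = {v: k for k, v in symbols.items()}
    qual_syms = {symbols[k] for k in qualifying if k in symbols}

    peak: dict[MutKey, float] = {}
    if not freqs.empty:
        sub = freqs[freqs["population"].astype(str) == str(population)]
        for row in sub.itertuples(index=False):
            key = (int(row.position), str(row.ref), str(row.alt))
            peak[key] = max(peak.get(key, 0.0), float(row.frequency))

    lineages: list[Lineage] = []
    assignment: dict[str, str] = {}

    def subtree_ids(node: str) -> list[str]:
        out = [node]
        stack = list(children.get(node, []))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(children.get(n, []))
        return out

    # candidate subtrees, each opened at the first qualifying acquisition on
    # a root-to-leaf walk: (chosen founding key, member clone ids)
    candidates: list[tuple[MutKey, list[str]]] = []

    def walk(node: str, parent_syms: set[int]) -> None:
        node_syms = set(strings[node])
        acquired = (node_syms - parent_syms) & qual_syms
        if acquired:
            founders = sorted(
                (sym_to_key[s] for s in acquired),
                key=lambda k: (-peak.get(k, 0.0), k[0], k[2]),
            )
            candidates.append((founders[0], subtree_ids(node)))
            return
        for child in children.get(node, []):
            walk(child, node_syms)

    root = population_root(population)
    for child in children.get(root, []):
        walk(child, set())

    # independent subtrees founded by the same mutation are one lineage
    # (apparent re-acquisitions of an established founder are artifacts of
    # attaching distant clones to the root)
    by_founder: dict[MutKey, list[str]] = {}
    for fkey, member_ids in candidates:
        by_founder.setdefault(fkey, []).extend(member_ids)
    for fkey in sorted(by_founder, key=lambda k: (-peak.get(k, 0.0), k[0], k[2])):
        member_ids = by_founder[fkey]
        days = {clone_by_id[m].day for m in member_ids}
        if len(days) < 2:
            continue
        lid = f"{population}/L{len(lineages) + 1}"
        lineages.append(Lineage(
            lineage_id=lid,
            population=population,
            founding_key=fkey,
            founding_label=f"{fkey[0]}:{fkey[1]}>{fkey[2]}",
            member_clone_ids=sorted(member_ids),
            first_day=min(days),
            last_day=max(days),
        ))
        for m in member_ids:
            assignment[m] = lid

    pseudo = Lineage(
        lineage_id=pseudo_lineage_id(population),
        population=population,
        founding_key=None,
        founding_label="pseudo",
        is_pseudo=True,
    )
    for c in clones:
        if c.clone_id not in assignment:
            assignment[c.clone_id] = pseudo.lineage_id
            pseudo.member_clone_ids.append(c.clone_id)
    if pseudo.member_clone_ids:
        days = {clone_by_id[m].day for m in pseudo.member_clone_ids}
        pseudo.first_day, pseudo.last_day = min(days), max(days)
        lineages.append(pseudo)
    for c in clones:
        c.lineage_id = assignment[c.clone_id]
    return lineages, assignment


@dataclass
class PopulationPhylogeny:
    population: str
    edges: list[PhylogenyEdge]
    lineages: list[Lineage]
    assignment: dict[str, str]
    parent_of: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.parent_of = {e.child_id: e.parent_id for e in self.edges}

    def ancestor_chain(self, clone_id: str) -> list[str]:
        """Clone ids from the immediate parent up to (excluding) the root."""
        root = population_root(self.population)
        chain = []
        cur = self.parent_of.get(clone_id)
        while cur is not None and cur != root:
            chain.append(cur)
            cur = self.parent_of.get(cur)
        return chain


def reconstruct_population(
    clones: Sequence[Clone],
    freqs: pd.DataFrame,
    population: str,
    threshold: float = FREQUENCY_THRESHOLD,
) -> PopulationPhylogeny:
    """Full per-population reconstruction: filter, distances, parents, lineages."""
    pop_clones = [c for c in clones if str(c.population) == str(population)]
    qualifying = qualifying_mutations(freqs, threshold).get(str(population), set())
    strings, symbols = clone_symbol_strings(pop_clones, qualifying)
    edges = infer_parents(pop_clones, strings)
    lineages, assignment = define_lineages(
        pop_clones, edges, qualifying, strings, symbols, freqs, str(population)
    )
    return PopulationPhylogeny(str(population), edges, lineages, assignment)


def reconstruct_all(
    clones: Sequence[Clone], threshold: float = FREQUENCY_THRESHOLD
) -> dict[str, PopulationPhylogeny]:
    freqs = mutation_frequencies(clones)
    pops = sorted({str(c.population) for c in clones})
    return {p: reconstruct_population(clones, freqs, p, threshold) for p in pops}


def muller_table(phylogenies: Mapping[str, PopulationPhylogeny], clones: Sequence[Clone]) -> pd.DataFrame:
    """Per population-day relative lineage frequencies (rows sum to 1 per day)."""
    clone_by_id = {c.clone_id: c for c in clones}
    rows = []
    for pop, phylo in sorted(phylogenies.items()):
        pop_clones = [c for c in clones if str(c.population) == pop]
        days = sorted({c.day for c in pop_clones})
        lineage_ids = [l.lineage_id for l in phylo.lineages]
        for day in days:
            day_clones = [c for c in pop_clones if c.day == day]
            n = len(day_clones)
            for lid in lineage_ids:
                k = sum(1 for c in day_clones if phylo.assignment[c.clone_id] == lid)
                rows.append({"population": pop, "day": day, "lineage": lid, "frequency": k / n})
    return pd.DataFrame(rows, columns=["population", "day", "lineage", "frequency"])


def lineage_table(phylogenies: Mapping[str, PopulationPhylogeny]) -> pd.DataFrame:
    rows = []
    for pop, phylo in sorted(phylogenies.items()):
        for lin in phylo.lineages:
            rows.append({
                "lineage": lin.lineage_id,
                "population": lin.population,
                "founding_mutation": lin.founding_label,
                "n_clones": len(lin.member_clone_ids),
                "first_day": lin.first_day,
                "last_day": lin.last_day,
                "is_pseudo": lin.is_pseudo,
            })
    return pd.DataFrame(rows)


def assignment_fraction(phylogenies: Mapping[str, PopulationPhylogeny]) -> float:
    """Fraction of clones assigned to a non-pseudo lineage."""
    assigned = total = 0
    for phylo in phylogenies.values():
        pseudo = pseudo_lineage_id(phylo.population)
        for cid, lid in phylo.assignment.items():
            total += 1
            if lid != pseudo:
                assigned += 1
    return assigned / total if total else float("nan")
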