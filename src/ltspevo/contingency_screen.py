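"""Cross-lineage screen for putatively contingent loci pairs.

For every candidate pair of convergently mutated loci a lineage-level 2x2
table is built: a = units containing a clone mutated in both loci, b = units
containing a clone mutated in the first locus only, c = second locus only,
d = units containing a clone mutated in neither. A unit (lineage or
pseudo-lineage; mutator lineages excluded) may contribute to several cells
simultaneously. Association strength is measured with Yule's Q, Yule's
coefficient of colligation Y and the phi coefficient, tested one-sided for
positive association with Benjamini-Hochberg FDR control, filtered by
functional-association-optimized cutoffs, and resolved for directionality by
walking ancestor chains of double-mutant clones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import Clone, FunctionalPairTable
from .lineage_inference import PopulationPhylogeny

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_LOCI = ("rpoB", "rpoC")


@dataclass
class PairTable:
    locus_a: str
    locus_b: str
    a: int  # units with a clone mutated in both
    b: int  # units with a clone mutated in A only
    c: int  # units with a clone mutated in B only
    d: int  # units with a clone mutated in neither
    units: tuple[str, ...] = ()


@dataclass
class DirectionEvidence:
    locus_a: str
    locus_b: str
    per_unit: dict[str, str] = field(default_factory=dict)  # unit -> a_first|b_first|together|conflicting
    call: str = "n/a"  # A_first | B_first | always_together | ambiguous | n/a


# ---------------------------------------------------------------------------
# units

def screen_units(
    clones: Sequence[Clone],
    phylogenies: Mapping[str, PopulationPhylogeny],
    exclude_mutator_lineages: bool = True,
) -> dict[str, list[Clone]]:
    """Unit -> non-mutator clone roster for the association screen.

    Units are the lineages and pseudo-lineages of all populations. A lineage
    is a mutator lineage (excluded together with all its clones) when the
    majority of its members are mutators; individual mutator clones are
    dropped from the remaining units as well.
    """
    clone_by_id = {c.clone_id: c for c in clones}
    units: dict[str, list[Clone]] = {}
    for phylo in phylogenies.values():
        for lin in phylo.lineages:
            members = [clone_by_id[cid] for cid in lin.member_clone_ids]
            if exclude_mutator_lineages and members:
                mut_frac = sum(c.is_mutator for c in members) / len(members)
                if not lin.is_pseudo and mut_frac > 0.5:
                    continue
            roster = [c for c in members if not c.is_mutator]
            if roster:
                units[lin.lineage_id] = roster
    return units


# ---------------------------------------------------------------------------
# pair enumeration and tables

def enumerate_candidate_pairs(
    convergent: Iterable[str],
    units: Mapping[str, Sequence[Clone]],
    min_units: int = 2,
    exclude_loci: Sequence[str] = DEFAULT_EXCLUDED_LOCI,
) -> list[tuple[str, str]]:
    """Pairs of convergent loci co-mutated within single clones in >= min_units units."""
    excluded = set(exclude_loci)
    loci = sorted(set(convergent) - excluded - {"unassigned"})
    co_units: dict[tuple[str, str], set[str]] = {}
    locus_set = set(loci)
    for unit, roster in units.items():
        for clone in roster:
            hit = sorted(clone.loci & locus_set)
            for pair in combinations(hit, 2):
                co_units.setdefault(pair, set()).add(unit)
    return sorted(pair for pair, us in co_units.items() if len(us) >= min_units)


def build_pair_table(
    pair: tuple[str, str], units: Mapping[str, Sequence[Clone]]
) -> PairTable:
    """Lineage-level 2x2 co-occurrence counts for one loci pair."""
    if not units:
        raise ValueError("empty unit roster")
    la, lb = pair
    a = b = c = d = 0
    for unit, roster in units.items():
        has_both = has_a = has_b = has_none = False
        for clone in roster:
            in_a = la in clone.loci
            in_b = lb in clone.loci
            if in_a and in_b:
                has_both = True
            elif in_a:
                has_a = True
            elif in_b:
                has_b = True
            else:
                has_none = True
        a += has_both
        b += has_a
        c += has_b
        d += has_none
    return PairTable(la, lb, a, b, c, d, tuple(sorted(units)))


# ---------------------------------------------------------------------------
# Yule coefficients and tests

def yule_coefficients(table: PairTable) -> tuple[float, float, float]:
    """Yule's Q, Yule's colligation Y, and the phi coefficient.

    Q = (ad - bc) / (ad + bc); Y = (sqrt(ad) - sqrt(bc)) / (sqrt(ad) + sqrt(bc));
    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)). Undefined values (zero
    denominators) are returned as nan.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    ad, bc = a * d, b * c
    q = (ad - bc) / (ad + bc) if ad + bc > 0 else math.nan
    sq_ad, sq_bc = math.sqrt(ad), math.sqrt(bc)
    y = (sq_ad - sq_bc) / (sq_ad + sq_bc) if sq_ad + sq_bc > 0 else math.nan
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    phi = (ad - bc) / math.sqrt(denom) if denom > 0 else math.nan
    return q, y, phi


def _one_sided_p(table: PairTable) -> tuple[float, float, float]:
    """One-sided large-sample p-values for positive association (Q, Y, phi).

    The z statistic is coefficient / SE with the classical large-sample
    standard errors: SE_Q = (1-Q^2)/2 * r, SE_Y = (1-Y^2)/4 * r with
    r = sqrt(1/a + 1/b + 1/c + 1/d); for phi the null SE 1/sqrt(n) is used
    (z = phi * sqrt(n), the chi-square test of association). Whenever any
    cell is 0, 0.5 is added to every cell for the SE computation only; the
    reported coefficients stay on raw counts.
    """
    q, y, phi = yule_coefficients(table)
    cells = [table.a, table.b, table.c, table.d]
    if min(cells) == 0:
        sa, sb, sc, sd = (v + 0.5 for v in cells)
    else:
        sa, sb, sc, sd = map(float, cells)
    r = math.sqrt(1 / sa + 1 / sb + 1 / sc + 1 / sd)
    # SE factors from the continuity-corrected table, so bc=0 does not
    # collapse the SE to zero
    qc, yc, _ = yule_coefficients(PairTable("", "", sa, sb, sc, sd))

    def upper_p(coef: float, se: float) -> float:
        if math.isnan(coef):
            return 1.0
        if se <= 0:
            return 0.0 if coef > 0 else 1.0
        return float(stats.norm.sf(coef / se))

    p_q = upper_p(q, (1 - qc * qc) / 2 * r)
    p_y = upper_p(y, (1 - yc * yc) / 4 * r)
    n = sum(cells)
    p_phi = upper_p(phi, 1 / math.sqrt(n)) if n > 0 else 1.0
    return p_q, p_y, p_phi


def test_association(
    tables: Sequence[PairTable], alpha: float = 0.05
) -> pd.DataFrame:
    """Coefficients, one-sided p-values and BH/FDR decisions for all pairs."""
    rows = []
    for t in tables:
        q, y, phi = yule_coefficients(t)
        p_q, p_y, p_phi = _one_sided_p(t)
        rows.append({
            "locus_a": t.locus_a, "locus_b": t.locus_b,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "Q": q, "Y": y, "phi": phi,
            "p_Q": p_q, "p_Y": p_y, "p_phi": p_phi,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        for col in ["sig_Q", "sig_Y", "sig_phi"]:
            df[col] = pd.Series(dtype=bool)
        return df
    for coef in ("Q", "Y", "phi"):
        reject, q_adj, _, _ = multipletests(df[f"p_{coef}"], alpha=alpha, method="fdr_bh")
        df[f"q_{coef}"] = q_adj
        df[f"sig_{coef}"] = reject
    return df


def select_thresholds(
    results: pd.DataFrame,
    functional: FunctionalPairTable,
    coefficients: Sequence[str] = ("Q", "Y"),
) -> dict[str, float]:
    """Per-coefficient cutoff maximizing the functional fraction above it.

    Scans the sorted distinct values of each coefficient among its
    FDR-significant pairs and returns the cutoff at which the highest
    fraction of above-cutoff pairs carries a known functional association;
    ties resolve to the lowest such cutoff.
    """
    if len(functional) == 0:
        logger.warning("empty functional table: threshold selection skipped")
        return {}
    cutoffs: dict[str, float] = {}
    for coef in coefficients:
        sig = results[results[f"sig_{coef}"] & results[coef].notna()]
        if sig.empty:
            continue
        vals = sig[coef].to_numpy()
        is_func = np.array([
            (ra, rb) in functional for ra, rb in zip(sig["locus_a"], sig["locus_b"])
        ])
        best_cut, best_frac = None, -1.0
        for cut in sorted(np.unique(vals)):
            mask = vals >= cut
            frac = is_func[mask].mean()
            if frac > best_frac + 1e-12:
                best_frac, best_cut = frac, float(cut)
        cutoffs[coef] = best_cut
    return cutoffs


def consensus_reliable_pairs(
    results: pd.DataFrame, q_cutoff: float = 0.8, y_cutoff: float = 0.5
) -> pd.DataFrame:
    """Pairs FDR-significant for phi that also clear the Q and Y cutoffs."""
    if results.empty:
        return results
    mask = (
        results["sig_phi"]
        & results["sig_Q"] & (results["Q"] >= q_cutoff)
        & results["sig_Y"] & (results["Y"] >= y_cutoff)
    )
    return results[mask].copy()


# ---------------------------------------------------------------------------
# functional-association randomization

def functional_enrichment_randomization(
    pairs: Sequence[tuple[str, str]],
    candidate_loci: Sequence[str],
    functional: FunctionalPairTable,
    n_rand: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Observed functional fraction of ``pairs`` and its randomization p-value.

    Each of ``n_rand`` randomizations draws ``len(pairs)`` distinct unordered
    pairs from ``candidate_loci``; p = (1 + #{randomized fraction >= observed})
    / (n_rand + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = sorted(set(candidate_loci))
    n_pairs = len(pairs)
    n_possible = len(loci) * (len(loci) - 1) // 2
    if n_pairs > n_possible:
        raise ValueError(f"cannot draw {n_pairs} distinct pairs from {len(loci)} loci")
    observed = sum(1 for p in pairs if p in functional) / n_pairs if n_pairs else 0.0
    if n_pairs == 0:
        return observed, 1.0
    exceed = 0
    for _ in range(n_rand):
        drawn: set[frozenset] = set()
        while len(drawn) < n_pairs:
            i, j = rng.choice(len(loci), size=2, replace=False)
            drawn.add(frozenset((loci[i], loci[j])))
        frac = sum(1 for p in drawn if tuple(p)[:2] in functional) / n_pairs
        if frac >= observed - 1e-12:
            exceed += 1
    return observed, (1 + exceed) / (n_rand + 1)


# ---------------------------------------------------------------------------
# directionality

def infer_directionality(
    pair: tuple[str, str],
    units: Mapping[str, Sequence[Clone]],
    phylogenies: Mapping[str, PopulationPhylogeny],
    clones: Sequence[Clone],
) -> DirectionEvidence:
    """Which member of a contingent pair is mutated first, per unit and combined.

    Only units containing a double-mutant clone are informative. Within such
    a unit the double mutant's ancestor chain is walked from the clone
    towards the root; the first ancestor carrying exactly one of the two
    loci determines which came first. If mutations at the two loci are never
    seen apart along any chain of the unit, the unit votes "together".
    Units that disagree make the combined call ambiguous; if no unit ever
    separates the mutations the call is always_together.
    """
    la, lb = pair
    clone_by_id = {c.clone_id: c for c in clones}
    ev = DirectionEvidence(la, lb)
    for unit, roster in units.items():
        doubles = [c for c in roster if la in c.loci and lb in c.loci]
        if not doubles:
            continue
        phylo = phylogenies[str(doubles[0].population)]
        votes = set()
        for clone in doubles:
            for anc_id in phylo.ancestor_chain(clone.clone_id):
                anc = clone_by_id[anc_id]
                in_a, in_b = la in anc.loci, lb in anc.loci
                if in_a != in_b:
                    votes.add("a_first" if in_a else "b_first")
                    break
            else:
                votes.add("together")
        directed = votes - {"together"}
        if len(directed) > 1:
            ev.per_unit[unit] = "conflicting"
        elif directed:
            ev.per_unit[unit] = directed.pop()
        else:
            ev.per_unit[unit] = "together"
    calls = set(ev.per_unit.values())
    directed_calls = calls & {"a_first", "b_first"}
    if not ev.per_unit:
        ev.call = "n/a"
    elif "conflicting" in calls or len(directed_calls) > 1:
        ev.call = "ambiguous"
    elif directed_calls:
        ev.call = "A_first" if directed_calls.pop() == "a_first" else "B_first"
    else:
        ev.call = "always_together"
    return ev


def directionality_table(evidence: Sequence[DirectionEvidence]) -> pd.DataFrame:
    rows = [{
        "locus_a": e.locus_a,
        "locus_b": e.locus_b,
        "direction": e.call,
        "n_informative_units": len(e.per_unit),
    } for e in evidence]
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "direction", "n_informative_units"])


def contingency_network(results: pd.DataFrame, evidence: Mapping[tuple[str, str], DirectionEvidence]) -> pd.DataFrame:
    """Semi-directed edge list: first-mutated locus -> second, or undirected."""
    rows = []
    for row in results.itertuples(index=False):
        pair = (row.locus_a, row.locus_b)
        ev = evidence.get(pair)
        call = ev.call if ev else "n/a"
        if call == "B_first":
            src, dst = row.locus_b, row.locus_a
        else:
            src, dst = row.locus_a, row.locus_b
        rows.append({"locus_A": src, "locus_B": dst,
                     "direction": "directed" if call in ("A_first", "B_first") else call})
    return pd.DataFrame(rows, columns=["locus_A", "locus_B", "direction"])


# ---------------------------------------------------------------------------
# locus <-> lineage-defining (RNAPC-style) mutation association

def rnapc_locus_association(
    clones: Sequence[Clone],
    phylogenies: Mapping[str, PopulationPhylogeny],
    founding_loci: Sequence[str] | None = None,
    merge_groups: Mapping[str, Sequence[str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association between loci and specific lineage-defining mutations.

    Each unit (lineage or pseudo-lineage, mutator lineages and clones
    included) either was or was not founded by a given defining mutation;
    a locus is mutated in the unit when any member clone carries it. This
    yields one ordinary 2x2 table per (locus, defining mutation) pair.
    ``merge_groups`` maps an entity name to loci counted as one (default:
    mismatch_repair = mutS + mutL + mutH).
    """
    if merge_groups is None:
        merge_groups = {"mismatch_repair": ("mutS", "mutL", "mutH")}
    group_of: dict[str, str] = {}
    for entity, members in merge_groups.items():
        for m in members:
            group_of[m] = entity

    clone_by_id = {c.clone_id: c for c in clones}
    unit_founding: dict[str, str | None] = {}
    unit_loci: dict[str, set[str]] = {}
    for phylo in phylogenies.values():
        for lin in phylo.lineages:
            label = None if lin.is_pseudo else lin.founding_label
            unit_founding[lin.lineage_id] = label
            loci = set()
            for cid in lin.member_clone_ids:
                loci |= {group_of.get(l, l) for l in clone_by_id[cid].loci}
            unit_loci[lin.lineage_id] = loci

    founding_labels = sorted({l for l in unit_founding.values() if l is not None})
    founding_locus_set = set(founding_loci or ())
    loci = sorted({l for s in unit_loci.values() for l in s} - founding_locus_set - {"unassigned"})
    tables = []
    for label in founding_labels:
        for locus in loci:
            a = b = c = d = 0
            for unit in unit_founding:
                has_label = unit_founding[unit] == label
                has_locus = locus in unit_loci[unit]
                if has_locus and has_label:
                    a += 1
                elif has_locus:
                    b += 1
                elif has_label:
                    c += 1
                else:
                    d += 1
            tables.append(PairTable(locus, f"founder:{label}", a, b, c, d))
    df = test_association(tables, alpha=alpha)
    return df
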