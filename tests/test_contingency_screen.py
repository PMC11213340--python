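"""Pair tables, Yule coefficients, significance testing, thresholds,
randomization enrichment, directionality, and founder associations."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from ltspevo.core_io import Clone, FunctionalPairTable, MutationRecord
from ltspevo import contingency_screen as cs
from ltspevo import lineage_inference as li


def yule_oracle(a, b, c, d):
    """Direct evaluation of the three printed formulas."""
    ad, bc = a * d, b * c
    q = (ad - bc) / (ad + bc)
    y = (math.sqrt(ad) - math.sqrt(bc)) / (math.sqrt(ad) + math.sqrt(bc))
    phi = (ad - bc) / math.sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return q, y, phi


def table(a, b, c, d):
    return cs.PairTable("A", "B", a, b, c, d)


def test_yule_known_values():
    q, y, phi = cs.yule_coefficients(table(5, 0, 0, 15))
    assert (q, y) == (1.0, 1.0)
    q, y, phi = cs.yule_coefficients(table(2, 2, 2, 2))
    assert (q, y, phi) == (0.0, 0.0, 0.0)
    q, y, phi = cs.yule_coefficients(table(6, 1, 2, 11))
    assert q == pytest.approx(64 / 68)
    assert y == pytest.approx((math.sqrt(66) - math.sqrt(2)) / (math.sqrt(66) + math.sqrt(2)))
    assert phi == pytest.approx(64 / math.sqrt(7 * 13 * 8 * 12))


def test_yule_undefined_flagged_not_raised():
    q, y, phi = cs.yule_coefficients(table(0, 0, 0, 0))
    assert math.isnan(q) and math.isnan(y) and math.isnan(phi)


def test_yule_identity_and_ordering_sweep():
    """Q = 2Y/(1+Y^2) always; |phi| <= |Q| on all-positive tables."""
    rng = np.random.default_rng(1)
    for _ in range(2000):
        a, b, c, d = rng.integers(1, 30, size=4)
        q, y, phi = cs.yule_coefficients(table(a, b, c, d))
        assert q == pytest.approx(2 * y / (1 + y * y), abs=1e-9)
        assert abs(phi) <= abs(q) + 1e-12
        if a * d != b * c:
            assert np.sign(q) == np.sign(y) == np.sign(phi)


def test_yule_permutation_symmetry():
    rng = np.random.default_rng(2)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 20, size=4)
        fwd = cs.yule_coefficients(table(a, b, c, d))
        swp = cs.yule_coefficients(table(a, c, b, d))
        for x, y_ in zip(fwd, swp):
            assert (math.isnan(x) and math.isnan(y_)) or x == pytest.approx(y_)


def unit(*clone_specs):
    """Build a unit roster from (cid, loci) specs."""
    out = []
    for cid, loci in clone_specs:
        c = Clone(cid, "1", 11)
        for i, locus in enumerate(loci):
            rec = MutationRecord(cid, "1", 11, 100 + i, "A", "G", "SNP")
            rec.locus_id = locus
            c.mutations.append(rec)
        out.append(c)
    return out


def test_build_pair_table_multi_category_unit():
    """A unit holding both a double mutant and an A-only clone feeds a and b."""
    units = {"u1": unit(("x", ["A", "B"]), ("y", ["A"]))}
    t = cs.build_pair_table(("A", "B"), units)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 0)


def test_build_pair_table_toy_partition():
    units = {
        "u1": unit(("x", ["A", "B"])),
        "u2": unit(("y", ["A"])),
        "u3": unit(("z", ["B"])),
        "u4": unit(("w", [])),
    }
    t = cs.build_pair_table(("A", "B"), units)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    absent = cs.build_pair_table(("Q", "R"), units)
    assert (absent.a, absent.b, absent.c, absent.d) == (0, 0, 0, 4)
    with pytest.raises(ValueError):
        cs.build_pair_table(("A", "B"), {})


def test_enumerate_candidate_pairs_rules():
    units = {
        "u1": unit(("c1", ["A", "B"]), ("c2", ["A", "C"])),
        "u2": unit(("c3", ["A", "B"]), ("c4", ["rpoB", "A"])),
        "u3": unit(("c5", ["B", "C"])),
    }
    convergent = ["A", "B", "C", "rpoB"]
    pairs = cs.enumerate_candidate_pairs(convergent, units)
    assert ("A", "B") in pairs          # co-mutated in u1 and u2
    assert ("A", "C") not in pairs      # single unit only
    assert all("rpoB" not in p for p in pairs)


def test_one_sided_test_at_independence():
    df = cs.test_association([table(2, 2, 2, 2)])
    row = df.iloc[0]
    assert row.p_Q == pytest.approx(0.5)
    assert row.p_Y == pytest.approx(0.5)
    assert row.p_phi == pytest.approx(0.5)


def test_bh_decisions_match_hand_computation():
    """FDR decisions equal the hand rule: reject ranks 1..k*, k* = max{i: p_(i) <= i*alpha/m}.

    (For p = {0.01, 0.02, 0.04} and m = 3 the thresholds are 0.0167, 0.0333
    and 0.05, so all three pass; the same hand rule is applied to the
    pipeline's own p-values here.)
    """
    assert _bh_by_hand([0.01, 0.02, 0.04], 0.05) == [True, True, True]
    rng = np.random.default_rng(7)
    tables = [table(*rng.integers(0, 15, size=4)) for _ in range(100)]
    df = cs.test_association(tables, alpha=0.05)
    for coef in ("Q", "Y", "phi"):
        assert df[f"sig_{coef}"].tolist() == _bh_by_hand(df[f"p_{coef}"].tolist(), 0.05)


def _bh_by_hand(pvals, alpha):
    order = np.argsort(pvals)
    m = len(pvals)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank * alpha / m:
            k_star = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            reject[idx] = True
    return reject


def test_fdr_nestedness():
    rng = np.random.default_rng(4)
    tables = [table(*rng.integers(0, 15, size=4)) for _ in range(300)]
    strict = cs.test_association(tables, alpha=0.01)
    loose = cs.test_association(tables, alpha=0.05)
    for coef in ("Q", "Y", "phi"):
        assert not (strict[f"sig_{coef}"] & ~loose[f"sig_{coef}"]).any()


def test_select_thresholds():
    df = pd.DataFrame({
        "locus_a": ["a", "a", "b", "b"],
        "locus_b": ["b", "c", "c", "d"],
        "Q": [0.9, 0.85, 0.6, 0.4],
        "Y": [0.7, 0.6, 0.3, 0.2],
        "sig_Q": [True] * 4,
        "sig_Y": [True] * 4,
    })
    functional = FunctionalPairTable([("a", "b"), ("a", "c")])
    cuts = cs.select_thresholds(df, functional)
    # functional pairs concentrate at Q >= 0.85: that cutoff scores 1.0
    assert cuts["Q"] == pytest.approx(0.85)
    # all-functional case: every cutoff scores 1, lowest returned
    all_func = FunctionalPairTable([("a", "b"), ("a", "c"), ("b", "c"), ("b", "d")])
    cuts2 = cs.select_thresholds(df, all_func)
    assert cuts2["Q"] == pytest.approx(0.4)
    assert cs.select_thresholds(df, FunctionalPairTable()) == {}


def test_consensus_requires_all_three():
    df = pd.DataFrame({
        "locus_a": ["a", "a"], "locus_b": ["b", "c"],
        "Q": [0.9, 0.9], "Y": [0.7, 0.4], "phi": [0.5, 0.5],
        "sig_Q": [True, True], "sig_Y": [True, True], "sig_phi": [True, True],
    })
    rel = cs.consensus_reliable_pairs(df, q_cutoff=0.8, y_cutoff=0.5)
    assert list(rel.locus_b) == ["b"]  # second pair fails only the Y cutoff


def test_functional_randomization_extremes():
    loci = [f"g{i}" for i in range(10)]
    everything = FunctionalPairTable(
        (loci[i], loci[j]) for i in range(10) for j in range(i + 1, 10)
    )
    pairs = [("g0", "g1"), ("g2", "g3")]
    obs, p = cs.functional_enrichment_randomization(pairs, loci, everything, n_rand=50, seed=0)
    assert obs == 1.0 and p == 1.0
    obs, p = cs.functional_enrichment_randomization(pairs, loci, FunctionalPairTable(), n_rand=50, seed=0)
    assert obs == 0.0 and p == 1.0
    with pytest.raises(ValueError):
        cs.functional_enrichment_randomization([("a", "b")] * 50, loci[:3], everything)


def test_functional_randomization_enriched_fixture():
    """Pairs 5x enriched for functional links come out significant."""
    rng = np.random.default_rng(8)
    loci = [f"g{i}" for i in range(30)]
    all_pairs = [(loci[i], loci[j]) for i in range(30) for j in range(i + 1, 30)]
    functional = FunctionalPairTable(
        p for p in all_pairs if rng.random() < 0.1
    )
    func_list = [p for p in all_pairs if p in functional]
    hits = [func_list[i] for i in rng.choice(len(func_list), size=10, replace=False)]
    background = [p for p in all_pairs if p not in functional]
    chosen = hits + [background[i] for i in rng.choice(len(background), size=10, replace=False)]
    obs, p = cs.functional_enrichment_randomization(chosen, loci, functional, n_rand=1000, seed=9)
    assert obs == pytest.approx(0.5)
    assert p <= 0.01


def _toy_phylo_units():
    """Three informative units; in each, {A} ancestor -> {A,B} descendant."""
    clones = []
    units = {}
    phylos = {}
    for u in range(3):
        pop = str(u + 1)
        anc = unit((f"anc{u}", ["A"]))[0]
        dec = unit((f"dec{u}", ["A", "B"]))[0]
        anc.population = dec.population = pop
        anc.day, dec.day = 11, 22
        clones += [anc, dec]
        units[f"L{u}"] = [anc, dec]
        edges = [
            li.PhylogenyEdge(li.population_root(pop), anc.clone_id, 1),
            li.PhylogenyEdge(anc.clone_id, dec.clone_id, 1),
        ]
        phylos[pop] = li.PopulationPhylogeny(pop, edges, [], {})
    return clones, units, phylos


def test_directionality_a_first():
    clones, units, phylos = _toy_phylo_units()
    ev = cs.infer_directionality(("A", "B"), units, phylos, clones)
    assert ev.call == "A_first"
    assert set(ev.per_unit.values()) == {"a_first"}
    # swapped pair orientation gives the mirrored call
    ev2 = cs.infer_directionality(("B", "A"), units, phylos, clones)
    assert ev2.call == "B_first"


def test_directionality_always_together():
    clones, units, phylos = _toy_phylo_units()
    for roster in units.values():
        roster[0].mutations = unit(("tmp", ["A", "B"]))[0].mutations  # ancestor double too
    ev = cs.infer_directionality(("A", "B"), units, phylos, clones)
    assert ev.call == "always_together"


def test_directionality_conflict_is_ambiguous():
    clones, units, phylos = _toy_phylo_units()
    # flip one unit's ancestor to B-only
    units["L2"][0].mutations[0].locus_id = "B"
    ev = cs.infer_directionality(("A", "B"), units, phylos, clones)
    assert ev.call == "ambiguous"


def test_directionality_no_informative_units():
    clones, units, phylos = _toy_phylo_units()
    ev = cs.infer_directionality(("A", "Z"), units, phylos, clones)
    assert ev.call == "n/a"


def test_screen_units_excludes_mutator_lineages(sim_default):
    from ltspevo.convergence import assign_loci
    from ltspevo.core_io import flag_mutators

    assign_loci(sim_default.records, sim_default.genes)
    flag_mutators(sim_default.clones, [sim_default.truth.mutator_gene_id])
    phylos = li.reconstruct_all(sim_default.clones)
    units = cs.screen_units(sim_default.clones, phylos)
    assert len(units) == 17  # 12 non-mutator lineages + 5 pseudo-lineages
    for roster in units.values():
        assert not any(c.is_mutator for c in roster)


def test_rnapc_association_perfect_mutator_link():
    """Mismatch-repair entity vs the founder that always hosts it: Q = 1."""
    lineages = []
    phylos = {}
    clones = []
    founders = ["F1", "F1", "F2", "F2", None]
    loci_sets = [["mutS", "x"], ["mutL"], ["y"], ["z"], ["w"]]
    for i, (fnd, loci) in enumerate(zip(founders, loci_sets)):
        pop = str(i + 1)
        c = unit((f"c{i}", loci))[0]
        c.population = pop
        clones.append(c)
        lin = li.Lineage(
            lineage_id=f"{pop}/L1" if fnd else li.pseudo_lineage_id(pop),
            population=pop,
            founding_key=(1, "A", "G") if fnd else None,
            founding_label=fnd or "pseudo",
            member_clone_ids=[c.clone_id],
            is_pseudo=fnd is None,
        )
        phylos[pop] = li.PopulationPhylogeny(pop, [], [lin], {c.clone_id: lin.lineage_id})
    df = cs.rnapc_locus_association(clones, phylos)
    row = df[(df.locus_a == "mismatch_repair") & (df.locus_b == "founder:F1")].iloc[0]
    assert (row.a, row.b, row.c, row.d) == (2, 0, 0, 3)
    assert row.Q == 1.0
    # a locus spread evenly shows no association
    sym = df[(df.locus_a == "x")].iloc[0]
    assert abs(sym.Q) <= 1.0
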