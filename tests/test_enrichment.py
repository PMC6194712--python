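import itertools

import numpy as np
import pandas as pd
import pytest

from cofracbench import enrichment as enr
from cofracbench.dataio import ComplexDatabase, Interactome


def hypergeom_enumeration_oracle(k, K, n, N):
    """P(X >= k) by exhaustive enumeration of all n-subsets of N items."""
    items = list(range(N))
    successes = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(items, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometricUpperTail:
    def test_k_zero_is_one(self):
        assert enr.hypergeometric_upper_tail(0, 5, 3, 10) == 1.0

    def test_closed_form_example(self):
        # drawing 3 of 10 with 4 successes, all 3 successes: C(4,3)/C(10,3)
        p = enr.hypergeometric_upper_tail(3, 4, 3, 10)
        assert p == pytest.approx(4 / 120, abs=1e-12)

    def test_matches_enumeration_small_populations(self):
        for N in range(1, 11):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        p = enr.hypergeometric_upper_tail(k, K, n, N)
                        oracle = hypergeom_enumeration_oracle(k, K, n, N)
                        assert p == pytest.approx(oracle, abs=1e-12)

    def test_monotone_decreasing_in_k(self):
        ps = [enr.hypergeometric_upper_tail(k, 10, 8, 30) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(5, 3, 4, 10), (1, 11, 3, 10), (-1, 3, 3, 10)])
    def test_bounds_rejected(self, args):
        with pytest.raises(ValueError):
            enr.hypergeometric_upper_tail(*args)


def toy_db():
    return ComplexDatabase.from_members(
        {"c1": ["A", "B", "C"], "c2": ["D", "E", "F", "G"], "c3": ["H", "I"]}
    )


class TestMapEdges:
    def test_counts_simple(self):
        it = Interactome.from_edges(
            "i1", "AP-MS", [("A", "B"), ("A", "C"), ("C", "D"), ("D", "E")]
        )
        rec = enr.map_edges_to_complexes(it, toy_db()).set_index("complex_id")
        assert rec.loc["c1", "n_pairs_possible"] == 3
        assert rec.loc["c1", "n_pairs_predicted"] == 2
        # c2: only D, E in universe
        assert rec.loc["c2", "n_pairs_possible"] == 1
        assert rec.loc["c2", "n_pairs_predicted"] == 1
        # c3 fully absent -> unobserved
        assert "c3" not in rec.index

    def test_matches_bruteforce_on_random_fixtures(self, rng):
        proteins = [f"P{i}" for i in range(30)]
        members = {
            f"c{i}": rng.choice(proteins, size=rng.integers(2, 7), replace=False)
            for i in range(12)
        }
        db = ComplexDatabase.from_members(members)
        all_pairs = list(itertools.combinations(proteins, 2))
        chosen = [all_pairs[i] for i in
                  rng.choice(len(all_pairs), size=60, replace=False)]
        it = Interactome.from_edges("i", "AP-MS", chosen)
        rec = enr.map_edges_to_complexes(it, db).set_index("complex_id")
        universe = it.proteins & db.protein_universe
        for cid in db.complex_ids:
            present = sorted(db.members(cid) & universe)
            possible = list(itertools.combinations(present, 2))
            predicted = [p for p in possible if p in it.edges]
            if len(present) < 2:
                assert cid not in rec.index
            else:
                assert rec.loc[cid, "n_pairs_possible"] == len(possible)
                assert rec.loc[cid, "n_pairs_predicted"] == len(predicted)


class TestEnrichComplexes:
    def test_degenerate_single_complex(self):
        db = ComplexDatabase.from_members({"c1": ["A", "B", "C"]})
        it = Interactome.from_edges("i", "AP-MS", [("A", "B"), ("B", "C")])
        rec = enr.enrich_complexes(it, db)
        assert rec.loc[0, "p_hyper"] == pytest.approx(1.0)

    def test_concentrated_edges_rank_lower_p(self):
        db = ComplexDatabase.from_members(
            {"c1": ["A", "B", "C"], "c2": ["D", "E", "F"]}
        )
        it = Interactome.from_edges(
            "i", "AP-MS",
            [("A", "B"), ("A", "C"), ("B", "C"), ("D", "E"), ("F", "X")],
        )
        rec = enr.enrich_complexes(it, db).set_index("complex_id")
        assert rec.loc["c1", "p_hyper"] < rec.loc["c2", "p_hyper"]

    def test_p_is_one_without_edges_in_complex(self):
        db = toy_db()
        it = Interactome.from_edges("i", "AP-MS", [("A", "B"), ("D", "H")])
        rec = enr.enrich_complexes(it, db).set_index("complex_id")
        unpredicted = rec[~rec["predicted_flag"]]
        assert (unpredicted["p_hyper"] == 1.0).all()


class TestCouldPredict:
    def test_cf_needs_two_quantified(self):
        it = Interactome.from_edges("cf", "CF", [("X", "Y")],
                                    quantified=["A", "B", "Q"])
        assert enr.could_predict(["A", "B", "C", "D", "E"], it)
        assert not enr.could_predict(["A", "Z1", "Z2"], it)

    def test_cf_missing_roster_is_error(self):
        it = Interactome.from_edges("cf", "CF", [("X", "Y")])
        with pytest.raises(ValueError):
            enr.could_predict(["A", "B"], it)

    def test_apms_matrix_model(self):
        it = Interactome.from_edges("ap", "AP-MS", [("A", "X"), ("B", "Y")])
        assert enr.could_predict(["A", "B", "C"], it)
        assert not enr.could_predict(["A", "Z"], it)  # only one member present

    def test_y2h_needs_one_bait(self):
        it = Interactome.from_edges("y", "Y2H", [("X", "Y")], baits=["A"])
        assert enr.could_predict(["A", "B"], it)
        assert not enr.could_predict(["B", "C"], it)

    def test_monotone_in_rosters(self, rng):
        members = ["A", "B", "C"]
        for _ in range(50):
            q1 = set(rng.choice(list("ABCDEFGH"), size=rng.integers(0, 5),
                                replace=False))
            q2 = q1 | {"A", "B"}
            it1 = Interactome.from_edges("cf", "CF", [("X", "Y")], quantified=q1)
            it2 = Interactome.from_edges("cf", "CF", [("X", "Y")], quantified=q2)
            if enr.could_predict(members, it1):
                assert enr.could_predict(members, it2)


def flags_frame(rows, labels):
    return pd.DataFrame(rows, columns=labels,
                        index=[f"c{i}" for i in range(len(rows))]).astype(bool)


class TestTechniqueSpecific:
    LABELS = ["CF1", "CF2", "CF3", "CF4", "CF5", "CF6", "AP1", "AP2", "AP3",
              "Y1", "Y2", "Y3"]
    TECHS = dict(
        [(f"CF{i}", "CF") for i in range(1, 7)]
        + [(f"AP{i}", "AP-MS") for i in range(1, 4)]
        + [(f"Y{i}", "Y2H") for i in range(1, 4)]
    )

    def test_consensus_rule(self):
        # 4/6 CF, 1 AP, 0 Y2H -> CF-specific; 4/6 CF with 2 AP -> excluded
        rows = [
            [1, 1, 1, 1, 0, 0, 1, 0, 0, 0, 0, 0],
            [1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 0, 0],
            [1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # only 3/6 CF
        ]
        flags = flags_frame(rows, self.LABELS)
        out = enr.technique_specific_complexes(flags, self.TECHS, "CF")
        assert out == {"c0"}

    def test_default_min_within_is_two_thirds(self):
        assert enr._default_min_within(6) == 4
        assert enr._default_min_within(3) == 2

    def test_matches_bruteforce(self, rng):
        flags = flags_frame(rng.random((40, 12)) < 0.4, self.LABELS)
        for tech in ("CF", "AP-MS", "Y2H"):
            got = enr.technique_specific_complexes(flags, self.TECHS, tech)
            within = [c for c in self.LABELS if self.TECHS[c] == tech]
            min_w = enr._default_min_within(len(within))
            expected = set()
            for cid in flags.index:
                row = flags.loc[cid]
                if row[within].sum() < min_w:
                    continue
                ok = True
                for other in {"CF", "AP-MS", "Y2H"} - {tech}:
                    cols = [c for c in self.LABELS if self.TECHS[c] == other]
                    if row[cols].sum() > 1:
                        ok = False
                if ok:
                    expected.add(cid)
            assert got == expected


class TestTechniqueSpecificChance:
    LABELS = TestTechniqueSpecific.LABELS
    TECHS = TestTechniqueSpecific.TECHS

    def test_impossible_rule(self, rng):
        flags = flags_frame(np.zeros((20, 12)), self.LABELS)
        res = enr.technique_specific_chance(flags, self.TECHS, "CF", n_boot=50)
        assert res.observed == 0 and res.expected == 0.0 and res.p_value == 1.0

    def test_constructed_extreme_is_significant(self):
        rows = np.zeros((40, 12))
        rows[:8, :6] = 1  # 8 complexes hit by every CF interactome, nothing else
        flags = flags_frame(rows, self.LABELS)
        res = enr.technique_specific_chance(flags, self.TECHS, "CF",
                                            n_boot=200, seed=0)
        assert res.observed == 8
        assert res.observed > res.expected
        assert res.p_value < 0.05

    def test_seeded_reproducibility(self, rng):
        flags = flags_frame(rng.random((30, 12)) < 0.3, self.LABELS)
        a = enr.technique_specific_chance(flags, self.TECHS, "CF", n_boot=100, seed=9)
        b = enr.technique_specific_chance(flags, self.TECHS, "CF", n_boot=100, seed=9)
        assert a == b
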