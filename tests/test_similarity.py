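import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cofracbench import similarity as sim
from cofracbench.dataio import complex_to_pairs, filter_min_fractions
from cofracbench.simulate import SimulationConfig, complex_database, generate_dataset


def pearson_oracle(x, y):
    """Naive two-pass Pearson on zero-filled vectors."""
    x = np.where(np.isnan(x), 0.0, np.asarray(x, float))
    y = np.where(np.isnan(y), 0.0, np.asarray(y, float))
    mx, my = x.mean(), y.mean()
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = np.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def euclidean_oracle(x, y):
    """Explicit normalize-then-distance computation."""
    def norm(v):
        v = np.where(np.isnan(v), 0.0, np.asarray(v, float))
        return (v - v.min()) / (v.max() - v.min())
    return float(np.sqrt(((norm(x) - norm(y)) ** 2).sum()))


class TestPearsonZeroFill:
    def test_identical_profiles(self):
        x = np.array([1.0, 2, 3, 2, 1])
        assert sim.pearson_zero_fill(x, x) == pytest.approx(1.0)

    def test_offset_peaks_anticorrelated(self):
        x = np.array([0.0, 0, 1, 2, 1, 0])
        y = np.array([1.0, 2, 1, 0, 0, 0])
        r = sim.pearson_zero_fill(x, y)
        assert r < 0
        assert r == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_matches_oracle_with_missing(self, rng):
        for _ in range(500):
            n = rng.integers(5, 20)
            x = rng.gamma(2.0, 1.0, n)
            y = rng.gamma(2.0, 1.0, n)
            x[rng.random(n) < 0.25] = np.nan
            y[rng.random(n) < 0.25] = np.nan
            r = sim.pearson_zero_fill(x, y)
            expected = pearson_oracle(x, y)
            if np.isnan(r):
                continue  # degenerate vector excluded by design
            assert r == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= r <= 1.0
            assert sim.pearson_zero_fill(y, x) == pytest.approx(r, abs=1e-15)

    def test_constant_vector_undefined(self):
        assert np.isnan(sim.pearson_zero_fill([1.0, 1, 1], [1.0, 2, 3]))
        # all-missing fills to constant zero
        assert np.isnan(
            sim.pearson_zero_fill([np.nan] * 3, [1.0, 2, 3])
        )


class TestEuclideanMinmax:
    def test_identity_is_zero(self):
        x = np.array([0.5, 2.0, 1.0])
        assert sim.euclidean_minmax(x, x) == 0.0

    def test_binary_vectors(self):
        assert sim.euclidean_minmax(
            np.array([0.0, 1, 0]), np.array([1.0, 0, 1])
        ) == pytest.approx(np.sqrt(3))

    def test_matches_oracle(self, rng):
        for _ in range(500):
            n = rng.integers(4, 15)
            x = rng.gamma(2.0, 1.0, n)
            y = rng.gamma(2.0, 1.0, n)
            x[rng.random(n) < 0.2] = np.nan
            d = sim.euclidean_minmax(x, y)
            if np.isnan(d):
                continue
            assert d == pytest.approx(euclidean_oracle(x, y), abs=1e-12)
            assert d >= 0
            assert sim.euclidean_minmax(y, x) == pytest.approx(d, abs=1e-15)

    def test_constant_profile_degenerate(self):
        assert np.isnan(sim.euclidean_minmax([2.0, 2.0, 2.0], [1.0, 2, 3]))


class TestPairSimilarityTable:
    def test_labels_and_consistency(self, random_dataset):
        prots = list(random_dataset.proteins)
        pairs = [(prots[0], prots[1]), (prots[2], prots[3])]
        gold = {(prots[0], prots[1])}
        table = sim.pair_similarity_table(random_dataset, pairs, gold)
        assert set(table["label"]) <= {"gold", "non-gold"}
        for row in table.itertuples():
            x = random_dataset.data.loc[row.protein_a].to_numpy()
            y = random_dataset.data.loc[row.protein_b].to_numpy()
            assert row.pearson_r == pytest.approx(
                sim.pearson_zero_fill(x, y), abs=1e-12
            )
            assert row.euclidean_d == pytest.approx(
                sim.euclidean_minmax(x, y), abs=1e-12
            )

    def test_absent_proteins_excluded_and_counted(self, random_dataset):
        prots = list(random_dataset.proteins)
        pairs = [(prots[0], prots[1]), ("ZZZ1", "ZZZ2")]
        table = sim.pair_similarity_table(random_dataset, pairs, set())
        assert len(table) == 1
        assert table.attrs["n_excluded"] == 1


class TestAnticorrelatedFraction:
    def test_all_positive_gives_zero(self):
        table = pd.DataFrame({"pearson_r": [0.1, 0.5, 0.9]})
        assert sim.anticorrelated_fraction(table).fraction == 0.0

    def test_monotone_in_threshold(self, rng):
        table = pd.DataFrame({"pearson_r": rng.uniform(-1, 1, 300)})
        f0 = sim.anticorrelated_fraction(table, 0.0).fraction
        f25 = sim.anticorrelated_fraction(table, 0.25).fraction
        assert f25 >= f0

    def test_empty_table_undefined(self):
        with pytest.raises(ValueError):
            sim.anticorrelated_fraction(pd.DataFrame({"pearson_r": []}))

    def test_recovers_planted_fraction(self):
        # 75% co-eluting complexes -> gold anti-correlated fraction should sit
        # within 3 binomial SE of the same-seed oracle estimate from a second
        # independent simulation of the same conditions
        def gold_frac(seed):
            cfg = SimulationConfig(
                n_proteins=240, n_fractions=40, n_complexes=30,
                complex_size_range=(3, 6), frac_coeluting=0.75,
                frac_disrupted=0.25, n_datasets=1, seed=seed,
            )
            rng = np.random.default_rng(seed)
            from cofracbench.simulate import generate_truth
            truth = generate_truth(cfg, rng)
            ds, _ = generate_dataset(cfg, truth, "d1", rng)
            ds = filter_min_fractions(ds, 5)
            gold = complex_to_pairs(complex_database(truth))
            table = sim.pair_similarity_table(ds, sorted(gold), gold)
            res = sim.anticorrelated_fraction(table)
            return res.fraction, res.n_total

        f1, n1 = gold_frac(11)
        f2, n2 = gold_frac(12)
        se = np.sqrt(f2 * (1 - f2) / n1 + f2 * (1 - f2) / n2)
        assert abs(f1 - f2) <= 3 * se + 0.02


class TestEvidenceStratification:
    def test_small_codes_omitted(self, rng):
        table = pd.DataFrame(
            {
                "dataset_id": "d1",
                "pearson_r": rng.uniform(-1, 1, 199),
                "evidence_code": ["sieving"] * 100 + ["lumier"] * 99,
            }
        )
        out = sim.stratify_by_evidence_code(table, min_pairs_per_code=100)
        assert list(out["evidence_code"]) == ["sieving"]

    def test_single_code_equals_whole_table(self, rng):
        table = pd.DataFrame(
            {
                "dataset_id": "d1",
                "pearson_r": rng.uniform(-1, 1, 150),
                "evidence_code": "sieving",
            }
        )
        out = sim.stratify_by_evidence_code(table, min_pairs_per_code=10)
        whole = sim.anticorrelated_fraction(table)
        assert out.loc[0, "frac_anticorrelated"] == pytest.approx(whole.fraction)
        assert out.loc[0, "mean_r"] == pytest.approx(table["pearson_r"].mean())

    def test_matches_groupby_oracle(self, rng):
        codes = rng.choice(["a", "b", "c"], size=400)
        table = pd.DataFrame(
            {
                "dataset_id": rng.choice(["d1", "d2"], size=400),
                "pearson_r": rng.uniform(-1, 1, 400),
                "evidence_code": codes,
            }
        )
        out = sim.stratify_by_evidence_code(table, min_pairs_per_code=1)
        for row in out.itertuples():
            grp = table[
                (table["dataset_id"] == row.dataset_id)
                & (table["evidence_code"] == row.evidence_code)
            ]["pearson_r"]
            assert row.mean_r == pytest.approx(grp.mean(), abs=1e-12)
            assert row.frac_anticorrelated == pytest.approx((grp < 0).mean())


def test_gold_indistinguishable_without_planted_structure():
    """With no co-eluting complexes, gold and non-gold R distributions agree."""
    cfg = SimulationConfig(
        n_proteins=300, n_fractions=40, n_complexes=30, complex_size_range=(3, 6),
        frac_coeluting=0.0, frac_disrupted=0.0, n_datasets=1, seed=21,
    )
    rng = np.random.default_rng(21)
    from cofracbench.simulate import generate_truth
    truth = generate_truth(cfg, rng)
    ds, _ = generate_dataset(cfg, truth, "d1", rng)
    ds = filter_min_fractions(ds, 5)
    gold = complex_to_pairs(complex_database(truth))
    prots = sorted(ds.proteins)
    non_gold = []
    rng2 = np.random.default_rng(22)
    while len(non_gold) < 2000:
        a, b = rng2.choice(len(prots), 2, replace=False)
        p = (prots[a], prots[b]) if prots[a] < prots[b] else (prots[b], prots[a])
        if p not in gold:
            non_gold.append(p)
    t_gold = sim.pair_similarity_table(ds, sorted(gold), gold)
    t_non = sim.pair_similarity_table(ds, non_gold, gold)
    ks = sps.ks_2samp(t_gold["pearson_r"], t_non["pearson_r"])
    assert ks.pvalue > 0.01


def test_gold_median_above_non_gold_with_coelution():
    cfg = SimulationConfig(
        n_proteins=300, n_fractions=40, n_complexes=30, complex_size_range=(3, 6),
        frac_coeluting=0.8, frac_disrupted=0.1, n_datasets=1, seed=23,
    )
    rng = np.random.default_rng(23)
    from cofracbench.simulate import generate_truth
    truth = generate_truth(cfg, rng)
    ds, _ = generate_dataset(cfg, truth, "d1", rng)
    ds = filter_min_fractions(ds, 5)
    gold = complex_to_pairs(complex_database(truth))
    import itertools
    all_pairs = list(itertools.combinations(sorted(ds.proteins), 2))
    table = sim.pair_similarity_table(ds, all_pairs, gold)
    med = table.groupby("label")["pearson_r"].median()
    assert med["gold"] > med["non-gold"]
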