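import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gliotalk.crosstalk import autocrine_screen, directional_screen, ora_enrichment, spearman_test
from gliotalk.data_model import BulkCohort, LRTable
from gliotalk.synthetic import SimConfig, simulate_bulk_cohort, simulate_lr_table, simulate_sc_cohort


def _bulk(values: pd.DataFrame) -> BulkCohort:
    clinical = pd.DataFrame(
        {"survival_days": 100.0, "event": True}, index=values.index
    )
    return BulkCohort(values, clinical)


class TestSpearman:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.random(30)
        y = rng.random(30)
        rho1, p1 = spearman_test(x, y)
        rho2, p2 = spearman_test(np.exp(x), y ** 3 + 2)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_perfect_monotone_gives_extremes(self):
        x = np.arange(1.0, 11.0)
        assert spearman_test(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_test(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_exact_permutation_oracle_n7(self):
        """n = 7 p-value equals full 7!-enumeration via the rank-d^2 formula."""
        rng = np.random.default_rng(3)
        for _ in range(3):
            x = rng.random(7)
            y = rng.random(7)
            rho, p = spearman_test(x, y)
            rx = np.argsort(np.argsort(x)) + 1.0
            ry = np.argsort(np.argsort(y)) + 1.0

            def rho_of(perm):  # distinct ranks: 1 - 6*sum(d^2)/(n(n^2-1))
                d2 = np.sum((rx - np.asarray(perm)) ** 2)
                return 1.0 - 6.0 * d2 / (7 * 48)

            obs = abs(rho_of(ry))
            count = sum(
                abs(rho_of(perm)) >= obs - 1e-12
                for perm in itertools.permutations(ry)
            )
            assert p == pytest.approx(count / math.factorial(7), rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_test(np.ones(10), np.arange(10.0))

    def test_large_n_matches_scipy_t_approximation(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x, y = rng.random(50), rng.random(50)
        rho, p = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


@pytest.fixture(scope="module")
def planted():
    pairs = [(f"G{500 + 2 * i:05d}", f"G{501 + 2 * i:05d}", 0.6) for i in range(5)]
    sim = SimConfig(n_genes=1000, n_bulk_samples=400, planted_pairs=pairs, seed=17)
    bulk, _ = simulate_bulk_cohort(sim)
    lr, truth = simulate_lr_table(sim, n_decoys=60)
    return bulk, lr, truth, pairs


class TestAutocrineScreen:
    def test_planted_pairs_pass_and_decoys_fail(self, planted):
        bulk, lr, truth, pairs = planted
        # DE table contains the planted genes plus every decoy gene
        de_genes = sorted(set(lr.pairs.to_numpy().ravel()))
        de_table = pd.DataFrame(
            {"combined_p": 1e-6, "log2_fc": 1.0}, index=pd.Index(de_genes)
        )
        result = autocrine_screen(de_table, lr, bulk, rho_min=0.4, alpha=0.05)
        key = result.set_index(["ligand", "receptor"])
        for lig, rec, _ in pairs:
            assert bool(key.loc[(lig, rec), "pass_overall"])
        decoys = truth.loc[~truth["planted"]]
        rate = key.loc[list(decoys[["ligand", "receptor"]].itertuples(index=False))][
            "pass_overall"].mean()
        assert rate <= 0.05

    def test_empty_de_table_empty_result(self, planted):
        bulk, lr, *_ = planted
        de_table = pd.DataFrame(columns=["combined_p", "log2_fc"])
        result = autocrine_screen(de_table, lr, bulk)
        assert not result["pass_de"].any()
        assert not result["pass_overall"].any()

    def test_matches_brute_force_filter(self, planted):
        bulk, lr, truth, pairs = planted
        de_genes = sorted(set(lr.pairs.to_numpy().ravel()))[:80]
        de_table = pd.DataFrame({"combined_p": 1e-6, "log2_fc": 1.0},
                                index=pd.Index(de_genes))
        result = autocrine_screen(de_table, lr, bulk, rho_min=0.4, alpha=0.05)
        survivors = set(
            result.loc[result["pass_overall"], ["ligand", "receptor"]]
            .itertuples(index=False, name=None)
        )
        brute = set()
        for lig, rec in lr.pairs.itertuples(index=False):
            if lig in de_genes and rec in de_genes:
                rho, p = spearman_test(bulk.values[lig].to_numpy(),
                                       bulk.values[rec].to_numpy())
                if rho > 0.4 and p < 0.05:
                    brute.add((lig, rec))
        assert survivors == brute

    def test_monotone_in_thresholds(self, planted):
        bulk, lr, truth, pairs = planted
        de_genes = sorted(set(lr.pairs.to_numpy().ravel()))
        de_table = pd.DataFrame({"combined_p": 1e-6, "log2_fc": 1.0},
                                index=pd.Index(de_genes))
        counts = []
        for rho_min, alpha in [(0.2, 0.10), (0.4, 0.05), (0.55, 0.01)]:
            res = autocrine_screen(de_table, lr, bulk, rho_min=rho_min, alpha=alpha)
            counts.append(int(res["pass_overall"].sum()))
        assert counts[0] >= counts[1] >= counts[2]

    def test_self_pairs_excluded_and_empty_lr_rejected(self, planted):
        bulk, *_ = planted
        lr = LRTable(pd.DataFrame({"ligand": ["G00500"], "receptor": ["G00500"]}))
        de_table = pd.DataFrame({"combined_p": 1e-6, "log2_fc": 1.0}, index=["G00500"])
        result = autocrine_screen(de_table, lr, bulk)
        assert result.empty
        with pytest.raises(ValueError):
            autocrine_screen(de_table, LRTable(pd.DataFrame(columns=["ligand", "receptor"])), bulk)


@pytest.fixture(scope="module")
def cohort(demo_sim):
    matrix, truth, catalog = simulate_sc_cohort(demo_sim)
    lr, lr_truth = simulate_lr_table(demo_sim, n_decoys=150)
    groups = {
        "csc": truth.index[truth["is_csc"]],
        "diff": truth.index[(truth["true_type"] == "neoplastic") & ~truth["is_csc"]],
        "mac": truth.index[truth["true_type"] == "macrophage"],
        "mic": truth.index[truth["true_type"] == "microglia"],
    }
    return matrix, lr, lr_truth, groups, demo_sim


class TestDirectionalScreen:
    def test_planted_directional_pairs_recovered(self, cohort):
        matrix, lr, lr_truth, g, sim = cohort
        res = directional_screen(matrix, g["csc"], g["diff"], g["mac"], g["mic"], lr,
                                 direction_label="csc_to_macrophage")
        found = set(res[["ligand", "receptor"]].itertuples(index=False, name=None))
        planted_c2m = {(l, r) for l, r, _ in sim.planted_pairs[4:8]}
        assert len(found & planted_c2m) >= 3
        # autocrine-planted pairs have no macrophage-side receptor signal
        planted_auto = {(l, r) for l, r, _ in sim.planted_pairs[:4]}
        assert not found & planted_auto

    def test_role_swap_gives_reverse_pairs(self, cohort):
        matrix, lr, lr_truth, g, sim = cohort
        rev = directional_screen(matrix, g["mac"], g["mic"], g["csc"], g["diff"], lr,
                                 direction_label="macrophage_to_csc")
        found = set(rev[["ligand", "receptor"]].itertuples(index=False, name=None))
        planted_m2c = {(l, r) for l, r, _ in sim.planted_pairs[8:12]}
        assert len(found & planted_m2c) >= 3
        assert (rev["direction"] == "macrophage_to_csc").all()

    def test_empty_group_rejected(self, cohort):
        matrix, lr, _, g, _ = cohort
        with pytest.raises(ValueError, match="empty"):
            directional_screen(matrix, [], g["diff"], g["mac"], g["mic"], lr)


class TestOra:
    def test_forced_and_zero_overlap_give_p_one(self):
        universe = [f"G{i}" for i in range(20)]
        out = ora_enrichment(universe, {"all": universe}, universe)
        assert out.loc["all", "p_value"] == pytest.approx(1.0)
        out = ora_enrichment(universe[:4], {"none": []}, universe)
        assert out.loc["none", "p_value"] == pytest.approx(1.0)

    def test_matches_tail_enumeration(self):
        """Hypergeometric p equals explicit tail sum (4-gene query, 10-gene
        pathway, 100-gene universe)."""
        universe = [f"G{i}" for i in range(100)]
        pathway = universe[:10]
        query = universe[8:12]  # overlap 2
        out = ora_enrichment(query, {"pw": pathway}, universe)
        n, K, k = 4, 10, 2
        tail = sum(
            math.comb(K, i) * math.comb(100 - K, n - i) / math.comb(100, n)
            for i in range(k, min(n, K) + 1)
        )
        assert out.loc["pw", "p_value"] == pytest.approx(tail, rel=1e-12)

    def test_query_outside_universe_dropped_and_empty_universe_rejected(self):
        universe = ["G1", "G2", "G3", "G4"]
        out = ora_enrichment(["G1", "NOPE"], {"pw": ["G1", "G2"]}, universe)
        assert out.loc["pw", "overlap"] == 1
        with pytest.raises(ValueError):
            ora_enrichment(["G1"], {"pw": ["G1"]}, [])
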