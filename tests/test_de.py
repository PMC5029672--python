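import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscape import de as de_mod
from lncscape.de import (
    bh_adjust,
    consensus_de,
    de_comparison,
    de_test_nb,
    de_test_perm,
    significant_set,
    size_factors,
)
from lncscape.simulate import SimulationConfig, generate_annotation, generate_counts


def naive_bh(p):
    """O(m^2) literal step-up: adj_i = min over j with p_j >= p_i of p_j*m/rank_j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_pos in range(m):
        i = order[rank_pos]
        best = min(
            p[order[k]] * m / (k + 1) for k in range(rank_pos, m)
        )
        adj[i] = min(best, 1.0)
    return adj


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=list("xyz"))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gives_factor_ratio_two(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=list("xyz"))
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, (100, 6)), columns=[f"s{i}" for i in range(6)]
        )
        sf = size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_recovers_known_depth_factors_on_nb_fixture(self):
        # NB counts with known per-sample factors: estimates within 5% at 2,000 genes
        rng = np.random.default_rng(8)
        n_genes, n_samp = 2000, 8
        mu = np.exp(rng.normal(4.5, 1.0, n_genes))
        true_sf = np.exp(rng.uniform(np.log(0.7), np.log(1.3), n_samp))
        true_sf /= np.exp(np.mean(np.log(true_sf)))
        shape = 1 / 0.1
        lam = rng.gamma(shape, (mu[:, None] * true_sf[None, :]) / shape)
        counts = pd.DataFrame(
            rng.poisson(lam), index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samp)],
        )
        sf = size_factors(counts)
        assert np.allclose(sf, true_sf, rtol=0.05)


class TestNbTest:
    def test_all_zero_gene(self):
        counts = pd.DataFrame(
            {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]}, index=["z", "g"]
        )
        res = de_test_nb(counts, ["a1", "a2"], ["b1", "b2"])
        assert res.at["z", "log2fc"] == 0.0
        assert res.at["z", "p"] == 1.0

    def test_minimum_group_size(self):
        counts = pd.DataFrame({"a1": [5], "b1": [5], "b2": [6]}, index=["g"])
        with pytest.raises(ValueError):
            de_test_nb(counts, ["a1"], ["b1", "b2"])

    def test_null_p_values_uniform(self):
        cfg = SimulationConfig(
            seed=7, n_per_group=10, n_mrna=1500, n_lnc=500, n_cis_pairs=0,
            n_chip_links=0, frac_de=0.0,
        )
        ann = generate_annotation(cfg)
        counts, samples, _ = generate_counts(cfg, ann)
        ga = list(samples.index[samples["group"] == "PC"])
        gb = list(samples.index[samples["group"] == "NC"])
        res = de_test_nb(counts, ga, gb)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_sign_recovered(self):
        cfg = SimulationConfig(
            seed=6, n_per_group=6, n_mrna=800, n_lnc=200, n_cis_pairs=0,
            n_chip_links=0, frac_de=0.2, de_log2fc=2.0, nb_dispersion=0.1,
        )
        ann = generate_annotation(cfg)
        counts, samples, truth = generate_counts(cfg, ann)
        ga = list(samples.index[samples["group"] == "PC"])
        gb = list(samples.index[samples["group"] == "NC"])
        res = de_test_nb(counts, ga, gb)
        truth_dir = truth.de_genes["PC-NC"]
        signs = [
            (res.at[g, "log2fc"] > 0) == (d == "up") for g, d in truth_dir.items()
        ]
        assert np.mean(signs) >= 0.99


class TestPermTest:
    def _sep_counts(self):
        # one fully separated gene, 3 vs 3
        return pd.DataFrame(
            {"a1": [100, 10], "a2": [120, 10], "a3": [110, 10],
             "b1": [10, 10], "b2": [12, 10], "b3": [11, 10]},
            index=["sep", "flat"],
        )

    def test_full_separation_matches_exhaustive_enumeration(self):
        counts = self._sep_counts()
        ga, gb = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        res = de_test_perm(counts, ga, gb, n_perm=100)
        # oracle: enumerate all 20 assignments of the normalized statistic
        sf = size_factors(counts)
        x = np.log2(counts.to_numpy() / sf.to_numpy() + 0.5)[0]
        obs = x[:3].mean() - x[3:].mean()
        tail = 0
        for c in itertools.combinations(range(6), 3):
            in_a = np.zeros(6, bool)
            in_a[list(c)] = True
            if abs(x[in_a].mean() - x[~in_a].mean()) >= abs(obs) - 1e-12:
                tail += 1
        assert tail == 2
        assert res.at["sep", "p"] == pytest.approx(tail / 20)
        assert res.at["sep", "p"] == pytest.approx(0.1)

    def test_label_symmetric_gene_large_p(self):
        counts = self._sep_counts()
        unit_sf = pd.Series(1.0, index=counts.columns)
        res = de_test_perm(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"], n_perm=100, sf=unit_sf)
        assert res.at["flat", "p"] >= 0.5

    def test_sampled_branch_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(30, (50, 16)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(16)],
        )
        ga, gb = [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 16)]
        r1 = de_test_perm(counts, ga, gb, n_perm=300, seed=42)
        r2 = de_test_perm(counts, ga, gb, n_perm=300, seed=42)
        assert r1.equals(r2)


class TestBhAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.7]))[0] == pytest.approx(0.7)

    def test_all_ones(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    def test_matches_naive_step_up_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 60)))
            assert np.allclose(bh_adjust(p), naive_bh(list(p)))

    def test_order_equivariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1, 40)
        perm = rng.permutation(40)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestConsensus:
    def _table(self, sig: dict[str, str], genes=("g1", "g2", "g3")):
        df = pd.DataFrame(
            {
                "log2fc": [1.5 if sig.get(g) == "up" else -1.5 if sig.get(g) == "down" else 0.1 for g in genes],
                "p": [0.001 if g in sig else 0.9 for g in genes],
                "fdr": [0.004 if g in sig else 0.95 for g in genes],
                "significant": [g in sig for g in genes],
            },
            index=list(genes),
        )
        df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
        return df

    def test_intersection_with_direction(self):
        a = self._table({"g1": "up", "g2": "up"})
        b = self._table({"g2": "up", "g3": "up"})
        out = consensus_de(a, b)
        assert significant_set(out) == {"g2"}

    def test_discordant_direction_excluded(self):
        a = self._table({"g1": "up"})
        b = self._table({"g1": "down"})
        assert significant_set(consensus_de(a, b)) == set()

    def test_mismatched_universe_errors(self):
        a = self._table({}, genes=("g1", "g2"))
        b = self._table({}, genes=("g1", "g3"))
        with pytest.raises(ValueError, match="g"):
            consensus_de(a, b)

    def test_fold_change_boundary_inclusive(self):
        # |log2fc| exactly 1 with small fdr must be significant
        df = pd.DataFrame({"log2fc": [1.0, 0.999], "p": [1e-5, 1e-5]}, index=["on", "under"])
        out = de_mod._finalize(df, "bh")
        assert bool(out.at["on", "significant"])
        assert not bool(out.at["under", "significant"])

    def test_reported_statistics_come_from_nb(self):
        a = self._table({"g1": "up"})
        b = self._table({"g1": "up"})
        b["log2fc"] = b["log2fc"] + 0.3
        out = consensus_de(a, b)
        assert out.at["g1", "log2fc"] == a.at["g1", "log2fc"]
        assert out.at["g1", "fdr"] == a.at["g1", "fdr"]
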