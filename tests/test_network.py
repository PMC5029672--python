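import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lncscape.network import (
    build_network,
    detect_modules,
    merge_modules,
    module_eigengene,
    module_trait_cor,
    pick_power,
    select_variable,
    tom,
)


def _frame(x: np.ndarray, prefix="g") -> pd.DataFrame:
    return pd.DataFrame(
        x, index=[f"{prefix}{i}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(x.shape[1])],
    )


def modular_data(seed=0, sizes=(40, 40), n_noise=80, n_samp=54, r=0.8):
    """Planted blocks sharing latent factors at correlation ~r, plus noise."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    a = np.sqrt(r / (1 - r))
    for m, size in enumerate(sizes, start=1):
        f = rng.normal(0, 1, n_samp)
        for _ in range(size):
            rows.append(a * f + rng.normal(0, 1, n_samp))
            labels.append(m)
    for _ in range(n_noise):
        rows.append(rng.normal(0, 1, n_samp))
        labels.append(0)
    x = _frame(np.array(rows))
    return x, pd.Series(labels, index=x.index)


class TestSelectVariable:
    def test_identity_when_k_is_all(self):
        x = _frame(np.random.default_rng(0).normal(0, 1, (10, 5)))
        assert set(select_variable(x, 10).index) == set(x.index)

    def test_constant_row_never_beats_varying(self):
        x = _frame(np.vstack([np.zeros(6), np.random.default_rng(1).normal(0, 1, (4, 6))]))
        assert "g0" not in select_variable(x, 4).index

    def test_matches_direct_sort(self):
        rng = np.random.default_rng(2)
        x = _frame(rng.normal(0, rng.uniform(0.1, 3, (20, 1)), (20, 12)))
        got = list(select_variable(x, 7).index)
        var = x.var(axis=1, ddof=1)
        exp = sorted(x.index, key=lambda g: (-var[g], g))[:7]
        assert got == exp

    def test_invalid_k(self):
        x = _frame(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(ValueError):
            select_variable(x, 0)
        with pytest.raises(ValueError):
            select_variable(x, 4)


class TestTom:
    def test_two_perfectly_correlated_transcripts(self):
        s = np.linspace(0, 1, 10)
        x = _frame(np.vstack([s, 2 * s + 3]))
        t = tom(x, power=6)
        assert t.iloc[0, 1] == pytest.approx(1.0)

    def test_matches_direct_formula_on_hand_matrix(self):
        rng = np.random.default_rng(7)
        x = _frame(rng.normal(0, 1, (5, 20)))
        power = 3
        t = tom(x, power).to_numpy()
        # independent oracle: correlations via np.corrcoef, triple loop
        c = np.abs(np.corrcoef(x.to_numpy())) ** power
        np.fill_diagonal(c, 0.0)
        k = c.sum(axis=1)
        exp = np.ones((5, 5))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                shared = sum(c[i, u] * c[u, j] for u in range(5) if u not in (i, j))
                exp[i, j] = (shared + c[i, j]) / (min(k[i], k[j]) + 1 - c[i, j])
        assert np.allclose(t, exp)

    def test_independent_noise_has_small_overlap(self):
        rng = np.random.default_rng(8)
        x = _frame(rng.normal(0, 1, (30, 400)))
        t = tom(x, 6).to_numpy()
        off = t[np.triu_indices(30, 1)]
        assert off.max() < 0.05

    def test_symmetric_unit_diag_in_unit_interval(self):
        x, _ = modular_data(seed=3, sizes=(15,), n_noise=15, n_samp=20)
        t = tom(x, 6).to_numpy()
        assert np.allclose(t, t.T)
        assert np.allclose(np.diag(t), 1.0)
        assert t.min() >= 0 and t.max() <= 1

    def test_constant_transcript_correlates_at_zero(self):
        x = _frame(np.vstack([np.zeros(10), np.linspace(0, 1, 10), np.linspace(1, 0, 10)]))
        t = tom(x, 2)
        assert t.iloc[0, 1] == pytest.approx(t.iloc[0, 2])


class TestPickPower:
    def test_single_candidate_returned(self):
        x, _ = modular_data(seed=4, sizes=(20,), n_noise=20)
        assert pick_power(x, candidate_powers=(7,)) == 7

    def test_deterministic(self):
        x, _ = modular_data(seed=5)
        assert pick_power(x) == pick_power(x)

    def test_hub_structure_reaches_scale_free_fit(self):
        # graded (heavy-tailed) loadings on one factor give a hub-like network
        rng = np.random.default_rng(6)
        n, m = 300, 54
        f = rng.normal(0, 1, m)
        w = rng.pareto(2.0, n) * 0.5
        x = _frame(w[:, None] * f[None, :] + rng.normal(0, 1, (n, m)))
        from lncscape.network import _scale_free_r2
        p = pick_power(x)
        assert _scale_free_r2(x, p, 10, False) >= 0.8

    def test_too_few_transcripts(self):
        x = _frame(np.random.default_rng(0).normal(0, 1, (5, 10)))
        with pytest.raises(ValueError):
            pick_power(x)


class TestDetectModules:
    def test_two_planted_blocks_recovered(self):
        x, truth = modular_data(seed=10, sizes=(40, 40), n_noise=80)
        labels = detect_modules(tom(x, 6), min_module_size=20)
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert len(set(labels) - {0}) == 2

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(11)
        x = _frame(rng.normal(0, 1, (120, 36)))
        labels = detect_modules(tom(x, 6))
        assert (labels == 0).mean() >= 0.9

    def test_single_block_single_module(self):
        x, _ = modular_data(seed=12, sizes=(50,), n_noise=0)
        labels = detect_modules(tom(x, 6), min_module_size=20)
        assert set(labels) == {1}


class TestEigengene:
    def test_identical_profiles_reproduce_profile(self):
        prof = np.array([1.0, -2.0, 0.5, 3.0, -1.0, -1.5])
        x = _frame(np.tile(prof, (4, 1)))
        labels = pd.Series(1, index=x.index)
        eg = module_eigengene(x, labels).loc[1].to_numpy()
        stdp = (prof - prof.mean()) / prof.std()
        assert np.allclose(eg, stdp)

    def test_sign_oriented_to_members(self):
        x, _ = modular_data(seed=13, sizes=(20,), n_noise=0)
        labels = pd.Series(1, index=x.index)
        eg = module_eigengene(x, labels)
        cors = [np.corrcoef(x.loc[g], eg.loc[1])[0, 1] for g in x.index]
        assert np.mean(cors) > 0
        # negating all members flips nothing after orientation
        eg_neg = module_eigengene(-x, labels)
        cors_neg = [np.corrcoef((-x).loc[g], eg_neg.loc[1])[0, 1] for g in x.index]
        assert np.mean(cors_neg) > 0

    def test_unit_variance(self):
        x, _ = modular_data(seed=14, sizes=(15,), n_noise=0)
        eg = module_eigengene(x, pd.Series(1, index=x.index))
        assert eg.loc[1].std(ddof=0) == pytest.approx(1.0)

    def test_singleton_module_errors(self):
        x = _frame(np.random.default_rng(0).normal(0, 1, (1, 8)))
        with pytest.raises(ValueError):
            module_eigengene(x, pd.Series(1, index=x.index))


class TestMerge:
    def test_highly_correlated_modules_merge(self):
        rng = np.random.default_rng(15)
        f = rng.normal(0, 1, 30)
        rows = [3 * f + rng.normal(0, 1, 30) for _ in range(40)]
        x = _frame(np.array(rows))
        labels = pd.Series([1] * 20 + [2] * 20, index=x.index)
        merged = merge_modules(x, labels, merge_cutoff=0.75)
        assert len(set(merged) - {0}) == 1

    def test_uncorrelated_modules_untouched_and_idempotent(self):
        x, truth = modular_data(seed=16, sizes=(25, 25), n_noise=0)
        labels = truth.copy()
        m1 = merge_modules(x, labels, merge_cutoff=0.75)
        m2 = merge_modules(x, m1, merge_cutoff=0.75)
        assert len(set(m1) - {0}) == 2
        assert m1.equals(m2)


class TestTraitCor:
    def _samples(self, n=12):
        groups = ["NC"] * (n // 3) + ["PC"] * (n // 3) + ["MC"] * (n // 3)
        return pd.DataFrame({"group": groups}, index=[f"s{j}" for j in range(n)])

    def test_eigengene_equal_to_indicator_gives_r_one(self):
        samples = self._samples(12)
        ind = (samples["group"] == "PC").astype(float)
        eg = pd.DataFrame([ind.to_numpy()], index=[1], columns=samples.index)
        tc = module_trait_cor(eg, samples)
        assert tc.loc[(1, "PC"), "r"] == pytest.approx(1.0)
        assert tc.loc[(1, "PC"), "p"] == 0.0

    def test_matches_closed_form_covariance(self):
        samples = pd.DataFrame({"group": ["PC", "NC", "PC", "NC"]}, index=list("abcd"))
        e = np.array([1.0, 2.0, 3.0, 4.0])
        eg = pd.DataFrame([e], index=[1], columns=samples.index)
        t = np.array([1.0, 0.0, 1.0, 0.0])
        exp_r = np.cov(e, t, ddof=0)[0, 1] / (e.std() * t.std())
        tc = module_trait_cor(eg, samples)
        assert tc.loc[(1, "PC"), "r"] == pytest.approx(exp_r)

    def test_constant_eigengene_reported_as_zero(self):
        samples = self._samples(9)
        eg = pd.DataFrame([np.ones(9)], index=[1], columns=samples.index)
        tc = module_trait_cor(eg, samples)
        assert (tc["r"] == 0).all() and (tc["p"] == 1).all()


def test_full_network_pipeline_recovers_trait_modules(small_dataset):
    """End-to-end module stage on simulated data with two trait-linked modules."""
    from lncscape.expression import log_rpkm, rpkm
    from lncscape.simulate import SimulationConfig, generate_annotation, generate_counts

    cfg = SimulationConfig(
        seed=17, n_per_group=12, n_mrna=220, n_lnc=80, genome_size=12_000_000,
        n_cis_pairs=0, n_chip_links=0, frac_de=0.0,
        module_spec=[{"size": 60, "trait": "PC"}, {"size": 60, "trait": "MC"}],
    )
    ann = generate_annotation(cfg)
    counts, samples, truth = generate_counts(cfg, ann)
    ms = build_network(log_rpkm(rpkm(counts, ann)), samples)
    truth_labels = pd.Series(0, index=ms.labels.index)
    for g, m in truth.module_labels.items():
        truth_labels[g] = m
    assert adjusted_rand_score(truth_labels, ms.labels) >= 0.8
    # the PC-linked module has the max correlation with the PC trait
    pc_rows = ms.trait_correlation.xs("PC", level="trait")
    best_mod = pc_rows["r"].idxmax()
    best_members = set(ms.labels.index[ms.labels == best_mod])
    planted_pc = {g for g, m in truth.module_labels.items() if truth.module_traits[m] == "PC"}
    overlap = len(best_members & planted_pc) / len(planted_pc)
    assert overlap >= 0.8
    assert pc_rows.loc[best_mod, "p"] < 0.01
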