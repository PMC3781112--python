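import numpy as np
import pytest

from aflpop.admixture import (
    AdmixtureResult,
    ancestry_test,
    evanno_deltaK,
    fit_admixture,
    match_clusters,
    pca_binary,
)
from aflpop.io import BinaryMarkerMatrix
from aflpop.simulate import FlockConfig, simulate_flock


@pytest.fixture(scope="module")
def two_species_with_hybrid():
    cfg = FlockConfig(
        n_species=2, species_names=("A", "B"), n_per_species=(15, 15),
        n_loci=2000, frac_outlier=0.0, fst_neutral=0.3, fst_outlier=0.5,
        introgressed_spec=None, expansion_params=[(1.0, 0.0, 3.0)] * 2,
        hybrid_spec=[("hyb", ("A", "B"), "F1"), ("gp", ("A", "B"), "grandparent")],
        seed=11,
    )
    return simulate_flock(cfg)


class TestFitAdmixture:
    def test_k1_trivial(self, three_species_flock):
        m, _, _ = three_species_flock
        r = fit_admixture(m, K=1, burnin=50, iterations=200, n_reps=1, seed=2)[0]
        assert np.allclose(r.Q, 1.0)
        assert np.isfinite(r.lnPD)

    def test_recovers_well_separated_species(self, three_species_flock):
        m, _, _ = three_species_flock
        r = fit_admixture(m, K=3, burnin=300, iterations=1200, n_reps=1, seed=1)[0]
        assert np.allclose(r.Q.sum(axis=1), 1.0)
        assert r.Q.max(axis=1).mean() > 0.95
        _, acc = match_clusters(r.Q, m.species)
        assert acc == 1.0

    def test_f1_hybrid_gets_mixed_ancestry(self, two_species_with_hybrid):
        m, _, _ = two_species_with_hybrid
        r = fit_admixture(m, K=2, burnin=300, iterations=1200, n_reps=1, seed=3)[0]
        q_h = r.Q[m.sample_ids.index("hyb")]
        assert 0.3 <= q_h[0] <= 0.7 and 0.3 <= q_h[1] <= 0.7

    def test_q_invariant_under_cluster_permutation(self, three_species_flock):
        m, _, _ = three_species_flock
        r = fit_admixture(m, K=3, burnin=200, iterations=600, n_reps=1, seed=4)[0]
        perm = [2, 0, 1]
        _, acc1 = match_clusters(r.Q, m.species)
        _, acc2 = match_clusters(r.Q[:, perm], m.species)
        assert acc1 == acc2

    def test_k_larger_than_samples_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="K larger"):
            fit_admixture(tiny_matrix, K=10, burnin=5, iterations=10, n_reps=1, seed=0)


class TestEvanno:
    @staticmethod
    def _stub_runs(means, sds, reps=3, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for K, (mu, sd) in enumerate(zip(means, sds), start=1):
            runs = []
            for _ in range(reps):
                lnpd = mu if sd == 0 else rng.normal(mu, 1e-12)
                r = AdmixtureResult(
                    K=K, Q=np.ones((2, K)) / K, P=np.full((K, 3), 0.5),
                    lnPD=lnpd, alpha=1.0, lam=1.0, drift=np.full(K, 0.1),
                    loglik_trace=np.array([lnpd]), converged=True,
                    burnin=0, iterations=0, seed=None,
                )
                runs.append(r)
            out[K] = runs
        return out

    def test_hand_arithmetic(self):
        # L = (-100, -50, -45, -44) with unit SDs: dK(2)=45, dK(3)=4
        runs = self._stub_runs([-100, -50, -45, -44], [1, 1, 1, 1])
        # overwrite lnPDs to exact values and SD to 1 via two replicates
        for K, (mu) in zip(runs, [-100, -50, -45, -44]):
            runs[K][0].lnPD = mu + 0.5 * np.sqrt(2)
            runs[K][1].lnPD = mu - 0.5 * np.sqrt(2)
            runs[K] = runs[K][:2]
        res = evanno_deltaK(runs)
        t = res.table.set_index("K")
        assert t.loc[2, "delta_K"] == pytest.approx(45.0, rel=1e-6)
        assert t.loc[3, "delta_K"] == pytest.approx(4.0, rel=1e-6)
        assert np.isnan(t.loc[1, "delta_K"]) and np.isnan(t.loc[4, "delta_K"])
        assert res.best_K == 2

    def test_linear_lnpd_gives_zero_delta(self):
        runs = self._stub_runs([-90, -80, -70, -60], [1, 1, 1, 1], seed=1)
        for K, mu in zip(runs, [-90, -80, -70, -60]):
            runs[K][0].lnPD = mu + 0.5 * np.sqrt(2)
            runs[K][1].lnPD = mu - 0.5 * np.sqrt(2)
            runs[K] = runs[K][:2]
        res = evanno_deltaK(runs)
        inner = res.table.dropna(subset=["delta_K"])
        assert (inner.delta_K < 1e-6).all()

    def test_zero_sd_warns_infinite(self):
        runs = self._stub_runs([-90, -50, -45], [0, 0, 0])
        with pytest.warns(UserWarning, match="zero SD"):
            res = evanno_deltaK(runs)
        assert np.isinf(res.table.set_index("K").loc[2, "delta_K"])

    def test_requires_consecutive_ks_and_replicates(self):
        runs = self._stub_runs([-90, -80, -70], [1, 1, 1])
        del runs[2]
        with pytest.raises(ValueError, match="consecutive"):
            evanno_deltaK(runs)


class TestAncestry:
    def test_pure_individuals_confident(self, two_species_with_hybrid):
        m, _, _ = two_species_with_hybrid
        at = ancestry_test(m, gb=2, nu=0.05).set_index("individual")
        pure = at.drop(index=["hyb", "gp"])
        assert (pure.p_pure > 0.95).mean() > 0.95

    def test_grandparent_hybrid_detected(self, two_species_with_hybrid):
        # 'gp' carries 1/4 ancestry from B but is labelled A
        m, _, _ = two_species_with_hybrid
        at = ancestry_test(m, gb=2, nu=0.05).set_index("individual")
        row = at.loc["gp"]
        assert row.p_pure < 0.5
        assert row.modal_hypothesis in ("grandparent:B", "parent:B")

    def test_stable_across_nu(self, two_species_with_hybrid):
        m, _, _ = two_species_with_hybrid
        clear = [s for s in m.sample_ids if s not in ("hyb", "gp")]
        ps = []
        for nu in (0.1, 0.05, 0.01):
            at = ancestry_test(m, gb=2, nu=nu).set_index("individual")
            ps.append(at.loc[clear, "p_pure"].to_numpy())
        spread = np.max(ps, axis=0) - np.min(ps, axis=0)
        assert spread.max() < 0.1

    def test_hypothesis_probabilities_sum_to_one(self, three_species_flock):
        m, _, _ = three_species_flock
        at = ancestry_test(m, gb=2, nu=0.05)
        hyp_cols = [c for c in at.columns if ":" in str(c)]
        totals = at.p_pure + at[hyp_cols].fillna(0).sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)

    def test_invalid_arguments(self, three_species_flock):
        m, _, _ = three_species_flock
        with pytest.raises(ValueError, match="gb"):
            ancestry_test(m, gb=5)
        with pytest.raises(ValueError, match="nu"):
            ancestry_test(m, nu=1.5)


class TestPca:
    def test_two_clusters_separated_on_pc1(self):
        rng = np.random.default_rng(0)
        p1 = np.r_[np.full(40, 0.9), np.full(40, 0.1)]
        p2 = np.r_[np.full(40, 0.1), np.full(40, 0.9)]
        data = np.vstack(
            [(rng.random(80) < p1) for _ in range(10)]
            + [(rng.random(80) < p2) for _ in range(10)]
        ).astype(int)
        m = BinaryMarkerMatrix(
            data, [f"s{i}" for i in range(20)], [f"L{j}" for j in range(80)],
            ["A"] * 10 + ["B"] * 10,
        )
        scores, pct = pca_binary(m)
        from sklearn.metrics import silhouette_score

        assert silhouette_score(scores[:, :1], m.species) > 0.8

    def test_duplicated_individual_identical_scores(self, three_species_flock):
        m, _, _ = three_species_flock
        data = np.vstack([m.data, m.data[0]])
        m2 = BinaryMarkerMatrix(
            data, m.sample_ids + ["dup"], m.locus_ids, m.species + [m.species[0]]
        )
        scores, _ = pca_binary(m2)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-9)

    def test_variance_explained_spectrum(self, three_species_flock):
        m, _, _ = three_species_flock
        _, pct = pca_binary(m)
        assert pct.sum() == pytest.approx(100.0)
        assert (np.diff(pct) <= 1e-9).all()

    def test_constant_matrix_rejected(self):
        m = BinaryMarkerMatrix(
            np.ones((3, 4), dtype=int), ["a", "b", "c"],
            [f"L{j}" for j in range(4)], ["A"] * 3,
        )
        with pytest.raises(ValueError, match="constant"):
            pca_binary(m)
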