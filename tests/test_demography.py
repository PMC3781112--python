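import numpy as np
import pytest

from aflpop.demography import (
    expansion_time,
    expected_mismatch,
    fit_sudden_expansion,
    implied_mu,
    mismatch_observed,
    raggedness,
)
from aflpop.io import SequenceAlignment
from aflpop.simulate import simulate_expansion_sequences


class TestMismatchObserved:
    def test_identical_pair(self):
        aln = SequenceAlignment(["a", "b"], ["AAA", "AAA"])
        counts, mean = mismatch_observed(aln)
        assert counts.tolist() == [1]
        assert mean == 0.0

    def test_hand_enumerated_triple(self):
        aln = SequenceAlignment(["a", "b", "c"], ["AAA", "AAT", "ATT"])
        counts, mean = mismatch_observed(aln)
        # pairs differ by 1 (ab), 2 (ac), 1 (bc)
        assert counts.tolist() == [0, 2, 1]
        assert mean == pytest.approx(4 / 3)

    def test_gap_modes(self):
        aln = SequenceAlignment(["a", "b"], ["AC-T", "ACGT"])
        c5, _ = mismatch_observed(aln, "fifth_state")
        cm, _ = mismatch_observed(aln, "missing")
        assert c5.tolist() == [0, 1]  # gap counts as a difference
        assert cm.tolist() == [1]  # gapped site skipped

    def test_mask_excludes_sites(self):
        aln = SequenceAlignment(
            ["a", "b"], ["AAAT", "AAAC"], mask=np.array([False, False, False, True])
        )
        counts, mean = mismatch_observed(aln)
        assert mean == 0.0

    def test_single_sequence_rejected(self):
        aln = SequenceAlignment(["a"], ["AAA"])
        with pytest.raises(ValueError):
            mismatch_observed(aln)


class TestExpectedMismatch:
    def test_point_mass_at_zero(self):
        e = expected_mismatch(0.0, 0.0, 3.0, 10)
        assert e[0] == pytest.approx(1.0)
        assert e[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_no_expansion_limit_is_geometric(self):
        theta = 0.8
        e = expected_mismatch(0.0, theta, theta, 15)
        i = np.arange(16)
        geom = theta**i / (1 + theta) ** (i + 1)
        np.testing.assert_allclose(e, geom, rtol=1e-12)

    def test_expansion_invariant_under_tau_when_thetas_equal(self):
        theta = 1.3
        for tau in (0.5, 2.0, 7.0):
            np.testing.assert_allclose(
                expected_mismatch(tau, theta, theta, 12),
                expected_mismatch(0.0, theta, theta, 12),
                rtol=1e-10,
            )

    def test_matches_simulation_oracle(self):
        # Monte-Carlo spectrum from the coalescent simulator at n = 2
        tau, th0, th1 = 2.5, 0.5625, 1.175
        rng = np.random.default_rng(5)
        from aflpop.demography import _pairwise_differences

        ds = []
        for _ in range(12000):
            aln = simulate_expansion_sequences(th0, th1, tau, 2, 600, rng=rng)
            ds.append(_pairwise_differences(aln.to_codes(), "fifth_state")[0])
        emp = np.bincount(ds, minlength=30)[:30] / len(ds)
        exp = expected_mismatch(tau, th0, th1, 29)
        assert 0.5 * np.abs(emp - exp).sum() < 0.02

    def test_partial_sums_monotone_and_bounded(self):
        e40 = expected_mismatch(1.7, 0.2, 4.0, 40)
        partial = np.cumsum(e40)
        assert (np.diff(partial) >= 0).all()
        assert partial[-1] <= 1.0 + 1e-12
        assert partial[-1] > 0.999  # tail mass eventually negligible

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            expected_mismatch(np.nan, 0.1, 1.0, 5)


class TestRaggedness:
    def test_hand_values(self):
        assert raggedness(np.array([1.0])) == pytest.approx(1.0)
        assert raggedness(np.array([0.5, 0.5])) == pytest.approx(0.25)

    def test_flat_spectrum_smooth_limit(self):
        r20 = raggedness(np.full(20, 1 / 20))
        r200 = raggedness(np.full(200, 1 / 200))
        assert r200 < r20 < 0.01

    def test_validation(self):
        with pytest.raises(ValueError, match="negative"):
            raggedness(np.array([1.5, -0.5]))
        with pytest.raises(ValueError, match="sum"):
            raggedness(np.array([0.4, 0.4]))


class TestFit:
    def test_geometric_input_recovers_tau_zero(self):
        theta = 1.0
        i = np.arange(25)
        counts = 1000 * theta**i / (1 + theta) ** (i + 1)
        fit = fit_sudden_expansion(counts, n_boot=0)
        assert fit.tau < 0.15
        assert fit.ssd < 1e-5

    def test_count_scaling_invariance(self):
        rng = np.random.default_rng(11)
        aln = simulate_expansion_sequences(0.0, 3.0, 2.0, 30, 4000, rng=rng)
        counts, _ = mismatch_observed(aln)
        f1 = fit_sudden_expansion(counts, n_boot=0)
        f2 = fit_sudden_expansion(counts * 7.0, n_boot=0)
        assert f1.tau == pytest.approx(f2.tau, abs=1e-6)
        assert f1.ssd == pytest.approx(f2.ssd, abs=1e-12)

    def test_round_trip_tau_in_bootstrap_interval(self):
        rng = np.random.default_rng(4)
        aln = simulate_expansion_sequences(0.03, 3.0, 1.4, 76, 5000, rng=rng)
        counts, _ = mismatch_observed(aln)
        fit = fit_sudden_expansion(counts, n_boot=0)
        # parametric bootstrap of tau around the fitted model
        taus = []
        brng = np.random.default_rng(6)
        for _ in range(60):
            b = simulate_expansion_sequences(
                fit.theta0, fit.theta1, fit.tau, 76, 5000, rng=brng
            )
            cb, _ = mismatch_observed(b)
            taus.append(fit_sudden_expansion(cb, n_boot=0, refine=False).tau)
        lo, hi = np.quantile(taus, [0.025, 0.975])
        assert lo - 0.05 <= fit.tau <= hi + 0.05

    def test_p_ssd_is_probability_and_theta1_cap_flagged(self):
        rng = np.random.default_rng(9)
        aln = simulate_expansion_sequences(0.0, 99999.0, 0.7, 20, 3000, rng=rng)
        counts, _ = mismatch_observed(aln)
        fit = fit_sudden_expansion(counts, n_boot=60, seed=2)
        assert 0.0 <= fit.p_ssd <= 1.0
        if fit.theta1_capped:
            assert fit.theta1 == 99999.0


class TestRateConversion:
    def test_linearity_in_tau(self):
        t1 = expansion_time(1.0, 0.05, 740)
        t2 = expansion_time(2.0, 0.05, 740)
        assert t2 == pytest.approx(2 * t1)

    def test_implied_per_year_rate(self):
        # tau = 1.4 over 21,021 years implies u = tau / (2 t) = 3.33e-5
        u, _mu = implied_mu(1.4, 21021, 740)
        assert u == pytest.approx(3.33e-5, rel=0.01)

    def test_rate_and_length_consistency(self):
        # with u = 3.33e-5 per sequence-year and mu = 0.045 /site/MY the
        # implied alignment length is ~740 sites
        u, _ = implied_mu(1.4, 21021, 740)
        L_implied = u * 1e6 / 0.045
        assert L_implied == pytest.approx(740, rel=0.01)
        # and the forward conversion returns the assumed time
        assert expansion_time(1.4, 0.045, 740) == pytest.approx(21021, rel=0.01)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            expansion_time(1.0, 0.0, 740)
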