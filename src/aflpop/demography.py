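"""Mismatch-distribution demography under the sudden-expansion model.

The number of differences between two sequences is a Poisson mixture over
the pair's coalescence time.  With time in mutational units, an
instantaneous size change at ``tau`` (scaled size ``theta1`` after the
expansion, ``theta0`` before) gives the closed form

    F_i = Fhat_i(theta1) * P(i+1, (1+1/theta1)*tau)
        + exp(-(1+1/theta1)*tau) * sum_j Fhat_{i-j}(theta0) * tau^j / j!

where ``Fhat_i(theta) = theta^i / (1+theta)^{i+1}`` is the geometric
equilibrium law and ``P`` the regularised lower incomplete gamma function.
The limits check out: ``tau=0`` gives the theta0 equilibrium, ``tau→inf``
the theta1 equilibrium, ``theta0=0`` the pure Poisson(tau) of a star
genealogy, and ``theta0=theta1`` is geometric for every tau.

Fitting minimises the sum of squared deviations (SSD) between observed and
expected relative mismatch frequencies, exactly the quantity whose
parametric-bootstrap distribution provides the goodness-of-fit p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import poisson

from .io import SequenceAlignment
from .simulate import simulate_expansion_sequences

__all__ = [
    "MismatchFit",
    "mismatch_observed",
    "expected_mismatch",
    "fit_sudden_expansion",
    "raggedness",
    "expansion_time",
    "implied_mu",
]

THETA1_CAP = 99999.0


@dataclass
class MismatchFit:
    """Sudden-expansion fit for one population sample."""

    tau: float
    theta0: float
    theta1: float
    mean_pairwise_diff: float
    ssd: float
    p_ssd: float | None
    raggedness: float
    theta1_capped: bool
    n_sequences: int
    converged: bool


def _pairwise_differences(codes: np.ndarray, gap_mode: str) -> np.ndarray:
    """Vector of pairwise difference counts over all unordered pairs.

    Codes follow :meth:`SequenceAlignment.to_codes`; state 4 is the gap,
    state 5 is N.  ``fifth_state`` counts gaps as an ordinary character
    (sites with N in either sequence are skipped); ``missing`` skips sites
    with a gap or N in either sequence.
    """
    n = codes.shape[0]
    diffs = []
    for i in range(n):
        a = codes[i]
        block = codes[i + 1 :]
        if gap_mode == "fifth_state":
            ok = (a != 5) & (block != 5)
        elif gap_mode == "missing":
            ok = (a < 4) & (block < 4)
        else:
            raise ValueError(f"unknown gap_mode {gap_mode!r}")
        diffs.append(((a != block) & ok).sum(axis=1))
    return np.concatenate(diffs) if diffs else np.array([], dtype=int)


def mismatch_observed(
    aln: SequenceAlignment, gap_mode: str = "fifth_state"
) -> tuple[np.ndarray, float]:
    """Observed mismatch spectrum and mean pairwise differences.

    Returns ``(counts, mean)`` where ``counts[i]`` is the number of
    unordered sequence pairs differing at exactly ``i`` unmasked sites.
    """
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    d = _pairwise_differences(aln.to_codes(), gap_mode)
    counts = np.bincount(d)
    return counts, float(d.mean())


def _geometric(theta: float, i_max: int) -> np.ndarray:
    i = np.arange(i_max + 1)
    if theta == 0.0:
        out = np.zeros(i_max + 1)
        out[0] = 1.0
        return out
    # theta^i/(1+theta)^{i+1} in log space for large theta
    log_f = i * np.log(theta) - (i + 1) * np.log1p(theta)
    return np.exp(log_f)


def expected_mismatch(
    tau: float, theta0: float, theta1: float, i_max: int
) -> np.ndarray:
    """Probabilities of 0..i_max pairwise differences under sudden expansion.

    The vector sums to less than 1; the remainder is the tail mass beyond
    ``i_max``.
    """
    for name, v in (("tau", tau), ("theta0", theta0), ("theta1", theta1)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0")
    if theta1 == 0.0:
        theta1 = 1e-12
    a = 1.0 + 1.0 / theta1
    i = np.arange(i_max + 1)
    part1 = _geometric(theta1, i_max) * gammainc(i + 1, a * tau)
    pois = poisson.pmf(i, tau) if tau > 0 else np.eye(1, i_max + 1, 0).ravel()
    part2 = np.exp(-tau / theta1) * np.convolve(_geometric(theta0, i_max), pois)[: i_max + 1]
    return part1 + part2


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness index on a relative mismatch spectrum.

    ``r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2`` with ``x_{d+1} = 0``; smooth,
    unimodal spectra (expanding populations) give small values.
    """
    x = np.asarray(freqs, dtype=float)
    if (x < 0).any():
        raise ValueError("negative frequencies")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    x = np.append(x, 0.0)
    return float(np.sum(np.diff(x) ** 2))


def _ssd(rel_obs: np.ndarray, tau: float, th0: float, th1: float) -> float:
    exp = expected_mismatch(tau, th0, th1, len(rel_obs) - 1)
    return float(np.sum((rel_obs - exp) ** 2))


def _objective(rel_obs: np.ndarray, tau: float, th0: float, th1: float) -> float:
    # the model is invariant in tau when theta0 = theta1, leaving tau
    # unidentified on equilibrium-shaped spectra; an infinitesimal penalty
    # breaks those exact ties toward the parsimonious tau = 0 solution
    return _ssd(rel_obs, tau, th0, th1) + 1e-8 * tau


def _grid_fit(rel_obs: np.ndarray, mean_d: float, coarse: bool) -> tuple[float, float, float]:
    n_tau = 12 if coarse else 24
    taus = np.linspace(0.0, 2.0 * mean_d + 4.0, n_tau)
    th0s = np.concatenate([[0.0], np.geomspace(0.01, max(mean_d, 0.02), 4 if coarse else 7)])
    th1s = np.concatenate(
        [np.geomspace(max(mean_d, 0.1), 1e4, 6 if coarse else 10), [THETA1_CAP]]
    )
    best, best_ssd = (0.0, 0.0, 1.0), np.inf
    for tau in taus:
        for th0 in th0s:
            for th1 in th1s:
                s = _objective(rel_obs, tau, th0, th1)
                if s < best_ssd:
                    best_ssd, best = s, (tau, th0, th1)
    return best


def fit_sudden_expansion(
    counts: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    refine: bool = True,
    gap_mode: str = "fifth_state",
) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to a mismatch spectrum.

    ``counts[i]`` = number of pairs with i differences.  The fit is a
    coarse grid followed by Nelder–Mead refinement; ``theta1`` is capped at
    99999 (flagged) where the likelihood surface is flat in that direction.
    ``p_ssd`` is the parametric-bootstrap probability of an SSD at least as
    large as observed, obtained by simulating samples of the same size
    under the fitted model and refitting each; ``n_boot=0`` skips it.
    The fit is invariant to scaling the counts by a constant.
    """
    counts = np.asarray(counts, dtype=float)
    n_pairs = counts.sum()
    if n_pairs <= 0:
        raise ValueError("empty mismatch spectrum")
    # sample size that produced n(n-1)/2 pairs (for the bootstrap)
    n_seq = int(round((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    if n_seq < 3:
        raise ValueError("counts must come from at least 3 sequences")
    rel = counts / n_pairs
    mean_d = float(np.sum(np.arange(len(counts)) * rel))

    tau, th0, th1 = _grid_fit(rel, mean_d, coarse=not refine)
    converged = True
    if refine:
        def objective(z):
            t, a, b = np.abs(z)
            return _objective(rel, t, a, min(b, THETA1_CAP))

        res = minimize(
            objective,
            x0=np.array([tau, th0, min(th1, THETA1_CAP)]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 2000},
        )
        if res.success:
            tau, th0, th1 = np.abs(res.x)
            th1 = min(th1, THETA1_CAP)
        else:
            converged = False
            warnings.warn("Nelder-Mead refinement did not converge; grid optimum kept")
    ssd_obs = _ssd(rel, tau, th0, th1)
    capped = th1 >= THETA1_CAP * 0.999
    if capped:
        th1 = THETA1_CAP

    p_ssd = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        worse = 0
        for _ in range(n_boot):
            aln = _simulate_for_boot(th0, th1, tau, n_seq, rng)
            c_b, _ = mismatch_observed(aln, gap_mode)
            rel_b = c_b / c_b.sum()
            mean_b = float(np.sum(np.arange(len(c_b)) * rel_b))
            tb, a0, a1 = _grid_fit(rel_b, mean_b, coarse=True)
            if _ssd(rel_b, tb, a0, a1) >= ssd_obs:
                worse += 1
        p_ssd = worse / n_boot

    return MismatchFit(
        tau=float(tau),
        theta0=float(th0),
        theta1=float(th1),
        mean_pairwise_diff=mean_d,
        ssd=ssd_obs,
        p_ssd=p_ssd,
        raggedness=raggedness(rel),
        theta1_capped=bool(capped),
        n_sequences=n_seq,
        converged=converged,
    )


def _simulate_for_boot(th0, th1, tau, n, rng) -> SequenceAlignment:
    L = 2000
    for _ in range(5):
        try:
            return simulate_expansion_sequences(th0, th1, tau, n, L, rng=rng)
        except ValueError:
            L *= 4
    raise RuntimeError("could not place mutations even on a very long sequence")


# ---------------------------------------------------------------------------
# rate / time conversion


def expansion_time(
    tau: float, mu_site: float, L: int, gen_time_years: float | None = None
) -> float:
    """Years since expansion implied by tau and a substitution rate.

    ``mu_site`` is in substitutions per site per million years per lineage
    (the conventional control-region unit); the per-sequence rate per year
    is ``u = mu_site * L / 1e6`` and ``t = tau / (2u)``.  If the rate is
    instead supplied per generation, pass ``gen_time_years`` to rescale
    (t is then in years = generations * gen_time).
    """
    if mu_site <= 0 or L <= 0 or tau < 0:
        raise ValueError("rates, lengths must be positive and tau >= 0")
    u_per_year = mu_site * L / 1e6
    t = tau / (2.0 * u_per_year)
    if gen_time_years is not None:
        t *= gen_time_years
    return t


def implied_mu(tau: float, t_years: float, L: int) -> tuple[float, float]:
    """Per-sequence-per-year rate and per-site-per-MY rate implied by
    tau and an assumed expansion time (the plausibility check used to vet
    mismatch results against a known lake age)."""
    if t_years <= 0 or L <= 0:
        raise ValueError("t_years and L must be positive")
    u_per_year = tau / (2.0 * t_years)
    mu_site = u_per_year * 1e6 / L
    return u_per_year, mu_site
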