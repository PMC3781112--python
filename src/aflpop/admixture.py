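"""Model-based clustering of dominant binary markers.

A STRUCTURE-style admixture model adapted to dominant data: each band is
treated as a haploid Bernoulli character, individual i draws the origin
of locus l from its ancestry vector q_i ~ Dirichlet(alpha), and cluster k
carries band frequency p_kl tied to an ancestral frequency pA_l through
the correlated-frequencies (Balding–Nichols) prior with per-cluster
drift F_k:

    p_kl ~ Beta(pA_l (1-F_k)/F_k, (1-pA_l)(1-F_k)/F_k).

All parameters, including the admixture concentration alpha and the
ancestral-frequency shape lambda, are sampled by Metropolis-within-Gibbs.
The model log-evidence per run is estimated from the likelihood trace as
mean(L) - var(L)/2 (the standard harmonic-style estimator used for the
"LnP(D)" model-choice statistic), and the number of clusters is chosen by
the Evanno second-difference statistic Delta K.

Ancestry testing with prior population information follows the
use-population-information design: each individual is evaluated against
the hypothesis set {pure member of its labelled species} union
{immigrant at generation g from species s} for g = 0 (self), 1 (parent),
2 (grandparent), with prior mass nu on the non-pure hypotheses split
geometrically over generations and uniformly over source species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import BinaryMarkerMatrix

__all__ = [
    "AdmixtureResult",
    "EvannoResult",
    "fit_admixture",
    "evanno_deltaK",
    "ancestry_test",
    "pca_binary",
    "match_clusters",
]


@dataclass
class AdmixtureResult:
    K: int
    Q: np.ndarray  # n_individuals x K posterior-mean ancestry
    P: np.ndarray  # K x n_loci posterior-mean band frequencies
    lnPD: float
    alpha: float
    lam: float
    drift: np.ndarray  # posterior-mean F_k
    loglik_trace: np.ndarray
    converged: bool
    burnin: int
    iterations: int
    seed: int | None


def _dirichlet_logpdf(q: np.ndarray, alpha: float) -> float:
    K = q.shape[1]
    return float(
        q.shape[0] * (gammaln(K * alpha) - K * gammaln(alpha))
        + (alpha - 1.0) * np.log(np.clip(q, 1e-300, None)).sum()
    )


def fit_admixture(
    m: BinaryMarkerMatrix,
    K: int,
    burnin: int = 5000,
    iterations: int = 10000,
    n_reps: int = 5,
    seed: int | None = None,
    slope_tol: float = 2.0,
) -> list[AdmixtureResult]:
    """Gibbs-sample the admixture model for ``n_reps`` replicate runs.

    ``iterations`` counts the kept (post-burn-in) sweeps.  Replicates whose
    post-burn-in likelihood trace still drifts (absolute slope of the
    fitted line, in log-likelihood units per 100 sweeps, above
    ``slope_tol`` standard errors) are flagged ``converged=False`` —
    the screening that replaces eyeballing likelihood-vs-iteration plots.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m.n_samples:
        raise ValueError("K larger than the number of individuals")
    master = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        rep_seed = int(master.integers(2**31))
        out.append(_one_run(m, K, burnin, iterations, rep_seed, slope_tol))
    return out


def _one_run(m, K, burnin, iterations, seed, slope_tol) -> AdmixtureResult:
    rng = np.random.default_rng(seed)
    X = m.data.astype(np.float64)  # n x L
    n, L = X.shape

    pA = np.clip(X.mean(axis=0), 0.05, 0.95)
    drift = np.full(K, 0.1)
    lam = 1.0
    alpha = 1.0
    # seed cluster frequencies from the band profiles of K random
    # individuals (distinct per replicate): data-informed starting points
    # disperse the chains across modes and cut the burn-in needed at desk
    # scale, while the stationary distribution is untouched
    anchors = rng.choice(n, size=K, replace=False)
    P = np.clip(0.7 * X[anchors] + 0.3 * pA[None, :], 0.02, 0.98)
    Q = rng.dirichlet(np.ones(K), size=n)

    if X.var() == 0 and K > 1:
        warnings.warn("all individuals identical; clusters are exchangeable")

    keep_every = 5
    trace = []
    Q_acc = np.zeros_like(Q)
    P_acc = np.zeros_like(P)
    drift_acc = np.zeros(K)
    alpha_acc = lam_acc = 0.0
    n_kept = 0

    total = burnin + iterations
    for step in range(total):
        # --- z: latent cluster of origin per individual x locus
        like = P[None, :, :] * X[:, None, :] + (1 - P[None, :, :]) * (1 - X[:, None, :])
        w = Q[:, :, None] * like  # n x K x L
        wsum = w.sum(axis=1)
        u = rng.random((n, L)) * wsum
        cum = np.cumsum(w, axis=1)
        z = (u[:, None, :] < cum).argmax(axis=1)  # n x L

        # --- P | z (conjugate Beta under the correlated prior)
        onehot = np.eye(K)[z]  # n x L x K
        cnt = onehot.sum(axis=0).T  # K x L
        ones = np.einsum("nlk,nl->kl", onehot, X)
        c = (1 - drift) / drift
        a = pA[None, :] * c[:, None] + ones
        b = (1 - pA[None, :]) * c[:, None] + (cnt - ones)
        P = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)

        # --- Q | z
        mcounts = onehot.sum(axis=1)  # n x K
        gam = rng.gamma(alpha + mcounts)
        Q = gam / gam.sum(axis=1, keepdims=True)

        # --- pA (ancestral frequencies), Metropolis, vectorised over loci
        prop = np.clip(pA + rng.normal(0, 0.05, L), 1e-3, 1 - 1e-3)
        def pa_loglik(pa_vec):
            cc = (1 - drift)[:, None] / drift[:, None]
            aa = pa_vec[None, :] * cc
            bb = (1 - pa_vec[None, :]) * cc
            term = (
                gammaln(aa + bb) - gammaln(aa) - gammaln(bb)
                + (aa - 1) * np.log(P) + (bb - 1) * np.log(1 - P)
            ).sum(axis=0)
            prior = (lam - 1) * (np.log(pa_vec) + np.log(1 - pa_vec))
            return term + prior
        log_r = pa_loglik(prop) - pa_loglik(pA)
        acc = np.log(rng.random(L)) < log_r
        pA[acc] = prop[acc]

        # --- drift F_k, Metropolis
        for k in range(K):
            fprop = float(np.clip(drift[k] * np.exp(rng.normal(0, 0.2)), 1e-4, 0.9))
            def f_loglik(f):
                cc = (1 - f) / f
                aa = pA * cc
                bb = (1 - pA) * cc
                return float(
                    (gammaln(aa + bb) - gammaln(aa) - gammaln(bb)
                     + (aa - 1) * np.log(P[k]) + (bb - 1) * np.log(1 - P[k])).sum()
                )
            log_r = f_loglik(fprop) - f_loglik(drift[k]) + np.log(fprop) - np.log(drift[k])
            if np.log(rng.random()) < log_r:
                drift[k] = fprop

        # --- alpha, Metropolis (uniform prior on [0.02, 10])
        aprop = float(np.clip(alpha * np.exp(rng.normal(0, 0.2)), 0.02, 10.0))
        log_r = (
            _dirichlet_logpdf(Q, aprop) - _dirichlet_logpdf(Q, alpha)
            + np.log(aprop) - np.log(alpha)
        )
        if np.log(rng.random()) < log_r:
            alpha = aprop

        # --- lambda, Metropolis (uniform prior on [0.05, 10])
        lprop = float(np.clip(lam * np.exp(rng.normal(0, 0.2)), 0.05, 10.0))
        def lam_loglik(l):
            return float(
                L * (gammaln(2 * l) - 2 * gammaln(l))
                + (l - 1) * (np.log(pA) + np.log(1 - pA)).sum()
            )
        log_r = lam_loglik(lprop) - lam_loglik(lam) + np.log(lprop) - np.log(lam)
        if np.log(rng.random()) < log_r:
            lam = lprop

        ll = float(np.log(np.clip(wsum, 1e-300, None)).sum())
        if step >= burnin:
            trace.append(ll)
            if (step - burnin) % keep_every == 0:
                n_kept += 1
                Q_acc += Q
                P_acc += P
                drift_acc += drift
                alpha_acc += alpha
                lam_acc += lam

    trace = np.asarray(trace)
    lnPD = float(trace.mean() - trace.var() / 2.0)

    # convergence screen: total linear drift across the kept window must
    # stay within slope_tol trace standard deviations
    t = np.arange(len(trace), dtype=float)
    if len(trace) >= 10 and trace.std() > 0:
        slope = np.polyfit(t, trace, 1)[0]
        converged = bool(abs(slope) * len(trace) <= slope_tol * trace.std())
    else:
        converged = True

    return AdmixtureResult(
        K=K,
        Q=Q_acc / max(n_kept, 1),
        P=P_acc / max(n_kept, 1),
        lnPD=lnPD,
        alpha=alpha_acc / max(n_kept, 1),
        lam=lam_acc / max(n_kept, 1),
        drift=drift_acc / max(n_kept, 1),
        loglik_trace=trace,
        converged=converged,
        burnin=burnin,
        iterations=iterations,
        seed=seed,
    )


def match_clusters(Q: np.ndarray, labels: list[str]) -> tuple[dict, float]:
    """Greedy cluster-to-species matching and assignment accuracy.

    Assigns each cluster to the species whose members give it the highest
    mean ancestry (largest first); returns (mapping, fraction of
    individuals whose max-Q cluster maps to their species).
    """
    species = list(dict.fromkeys(labels))
    lab = np.asarray(labels)
    K = Q.shape[1]
    means = np.vstack([Q[lab == sp].mean(axis=0) for sp in species])  # S x K
    mapping: dict[int, str] = {}
    used: set[str] = set()
    order = np.dstack(np.unravel_index(np.argsort(-means, axis=None), means.shape))[0]
    for s_ix, k_ix in order:
        sp = species[s_ix]
        if k_ix in mapping or sp in used:
            continue
        mapping[int(k_ix)] = sp
        used.add(sp)
        if len(mapping) == K or len(used) == len(species):
            break
    best = Q.argmax(axis=1)
    correct = sum(mapping.get(int(k), None) == l for k, l in zip(best, lab))
    return mapping, correct / len(lab)


# ---------------------------------------------------------------------------
# Evanno


@dataclass
class EvannoResult:
    table: pd.DataFrame  # per K: mean_lnPD, sd_lnPD, delta_K

    @property
    def best_K(self) -> int:
        t = self.table.dropna(subset=["delta_K"])
        return int(t.loc[t.delta_K.idxmax(), "K"])


def evanno_deltaK(runs_by_K: dict[int, list[AdmixtureResult]]) -> EvannoResult:
    """Second-difference statistic on the model log-evidence.

    Delta K(K) = |L(K+1) - 2 L(K) + L(K-1)| / SD(L(K)), with L the mean
    lnPD over replicates; undefined at the boundary K values.
    """
    Ks = sorted(runs_by_K)
    if len(Ks) < 3 or Ks != list(range(Ks[0], Ks[-1] + 1)):
        raise ValueError("need at least 3 consecutive K values")
    mean = {}
    sd = {}
    for K, runs in runs_by_K.items():
        if len(runs) < 2:
            raise ValueError(f"need >= 2 replicates at K={K}")
        vals = np.array([r.lnPD for r in runs])
        mean[K], sd[K] = vals.mean(), vals.std(ddof=1)
    rows = []
    for K in Ks:
        if K == Ks[0] or K == Ks[-1]:
            dk = np.nan
        else:
            num = abs(mean[K + 1] - 2 * mean[K] + mean[K - 1])
            if sd[K] == 0:
                warnings.warn(f"zero SD of lnPD at K={K}; delta K infinite")
                dk = np.inf
            else:
                dk = num / sd[K]
        rows.append((K, mean[K], sd[K], dk))
    return EvannoResult(pd.DataFrame(rows, columns=["K", "mean_lnPD", "sd_lnPD", "delta_K"]))


# ---------------------------------------------------------------------------
# ancestry testing with prior population information


def ancestry_test(
    m: BinaryMarkerMatrix,
    labels: list[str] | None = None,
    gb: int = 2,
    nu: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Posterior over immigrant-ancestry hypotheses per individual.

    Species band frequencies are plug-in posterior means estimated from the
    labelled individuals with a Jeffreys prior, leaving the focal
    individual out of its own species' estimate.  Hypotheses: pure member
    (prior 1 - nu) or an ancestor at generation g in {0..gb} from another
    species s (prior nu split 2^-g-proportionally over generations and
    evenly over sources).  An ancestor at generation g contributes an
    expected genome fraction 2^-g, so the per-locus likelihood is the
    corresponding two-population mixture.

    Returns a tidy frame: individual, species, p_pure, and the modal
    non-pure hypothesis with its probability, plus one column per
    (source, generation) hypothesis probability.
    """
    if labels is None:
        labels = list(m.species)
    if gb not in (0, 1, 2):
        raise ValueError("gb must be 0, 1 or 2")
    if not (0.0 < nu < 1.0):
        raise ValueError("nu must be in (0, 1)")
    lab = np.asarray(labels)
    species = list(dict.fromkeys(labels))
    X = m.data.astype(float)
    n, L = X.shape

    counts = {sp: X[lab == sp].sum(axis=0) for sp in species}
    sizes = {sp: int((lab == sp).sum()) for sp in species}
    for sp, sz in sizes.items():
        if sz < 2:
            warnings.warn(f"species {sp!r} has < 2 labelled members; frequencies unreliable")

    gens = list(range(gb + 1))
    gen_w = np.array([2.0 ** -g for g in gens])
    gen_w = gen_w / gen_w.sum()

    rows = []
    for i in range(n):
        own = lab[i]
        own_cnt = counts[own] - X[i]
        own_n = sizes[own] - 1
        p_own = (own_cnt + 0.5) / (own_n + 1.0)
        logls = {}
        logls["pure"] = float(
            (X[i] * np.log(p_own) + (1 - X[i]) * np.log(1 - p_own)).sum()
        )
        others = [sp for sp in species if sp != own]
        for sp in others:
            p_src = (counts[sp] + 0.5) / (sizes[sp] + 1.0)
            for g in gens:
                frac = 2.0 ** -g
                p_mix = frac * p_src + (1 - frac) * p_own
                logls[(sp, g)] = float(
                    (X[i] * np.log(p_mix) + (1 - X[i]) * np.log(1 - p_mix)).sum()
                )
        prior = {"pure": 1.0 - nu}
        if others:
            for sp in others:
                for g in gens:
                    prior[(sp, g)] = nu * gen_w[g] / len(others)
        keys = list(logls)
        logpost = np.array([logls[k] + np.log(prior[k]) for k in keys])
        logpost -= logpost.max()
        post = np.exp(logpost)
        post /= post.sum()
        pmap = dict(zip(keys, post))
        nonpure = [(k, v) for k, v in pmap.items() if k != "pure"]
        modal = max(nonpure, key=lambda kv: kv[1]) if nonpure else (None, 0.0)
        row = {
            "individual": m.sample_ids[i],
            "species": own,
            "p_pure": pmap["pure"],
            "modal_hypothesis": _hyp_name(modal[0]),
            "modal_prob": modal[1],
        }
        for k, v in pmap.items():
            if k != "pure":
                row[_hyp_name(k)] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _hyp_name(k) -> str | None:
    if k is None:
        return None
    sp, g = k
    kind = {0: "immigrant", 1: "parent", 2: "grandparent"}[g]
    return f"{kind}:{sp}"


# ---------------------------------------------------------------------------
# PCA


def pca_binary(m: BinaryMarkerMatrix, n_components: int | None = None):
    """Column-centred covariance PCA of the band matrix.

    Returns ``(scores, pct_variance)``; components are ordered by
    decreasing variance explained.
    """
    if m.n_samples < 2 or m.n_loci < 2:
        raise ValueError("need at least 2 samples and 2 loci")
    X = m.data.astype(float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no variance to decompose")
    u, s, _vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (m.n_samples - 1)
    pct = 100.0 * var / var.sum()
    scores = u * s
    if n_components is not None:
        scores, pct = scores[:, :n_components], pct[:n_components]
    return scores, pct
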