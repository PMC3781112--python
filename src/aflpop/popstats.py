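"""F-statistics, AMOVA and private-allele accounting.

Differentiation statistics are computed as analyses of molecular variance
(AMOVA) on squared inter-individual distances: the among-groups share of
the total molecular variance is the fixation index (FST when distances are
pairwise band/nucleotide differences, PhiST when a metric such as the
Jaccard-transformed distance weights the comparison).  Significance comes
from permuting individuals among groups; negative estimates are reported
unclamped, as is conventional for variance-component estimators.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BinaryMarkerMatrix
from .trees import DistanceMatrix

__all__ = [
    "PopDiffResult",
    "AmovaResult",
    "amova",
    "pairwise_fst",
    "private_alleles",
    "holm_adjust",
]


@dataclass
class AmovaResult:
    """One-level AMOVA decomposition."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among groups", "within groups"],
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "variance": [self.sigma2_among, self.sigma2_within],
                "pct_variation": [self.pct_among, self.pct_within],
            }
        )


def _phi_from_d2(d2: np.ndarray, onehot: np.ndarray, sizes: np.ndarray):
    """(phi, sigma2_a, sigma2_w, ss_a, ss_w) from squared distances and a
    one-hot group membership matrix."""
    N = d2.shape[0]
    G = onehot.shape[1]
    ss_total = d2.sum() / (2.0 * N)
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / 2.0
    ss_within = (within / sizes).sum()
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, N - G
    ms_w = ss_within / df_w
    n_prime = (N - (sizes**2).sum() / N) / df_a
    sigma2_a = (ss_among / df_a - ms_w) / n_prime
    sigma2_w = ms_w
    total = sigma2_a + sigma2_w
    phi = sigma2_a / total if total > 0 else 0.0
    return phi, sigma2_a, sigma2_w, ss_among, ss_within


def amova(
    d: DistanceMatrix,
    groups: list[str],
    n_perm: int = 10100,
    seed: int | None = None,
    squared: bool = False,
) -> AmovaResult:
    """One-level AMOVA from an inter-individual distance matrix.

    ``squared=True`` means the matrix entries are already squared Euclidean
    distances (e.g. counts of pairwise differences); otherwise entries are
    squared before the sums of squares are formed.  The permutation test
    shuffles individuals among groups, keeping group sizes.
    """
    labels = np.asarray(groups)
    if len(labels) != len(d.ids):
        raise ValueError("one group label per individual required")
    uniq, inv = np.unique(labels, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise ValueError("AMOVA undefined with a single group")
    sizes = np.bincount(inv).astype(float)
    if (sizes < 2).any():
        small = uniq[sizes < 2]
        raise ValueError(f"groups of size 1 not allowed: {list(small)}")

    d2 = d.data**2 if not squared else d.data.astype(float)
    N = len(labels)
    onehot = np.zeros((N, G))
    onehot[np.arange(N), inv] = 1.0

    phi, s2a, s2w, ssa, ssw = _phi_from_d2(d2, onehot, sizes)
    total = s2a + s2w
    if total <= 0:
        warnings.warn("zero total molecular variance; statistic defined as 0")
        pct_a = pct_w = 0.0
    else:
        pct_a = 100.0 * s2a / total
        pct_w = 100.0 * s2w / total

    p = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            phi_p, *_ = _phi_from_d2(d2, onehot[perm], sizes)
            if phi_p >= phi:
                count += 1
        p = (count + 1) / (n_perm + 1)

    return AmovaResult(
        df_among=G - 1,
        df_within=N - G,
        ss_among=ssa,
        ss_within=ssw,
        sigma2_among=s2a,
        sigma2_within=s2w,
        pct_among=pct_a,
        pct_within=pct_w,
        phi_st=phi,
        p_value=p,
        n_permutations=n_perm or 0,
    )


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Sequential-Bonferroni (Holm) adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class PopDiffResult:
    """Pairwise differentiation with permutation p-values."""

    statistic: pd.DataFrame  # group x group, NaN diagonal
    p_values: pd.DataFrame
    p_adjusted: pd.DataFrame
    method: str
    n_permutations: int
    adjustment: str = "holm"

    def pair(self, a: str, b: str) -> float:
        return float(self.statistic.loc[a, b])


def pairwise_fst(
    d: DistanceMatrix,
    groups: list[str],
    n_perm: int = 10100,
    seed: int | None = None,
    squared: bool = False,
) -> PopDiffResult:
    """All pairwise fixation indices via two-group AMOVAs.

    Each pair of groups enters a two-group AMOVA on the distance submatrix;
    p-values come from permuting individuals between the two groups and are
    sequential-Bonferroni adjusted across the pairs.  Negative estimates
    are kept (they indicate within-group variance exceeding the total).
    """
    labels = np.asarray(groups)
    uniq = list(dict.fromkeys(labels))  # order of first appearance
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)

    stat = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    pmat = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    raw_ps, pairs = [], []
    for a, b in itertools.combinations(uniq, 2):
        keep = np.flatnonzero((labels == a) | (labels == b))
        sub = DistanceMatrix(
            ids=[d.ids[i] for i in keep],
            data=d.data[np.ix_(keep, keep)],
            method=d.method,
        )
        res = amova(
            sub, list(labels[keep]), n_perm=n_perm,
            seed=int(rng.integers(2**31)), squared=squared,
        )
        stat.loc[a, b] = stat.loc[b, a] = res.phi_st
        pmat.loc[a, b] = pmat.loc[b, a] = res.p_value
        raw_ps.append(res.p_value)
        pairs.append((a, b))

    padj = pd.DataFrame(np.nan, index=uniq, columns=uniq)
    if n_perm:
        adj = holm_adjust(np.array(raw_ps))
        for (a, b), q in zip(pairs, adj):
            padj.loc[a, b] = padj.loc[b, a] = q

    return PopDiffResult(
        statistic=stat,
        p_values=pmat,
        p_adjusted=padj,
        method=d.method,
        n_permutations=n_perm or 0,
    )


def sequence_distance_matrix(aln, mode: str = "p_distance") -> DistanceMatrix:
    """Inter-individual distances from an alignment, for PhiST/AMOVA.

    ``p_distance`` counts pairwise differences at unmasked sites (the
    distance-weighted variant, the primary choice); ``identity`` scores
    0/1 for same/different haplotype, reducing the AMOVA to haplotype
    frequencies only.  Entries are difference counts: pass
    ``squared=True`` to :func:`amova` / :func:`pairwise_fst`, matching
    the pairwise-difference convention.
    """
    from scipy.spatial.distance import squareform

    from .demography import _pairwise_differences

    d = _pairwise_differences(aln.to_codes(), "fifth_state").astype(float)
    if mode == "identity":
        d = (d > 0).astype(float)
    elif mode != "p_distance":
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceMatrix(list(aln.sample_ids), squareform(d), f"mtdna_{mode}")


def private_alleles(m: BinaryMarkerMatrix) -> pd.DataFrame:
    """Private and fixed-private band counts per species.

    A band is private to species S when present in at least one member of
    S and absent from every other individual; fixed private when it is
    additionally present in every member of S.
    """
    groups = m.species_groups()
    rows = []
    present_by_sp = {sp: m.data[ix].any(axis=0) for sp, ix in groups.items()}
    all_by_sp = {sp: m.data[ix].all(axis=0) for sp, ix in groups.items()}
    for sp, ix in groups.items():
        others = np.zeros(m.n_loci, dtype=bool)
        for other, pres in present_by_sp.items():
            if other != sp:
                others |= pres
        private = present_by_sp[sp] & ~others
        fixed_private = all_by_sp[sp] & ~others
        rows.append((sp, int(private.sum()), int(fixed_private.sum())))
    return pd.DataFrame(rows, columns=["species", "private_bands", "fixed_private_bands"])
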