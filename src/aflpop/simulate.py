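"""Synthetic species-flock generator.

Produces the two data types the pipeline consumes with known ground truth:

* mtDNA-style sequence samples from a coalescent with a single
  instantaneous population-size change (the sudden-expansion model), in
  mutational time units, so that demographic fits can be validated against
  the parameters that generated the data;
* binary dominant-marker (AFLP-style) matrices for a flock of closely
  related species, with neutral and divergently selected loci, admixed
  individuals and an introgressed subgroup carrying fixed private bands.

The drift model for band frequencies is the Balding–Nichols ("F-model")
parameterisation: species frequencies are Beta-distributed around an
ancestral frequency with variance set by the target FST, which matches the
correlated-allele-frequencies assumption of the model-based clustering.
Band presence is treated as a haploid Bernoulli character per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import BinaryMarkerMatrix, SequenceAlignment

__all__ = [
    "FlockConfig",
    "FlockTruth",
    "simulate_expansion_sequences",
    "simulate_flock",
]

_BASES = np.array(list("ACGT"))

#: Per-species sample sizes and sudden-expansion parameters (tau, theta0,
#: theta1) used by the default configuration.  These emulate a six-species
#: crater-lake cichlid flock: modest sample sizes per species and recent
#: expansions of varying age and intensity.
DEFAULT_SPECIES = ("astorquii", "chancho", "flaveolus", "globosus", "supercilius", "zaliosus")
DEFAULT_N_PER_SPECIES = (18, 21, 20, 20, 19, 22)
DEFAULT_EXPANSION = (
    (1.4, 0.03164, 2.947),
    (2.6, 0.0, 3.062),
    (2.5, 0.00703, 6.210),
    (0.7, 0.0, 99999.0),
    (2.5, 0.5625, 1.175),
    (1.0, 0.0, 427.35),
)


@dataclass
class FlockConfig:
    """Configuration of the synthetic flock.

    Defaults describe the study conditions the analysis is designed for:
    six young species with ~20 individuals each, 2297 dominant loci of
    which ~2% are under divergent selection, a handful of admixed
    individuals, and one introgressed subgroup of seven individuals with
    four fixed private bands.
    """

    n_species: int = 6
    species_names: Sequence[str] = DEFAULT_SPECIES
    n_per_species: Sequence[int] = DEFAULT_N_PER_SPECIES
    n_loci: int = 2297
    frac_outlier: float = 0.02
    fst_neutral: float = 0.10
    fst_outlier: float = 0.50
    #: list of (label, (parent_a, parent_b), generation) with generation in
    #: {"F1", "grandparent"}; the hybrid is appended as an extra individual
    #: labelled as parent_a (mimicking a misidentified field sample).
    hybrid_spec: Sequence[tuple] = ()
    #: (species, n_individuals, n_fixed_private_bands) or None.
    introgressed_spec: tuple | None = ("zaliosus", 7, 4)
    seq_len: int = 740
    n_locations: int = 3
    expansion_params: Sequence[tuple] = DEFAULT_EXPANSION
    gen_time_years: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.n_loci < 1 or self.seq_len < 1:
            raise ValueError("counts must be >= 1")
        if len(self.species_names) != self.n_species:
            raise ValueError("species_names length must equal n_species")
        if len(self.n_per_species) != self.n_species:
            raise ValueError("n_per_species length must equal n_species")
        if any(n < 1 for n in self.n_per_species):
            raise ValueError("all per-species sample sizes must be >= 1")
        if not (0.0 <= self.frac_outlier <= 1.0):
            raise ValueError("frac_outlier must be in [0, 1]")
        for f in (self.fst_neutral, self.fst_outlier):
            if not (0.0 <= f < 1.0):
                raise ValueError("FST targets must be in [0, 1)")
        if self.frac_outlier > 0 and self.fst_outlier <= self.fst_neutral:
            raise ValueError("fst_outlier must exceed fst_neutral")
        if len(self.expansion_params) != self.n_species:
            raise ValueError("expansion_params must give (tau, theta0, theta1) per species")
        for name, _pair, gen in self.hybrid_spec:
            if gen not in ("F1", "grandparent"):
                raise ValueError(f"unknown hybrid generation {gen!r} for {name!r}")
        if self.introgressed_spec is not None:
            sp, n_ind, n_priv = self.introgressed_spec
            if sp not in self.species_names:
                raise ValueError(f"introgressed species {sp!r} not in species_names")
            if n_priv > self.n_loci:
                raise ValueError("more fixed private bands requested than loci")
            if n_ind > self.n_per_species[list(self.species_names).index(sp)]:
                raise ValueError("introgressed subgroup larger than its species sample")


@dataclass
class FlockTruth:
    """Ground truth of one simulated flock, for parameter-recovery tests."""

    species: list[str]
    ancestry: np.ndarray  # n_individuals x n_species, rows sum to 1
    outlier_loci: np.ndarray  # indices into the locus axis
    introgressed_individuals: np.ndarray  # row indices
    private_loci: np.ndarray  # indices of the planted fixed private bands
    expansion_params: dict[str, tuple]

    def __post_init__(self) -> None:
        sums = self.ancestry.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("ancestry fractions must sum to 1 per individual")


# ---------------------------------------------------------------------------
# coalescent under instantaneous expansion


def simulate_expansion_sequences(
    theta0: float,
    theta1: float,
    tau: float,
    n: int,
    L: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ancestral: str | None = None,
    id_prefix: str = "seq",
) -> SequenceAlignment:
    """Sample ``n`` aligned sequences under a sudden-expansion coalescent.

    Time is measured in mutational units (tau = 2*u*t with u the
    per-sequence mutation rate per generation).  Looking backwards, the
    population has scaled size ``theta1`` until ``tau``, and ``theta0``
    beyond; ``theta0 = 0`` collapses all remaining lineages at ``tau``
    (star genealogy).  Mutations are Poisson with rate 1/2 per unit branch
    length, so for a constant-size population E[pairwise differences] =
    theta.  Infinite-sites placement: each mutation occupies a distinct
    position among ``L``; more mutations than positions is an error rather
    than a silent violation.
    """
    for name, v in (("theta0", theta0), ("theta1", theta1), ("tau", tau)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0")
    if theta1 <= 0:
        raise ValueError("theta1 must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)

    # Hudson coalescent with one epoch change at tau (mutational units).
    parent = np.full(2 * n - 1, -1, dtype=int)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    next_node = n
    t = 0.0
    recent_epoch = True  # more recent than the expansion at tau
    epoch_theta = theta1
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / epoch_theta if epoch_theta > 0 else np.inf
        wait = rng.exponential(1.0 / rate) if np.isfinite(rate) else 0.0
        if recent_epoch and t + wait > tau:
            # cross into the pre-expansion epoch
            t = tau
            recent_epoch = False
            epoch_theta = theta0
            if epoch_theta == 0.0:
                # instantaneous coalescence of all remaining lineages
                while len(active) > 1:
                    i = active.pop(rng.integers(len(active)))
                    j = active.pop(rng.integers(len(active)))
                    parent[i] = parent[j] = next_node
                    node_time[next_node] = t
                    active.append(next_node)
                    next_node += 1
                break
            continue
        t += wait
        i = active.pop(rng.integers(len(active)))
        j = active.pop(rng.integers(len(active)))
        parent[i] = parent[j] = next_node
        node_time[next_node] = t
        active.append(next_node)
        next_node += 1

    root = active[0]
    n_nodes = next_node

    # mutations per branch ~ Poisson(branch_length / 2)
    branch_len = np.zeros(n_nodes)
    for v in range(n_nodes):
        if v != root and parent[v] >= 0:
            branch_len[v] = node_time[parent[v]] - node_time[v]
    n_mut = rng.poisson(branch_len / 2.0)
    total = int(n_mut.sum())
    if total > L:
        raise ValueError(
            f"{total} mutations cannot be placed on {L} sites under infinite sites; "
            "increase L"
        )
    positions = rng.choice(L, size=total, replace=False)

    if ancestral is None:
        anc = _BASES[rng.integers(4, size=L)]
    else:
        if len(ancestral) != L:
            raise ValueError("ancestral sequence length must equal L")
        anc = np.array(list(ancestral))

    # derived state differs from the ancestral state at that position
    derived = np.empty(total, dtype="<U1")
    for m in range(total):
        choices = [b for b in "ACGT" if b != anc[positions[m]]]
        derived[m] = choices[rng.integers(3)]

    # assign mutations to branches, then propagate root-to-leaf
    mut_of_node: list[list[int]] = [[] for _ in range(n_nodes)]
    idx = 0
    for v in range(n_nodes):
        for _ in range(n_mut[v]):
            mut_of_node[v].append(idx)
            idx += 1

    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for v in range(n_nodes):
        if v != root and parent[v] >= 0:
            children[parent[v]].append(v)

    seqs = [None] * n
    stack: list[tuple[int, list[int]]] = [(root, [])]
    while stack:
        v, muts = stack.pop()
        muts = muts + mut_of_node[v]
        if v < n:
            s = anc.copy()
            for m in muts:
                s[positions[m]] = derived[m]
            seqs[v] = "".join(s)
        else:
            for c in children[v]:
                stack.append((c, muts))

    ids = [f"{id_prefix}_{i}" for i in range(n)]
    return SequenceAlignment(sample_ids=ids, sequences=seqs)


# ---------------------------------------------------------------------------
# flock simulation


def _balding_nichols(rng, p_anc: np.ndarray, fst: float, size=None) -> np.ndarray:
    """Species frequencies around ``p_anc`` with Wright's FST = ``fst``."""
    if fst <= 0.0:
        return np.broadcast_to(p_anc, size if size is not None else p_anc.shape).copy()
    c = (1.0 - fst) / fst
    return rng.beta(p_anc * c, (1.0 - p_anc) * c, size=size)


def simulate_flock(config: FlockConfig):
    """Simulate a flock: marker matrix, mtDNA alignment and ground truth.

    Returns ``(BinaryMarkerMatrix, SequenceAlignment, FlockTruth)``.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    K = config.n_species
    names = list(config.species_names)
    L = config.n_loci

    n_out = int(round(config.frac_outlier * L))
    outlier_loci = np.sort(rng.choice(L, size=n_out, replace=False))
    is_out = np.zeros(L, dtype=bool)
    is_out[outlier_loci] = True

    p_anc = rng.uniform(0.1, 0.9, size=L)
    freqs = np.empty((K, L))
    neutral_cols = ~is_out
    freqs[:, neutral_cols] = _balding_nichols(
        rng, p_anc[neutral_cols], config.fst_neutral, size=(K, int(neutral_cols.sum()))
    )
    if n_out:
        freqs[:, is_out] = _balding_nichols(
            rng, p_anc[is_out], config.fst_outlier, size=(K, n_out)
        )

    sample_ids: list[str] = []
    species: list[str] = []
    rows: list[np.ndarray] = []
    ancestry_rows: list[np.ndarray] = []
    for k, (name, n_k) in enumerate(zip(names, config.n_per_species)):
        draws = rng.random((n_k, L)) < freqs[k]
        for i in range(n_k):
            sample_ids.append(f"{name}_{i:02d}")
            species.append(name)
            rows.append(draws[i].astype(np.uint8))
            a = np.zeros(K)
            a[k] = 1.0
            ancestry_rows.append(a)

    # admixed individuals: band probability is the ancestry-weighted mixture
    # of parental frequencies, loci independent (unlinked dominant markers)
    for label, (pa, pb), gen in config.hybrid_spec:
        ka, kb = names.index(pa), names.index(pb)
        w = 0.5 if gen == "F1" else 0.75  # grandparent: 1/4 from pb
        prob = w * freqs[ka] + (1.0 - w) * freqs[kb]
        rows.append((rng.random(L) < prob).astype(np.uint8))
        sample_ids.append(label)
        species.append(pa)
        a = np.zeros(K)
        a[ka], a[kb] = w, 1.0 - w
        ancestry_rows.append(a)

    data = np.vstack(rows)
    species_arr = np.array(species)
    ancestry = np.vstack(ancestry_rows)

    introgressed_idx = np.array([], dtype=int)
    private_loci = np.array([], dtype=int)
    if config.introgressed_spec is not None:
        sp, n_ind, n_priv = config.introgressed_spec
        members = np.flatnonzero(species_arr == sp)[:n_ind]
        introgressed_idx = members
        if n_priv > 0:
            candidates = np.flatnonzero(neutral_cols)
            private_loci = np.sort(rng.choice(candidates, size=n_priv, replace=False))
            data[:, private_loci] = 0
            data[np.ix_(members, private_loci)] = 1
            # guard: no other locus may accidentally be fixed private to the
            # introgressed subgroup, so the construction invariant is exact
            others = np.setdiff1d(np.arange(data.shape[0]), members)
            for j in range(L):
                if j in private_loci:
                    continue
                if data[members, j].all() and not data[others, j].any():
                    flip = members[rng.integers(n_ind)]
                    data[flip, j] = 0

    # mtDNA: one ancestral haplotype shared by the whole flock; each species
    # accumulates its own expansion-era mutations (central-haplotype pattern)
    anc_seq = "".join(_BASES[rng.integers(4, size=config.seq_len)])
    seq_ids: list[str] = []
    seqs: list[str] = []
    expansion_used: dict[str, tuple] = {}
    for k, (name, n_k) in enumerate(zip(names, config.n_per_species)):
        tau, th0, th1 = config.expansion_params[k]
        expansion_used[name] = (tau, th0, th1)
        aln_k = simulate_expansion_sequences(
            th0, th1, tau, n_k, config.seq_len, rng=rng,
            ancestral=anc_seq, id_prefix=name,
        )
        seq_ids.extend(f"{name}_{i:02d}" for i in range(n_k))
        seqs.extend(aln_k.sequences)
    # hybrids inherit a maternal (parent_a) haplotype: re-use the first
    # parent-species sequence
    for label, (pa, _pb), _gen in config.hybrid_spec:
        donor = seq_ids.index(f"{pa}_00")
        seq_ids.append(label)
        seqs.append(seqs[donor])

    # sampling locations: individuals of every species occur at each of a
    # few shore sites, with no location-specific genetic structure
    locations = [f"site{rng.integers(config.n_locations) + 1}" for _ in sample_ids]
    matrix = BinaryMarkerMatrix(
        data=data,
        sample_ids=sample_ids,
        locus_ids=[f"L{j:04d}" for j in range(L)],
        species=list(species),
        location=locations,
    )
    alignment = SequenceAlignment(sample_ids=seq_ids, sequences=seqs)
    truth = FlockTruth(
        species=list(species),
        ancestry=ancestry,
        outlier_loci=outlier_loci,
        introgressed_individuals=introgressed_idx,
        private_loci=private_loci,
        expansion_params=expansion_used,
    )
    return matrix, alignment, truth


def realized_fst(freqs: np.ndarray) -> float:
    """Wright's FST implied by a species x loci frequency table.

    Ratio-of-means estimator: mean across loci of the between-species
    variance over mean total p(1-p), with the small-sample correction for
    the number of species.
    """
    K = freqs.shape[0]
    pbar = freqs.mean(axis=0)
    var = freqs.var(axis=0, ddof=1)
    num = var.mean()
    # E[pbar(1-pbar)] = p(1-p)(1 - F/K); adding var/K removes the bias
    den = (pbar * (1 - pbar) + var / K).mean()
    return float(num / den) if den > 0 else 0.0
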