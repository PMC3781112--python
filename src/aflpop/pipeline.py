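"""End-to-end orchestration of the flock analysis.

Stages run in dependency order: simulate (or load) → distances/trees/
diagnostics → haplotypes/network → mismatch demography → F-statistics/
AMOVA → outlier scan and matrix partition → neutral-matrix statistics and
report → admixture/Evanno/ancestry/PCA.  Every stochastic stage draws its
seed deterministically from the master seed, and every output file is
listed in a manifest together with the parameters and input checksums
needed to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import admixture as adm
from . import demography as dem
from . import haplonet, popstats, report, selection, trees
from .io import (
    BinaryMarkerMatrix,
    SequenceAlignment,
    read_fasta,
    read_marker_matrix,
    write_fasta,
    write_marker_matrix,
    write_newick,
    write_nexus_distances,
)
from .simulate import FlockConfig, simulate_flock

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("aflpop")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are desk-scale."""

    outdir: str = "aflpop_run"
    seed: int = 0
    # input: either simulation or paths
    simulate: bool = True
    flock: dict = field(default_factory=dict)  # FlockConfig overrides
    matrix_path: str | None = None
    metadata_path: str | None = None
    fasta_path: str | None = None
    # stage switches and sizes
    distance_method: str = "link"
    bootstrap_reps: int = 200
    run_outlier_scan: bool = True
    outlier_alpha: float = 0.99
    fdist_sims: int = 20000
    bayes_mcmc: tuple = (500, 2000, 2)
    n_permutations: int = 1000
    run_admixture: bool = True
    k_range: tuple = (1, 8)
    admix_burnin: int = 300
    admix_iterations: int = 1200
    admix_reps: int = 3
    nu_list: tuple = (0.1, 0.05, 0.01)
    mismatch_boot: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, cfg: RunConfig):
        self.outdir = outdir
        self.data = {"config": cfg.__dict__ | {"bayes_mcmc": list(cfg.bayes_mcmc)},
                     "stages": {}}

    def record(self, stage: str, params: dict, outputs: list[Path], seconds: float):
        self.data["stages"][stage] = {
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()},
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
            "seconds": round(seconds, 2),
        }

    def write(self):
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.data, indent=2, default=str) + "\n"
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    manifest = _Manifest(out, cfg)
    summary: dict = {}

    # ---- input
    t0 = time.time()
    if cfg.simulate:
        fc = FlockConfig(**({"seed": _stage_seed(cfg.seed, "simulate")} | cfg.flock))
        matrix, aln, truth = simulate_flock(fc)
        write_marker_matrix(matrix, out / "markers.tsv", out / "samples.tsv")
        write_fasta(aln, out / "mtdna.fasta")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "outlier_loci": [matrix.locus_ids[j] for j in truth.outlier_loci],
                    "private_loci": [matrix.locus_ids[j] for j in truth.private_loci],
                    "introgressed_individuals": [
                        matrix.sample_ids[i] for i in truth.introgressed_individuals
                    ],
                    "expansion_params": truth.expansion_params,
                },
                indent=2,
            )
        )
        manifest.record(
            "simulate", {"seed": fc.seed, "n_loci": fc.n_loci},
            [out / "markers.tsv", out / "samples.tsv", out / "mtdna.fasta", out / "truth.json"],
            time.time() - t0,
        )
    else:
        if not (cfg.matrix_path and cfg.metadata_path):
            raise ValueError("matrix_path and metadata_path required when simulate=false")
        matrix = read_marker_matrix(cfg.matrix_path, cfg.metadata_path)
        aln = read_fasta(cfg.fasta_path) if cfg.fasta_path else None
        truth = None
    log.info("input: %d individuals x %d loci", matrix.n_samples, matrix.n_loci)

    # ---- distances, tree, bootstrap diagnostics
    t0 = time.time()
    seed = _stage_seed(cfg.seed, "tree")
    dm = trees.binary_distance(matrix, cfg.distance_method)
    write_nexus_distances(dm.ids, dm.data, out / "distances.nex")
    boot = trees.bootstrap_support(matrix, cfg.bootstrap_reps, cfg.distance_method, seed)
    write_newick(boot.tree, out / "nj_tree.nwk")
    ls = trees.leaf_stability(boot.bootstrap)
    _write_tsv(out / "leaf_stability.tsv", ["taxon", "LS"], sorted(ls.items()))
    manifest.record(
        "tree",
        {"method": cfg.distance_method, "bootstrap_reps": cfg.bootstrap_reps, "seed": seed},
        [out / "distances.nex", out / "nj_tree.nwk", out / "leaf_stability.tsv"],
        time.time() - t0,
    )
    summary["mean_leaf_stability"] = float(np.mean(list(ls.values())))

    # ---- haplotypes, network, mismatch demography
    if aln is not None:
        t0 = time.time()
        hs = haplonet.collapse_haplotypes(
            aln, species=dict(zip(matrix.sample_ids, matrix.species))
        )
        hs.per_species_table().to_csv(out / "haplotypes.tsv", sep="\t")
        g = haplonet.median_joining_network(hs)
        haplonet.network_edge_table(g).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        summary["n_haplotypes"] = hs.n_haplotypes
        summary["modal_haplotype_pct"] = hs.modal_frequency_pct()

        fits = {}
        for sp in dict.fromkeys(matrix.species):
            ids = [s for s, spp in zip(matrix.sample_ids, matrix.species) if spp == sp]
            sub = aln.subset([s for s in ids if s in aln.sample_ids])
            if sub.n_sequences < 4:
                continue
            counts, _mean = dem.mismatch_observed(sub)
            fits[sp] = dem.fit_sudden_expansion(
                counts, n_boot=cfg.mismatch_boot, seed=_stage_seed(cfg.seed, f"mm:{sp}")
            )
        rows = [
            (sp, f.n_sequences, round(f.mean_pairwise_diff, 3), round(f.tau, 3),
             round(f.theta0, 5), round(f.theta1, 3), round(f.ssd, 5),
             f.p_ssd, round(f.raggedness, 5))
            for sp, f in fits.items()
        ]
        _write_tsv(
            out / "mismatch.tsv",
            ["species", "n", "mean_diff", "tau", "theta0", "theta1", "SSD", "p_SSD", "raggedness"],
            rows,
        )
        manifest.record(
            "haplotypes+mismatch", {"mismatch_boot": cfg.mismatch_boot},
            [out / "haplotypes.tsv", out / "network_edges.tsv", out / "mismatch.tsv"],
            time.time() - t0,
        )

    # ---- F-statistics and AMOVA on the complete matrix
    t0 = time.time()
    seed = _stage_seed(cfg.seed, "fstats")
    d_pd = trees.DistanceMatrix(
        dm.ids, _pairwise_diff_matrix(matrix), "pairwise_difference"
    )
    fst_full = popstats.pairwise_fst(
        d_pd, matrix.species, n_perm=cfg.n_permutations, seed=seed, squared=True
    )
    d_j = trees.binary_distance(matrix, "jaccard")
    phi_full = popstats.pairwise_fst(
        d_j, matrix.species, n_perm=cfg.n_permutations, seed=seed + 1
    )
    fst_full.statistic.to_csv(out / "fst_full.tsv", sep="\t")
    phi_full.statistic.to_csv(out / "phist_full.tsv", sep="\t")
    am = popstats.amova(
        d_pd, matrix.species, n_perm=cfg.n_permutations, seed=seed + 2, squared=True
    )
    am.to_frame().to_csv(out / "amova_species.tsv", sep="\t", index=False)
    summary["amova_pct_among_species"] = am.pct_among
    if matrix.location is not None and len(set(matrix.location)) > 1:
        am_loc = popstats.amova(
            d_pd, matrix.location, n_perm=cfg.n_permutations, seed=seed + 4, squared=True
        )
        am_loc.to_frame().to_csv(out / "amova_locations.tsv", sep="\t", index=False)
        summary["amova_pct_among_locations"] = am_loc.pct_among
    priv = popstats.private_alleles(matrix)
    priv.to_csv(out / "private_alleles.tsv", sep="\t", index=False)
    manifest.record(
        "fstats", {"n_perm": cfg.n_permutations, "seed": seed},
        [out / "fst_full.tsv", out / "phist_full.tsv", out / "amova_species.tsv",
         out / "private_alleles.tsv"],
        time.time() - t0,
    )

    # ---- outlier scan, partition, neutral statistics, report
    if cfg.run_outlier_scan:
        t0 = time.time()
        seed = _stage_seed(cfg.seed, "outliers")
        bres = selection.bayes_scan(matrix, mcmc=tuple(cfg.bayes_mcmc), seed=seed)
        bres.table.to_csv(out / "bayes_scan.tsv", sep="\t", index=False)
        fres = selection.fdist_scan(
            matrix, alpha=cfg.outlier_alpha, n_sims=cfg.fdist_sims, seed=seed + 1
        )
        fres.table.to_csv(out / "fdist_scan.tsv", sep="\t", index=False)
        outliers = bres.flagged
        summary["n_outlier_loci"] = len(outliers)
        neutral, out_m = selection.partition_matrix(matrix, outliers)
        if neutral.n_loci and out_m.n_loci:
            write_marker_matrix(neutral, out / "markers_neutral.tsv", out / "samples_neutral.tsv")
            d_pd_n = trees.DistanceMatrix(
                dm.ids, _pairwise_diff_matrix(neutral), "pairwise_difference"
            )
            fst_neu = popstats.pairwise_fst(
                d_pd_n, matrix.species, n_perm=cfg.n_permutations, seed=seed + 2, squared=True
            )
            phi_neu = popstats.pairwise_fst(
                trees.binary_distance(neutral, "jaccard"), matrix.species,
                n_perm=cfg.n_permutations, seed=seed + 3,
            )
            table = report.pairwise_table((fst_full, phi_full), (fst_neu, phi_neu))
            table.to_csv(out / "pairwise_fst_table.tsv", sep="\t", index=False)
            summ = report.fst_report_summary(table)
            (out / "fst_summary.json").write_text(json.dumps(summ, indent=2))
            summary |= {f"report_{k}": v for k, v in summ.items()}
        manifest.record(
            "outliers", {"mcmc": cfg.bayes_mcmc, "alpha": cfg.outlier_alpha, "seed": seed},
            [out / "bayes_scan.tsv", out / "fdist_scan.tsv"],
            time.time() - t0,
        )
    else:
        log.info("outlier scan disabled: neutral-matrix stages skipped")
        summary["neutral_stages"] = "skipped (outlier scan disabled)"

    # ---- admixture, Evanno, ancestry, PCA
    if cfg.run_admixture:
        t0 = time.time()
        seed = _stage_seed(cfg.seed, "admixture")
        k_lo, k_hi = cfg.k_range
        runs_by_K = {
            K: adm.fit_admixture(
                matrix, K, cfg.admix_burnin, cfg.admix_iterations,
                n_reps=cfg.admix_reps, seed=seed + K,
            )
            for K in range(k_lo, k_hi + 1)
        }
        ev = adm.evanno_deltaK(runs_by_K)
        ev.table.to_csv(out / "evanno.tsv", sep="\t", index=False)
        best = ev.best_K
        summary["evanno_best_K"] = best
        best_run = max(runs_by_K[best], key=lambda r: r.lnPD)
        qdf = _q_frame(best_run, matrix)
        qdf.to_csv(out / "q_matrix.tsv", sep="\t", index=False)
        _mapping, acc = adm.match_clusters(best_run.Q, matrix.species)
        summary["assignment_accuracy"] = acc

        anc_frames = []
        for nu in cfg.nu_list:
            at = adm.ancestry_test(matrix, gb=2, nu=nu)
            at["nu"] = nu
            anc_frames.append(at)
        import pandas as pd

        pd.concat(anc_frames).to_csv(out / "ancestry_test.tsv", sep="\t", index=False)

        scores, pct = adm.pca_binary(matrix)
        _write_tsv(
            out / "pca_scores.tsv",
            ["sample", "species", "PC1", "PC2"],
            [
                (s, sp, round(scores[i, 0], 4), round(scores[i, 1], 4))
                for i, (s, sp) in enumerate(zip(matrix.sample_ids, matrix.species))
            ],
        )
        summary["pca_pct_pc1"] = float(pct[0])
        manifest.record(
            "admixture",
            {"k_range": cfg.k_range, "burnin": cfg.admix_burnin,
             "iterations": cfg.admix_iterations, "reps": cfg.admix_reps, "seed": seed},
            [out / "evanno.tsv", out / "q_matrix.tsv", out / "ancestry_test.tsv",
             out / "pca_scores.tsv"],
            time.time() - t0,
        )

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str) + "\n")
    manifest.write()
    return summary


def _pairwise_diff_matrix(m: BinaryMarkerMatrix) -> np.ndarray:
    X = m.data.astype(float)
    a = X @ X.T
    s = X.sum(axis=1)
    return s[:, None] + s[None, :] - 2 * a  # band differences (squared Euclidean)


def _q_frame(run: adm.AdmixtureResult, m: BinaryMarkerMatrix):
    import pandas as pd

    df = pd.DataFrame(run.Q, columns=[f"Q{k + 1}" for k in range(run.K)])
    df.insert(0, "species", m.species)
    df.insert(0, "sample", m.sample_ids)
    return df


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
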