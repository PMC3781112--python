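"""Report arithmetic on pairwise-differentiation tables.

A differentiation report for a flock is a tidy table with one row per
species pair and four statistics: FST (pairwise-difference based) and
PhiST (Jaccard-distance based), each on the complete marker matrix and on
the neutral matrix with outlier loci removed.  The summary statistics
derived from such a table quantify (i) how much the distance-weighted
PhiST exceeds FST, (ii) how much differentiation drops when divergently
selected loci are excluded, and (iii) how concordant the two measures are.

``printed_fst_table`` returns the published six-species pairwise table for
a Lake Apoyo Midas-cichlid flock (2297 dominant loci, 49 outlier loci
removed for the neutral estimates), which serves as a fixed input for
regression-testing the summary arithmetic.
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

__all__ = ["printed_fst_table", "fst_report_summary", "pairwise_table"]

# Published pairwise estimates for the six-species flock: FST from pairwise
# differences and PhiST from Jaccard distances (d = 1 - s), on the complete
# matrix and on the neutral matrix.  Dot decimals.
_PRINTED = """\
species_a\tspecies_b\tfst_full\tphist_full\tfst_neutral\tphist_neutral
zaliosus\tglobosus\t0.223\t0.353\t0.141\t0.219
zaliosus\tastorquii\t0.134\t0.233\t0.098\t0.171
zaliosus\tchancho\t0.173\t0.293\t0.099\t0.170
zaliosus\tflaveolus\t0.154\t0.266\t0.092\t0.163
zaliosus\tsupercilius\t0.188\t0.317\t0.119\t0.207
globosus\tastorquii\t0.142\t0.238\t0.105\t0.177
globosus\tchancho\t0.148\t0.252\t0.099\t0.166
globosus\tflaveolus\t0.128\t0.212\t0.098\t0.160
globosus\tsupercilius\t0.159\t0.263\t0.112\t0.184
astorquii\tchancho\t0.101\t0.182\t0.078\t0.141
astorquii\tflaveolus\t0.062\t0.114\t0.049\t0.092
astorquii\tsupercilius\t0.084\t0.153\t0.064\t0.118
chancho\tflaveolus\t0.105\t0.188\t0.071\t0.129
chancho\tsupercilius\t0.132\t0.230\t0.085\t0.152
flaveolus\tsupercilius\t0.052\t0.096\t0.036\t0.067
"""


def printed_fst_table() -> pd.DataFrame:
    """The published pairwise FST/PhiST table as a tidy DataFrame."""
    return pd.read_csv(_io.StringIO(_PRINTED), sep="\t")


def read_pair_table(path) -> pd.DataFrame:
    """Read a tidy pairwise table from TSV.

    Comma decimals (as printed in some journals' tables) are accepted on
    input; outputs of this package always use dot decimals.
    """
    t = pd.read_csv(path, sep="\t", dtype=str)
    for c in t.columns:
        if c.startswith(("fst", "phist")):
            t[c] = t[c].str.replace(",", ".", regex=False).astype(float)
    return t


def pairwise_table(full, neutral) -> pd.DataFrame:
    """Assemble a tidy pair table from two :class:`PopDiffResult`-like
    pairs ``(fst_result, phist_result)`` for the full and neutral matrices."""
    (fst_f, phi_f), (fst_n, phi_n) = full, neutral
    species = list(fst_f.statistic.index)
    rows = []
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            rows.append(
                (
                    a,
                    b,
                    fst_f.statistic.loc[a, b],
                    phi_f.statistic.loc[a, b],
                    fst_n.statistic.loc[a, b],
                    phi_n.statistic.loc[a, b],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species_a",
            "species_b",
            "fst_full",
            "phist_full",
            "fst_neutral",
            "phist_neutral",
        ],
    )


def fst_report_summary(table: pd.DataFrame) -> dict[str, float]:
    """Summary statistics over a pairwise differentiation table.

    Returns percentages:

    ``phist_excess_mean_pct`` / ``_sd_pct``
        mean and SD over pairs of the relative excess of PhiST over FST on
        the complete matrix, 100 * (PhiST - FST) / PhiST;
    ``fst_decrease_mean_pct`` / ``_sd_pct`` / ``_max_pct``
        relative decrease of FST after outlier removal,
        100 * (FST_full - FST_neutral) / FST_full;
    ``phist_decrease_mean_pct`` / ``_sd_pct``
        the same for PhiST;
    ``pearson_r_full``
        Pearson correlation between the FST and PhiST values on the
        complete matrix.

    SDs use the n-1 denominator.
    """
    t = table
    excess = 100.0 * (t.phist_full - t.fst_full) / t.phist_full
    f_dec = 100.0 * (t.fst_full - t.fst_neutral) / t.fst_full
    p_dec = 100.0 * (t.phist_full - t.phist_neutral) / t.phist_full
    r = float(np.corrcoef(t.fst_full, t.phist_full)[0, 1])
    r_neutral = float(np.corrcoef(t.fst_neutral, t.phist_neutral)[0, 1])
    return {
        "phist_excess_mean_pct": float(excess.mean()),
        "phist_excess_sd_pct": float(excess.std(ddof=1)),
        "fst_decrease_mean_pct": float(f_dec.mean()),
        "fst_decrease_sd_pct": float(f_dec.std(ddof=1)),
        "fst_decrease_max_pct": float(f_dec.max()),
        "phist_decrease_mean_pct": float(p_dec.mean()),
        "phist_decrease_sd_pct": float(p_dec.std(ddof=1)),
        "pearson_r_full": r,
        "pearson_r_neutral": r_neutral,
    }
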