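"""Input/output for the formats the pipeline touches.

Containers
----------
:class:`BinaryMarkerMatrix`
    Individuals x loci presence/absence matrix (dominant markers such as
    AFLP bands) with per-individual species and optional location labels.
:class:`SequenceAlignment`
    Equal-length nucleotide sequences with an excluded-site mask, as used
    for mtDNA control-region data where unalignable repeat regions are
    masked out before any comparison.

All writers emit dot decimals regardless of locale; comma decimals are
accepted on numeric input tables but never produced.  Site indices are
0-based half-open internally and 1-based in human-readable reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "BinaryMarkerMatrix",
    "SequenceAlignment",
    "read_fasta",
    "write_fasta",
    "read_marker_matrix",
    "write_marker_matrix",
    "write_newick",
    "write_nexus_distances",
]

VALID_BASES = frozenset("ACGT-N")


@dataclass
class SequenceAlignment:
    """Aligned sequences over {A,C,G,T,-,N} plus an excluded-site mask.

    ``mask[j] is True`` means column ``j`` is excluded from every
    downstream comparison (haplotype collapse, mismatch counting).
    """

    sample_ids: list[str]
    sequences: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unaligned input: sequence lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        for sid, s in zip(self.sample_ids, self.sequences):
            bad = set(s) - VALID_BASES
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in record {sid!r}")
        if self.mask is None:
            self.mask = np.zeros(self.length, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.length,):
            raise ValueError("mask length must equal alignment length")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_codes(self) -> np.ndarray:
        """Integer-coded matrix (n x L) over the unmasked columns only.

        Codes: A=0, C=1, G=2, T=3, -=4 (gap as fifth state), N=5.
        """
        table = np.full(256, 5, dtype=np.int8)
        for i, b in enumerate("ACGT-N"):
            table[ord(b)] = i
        arr = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        codes = table[arr].reshape(self.n_sequences, self.length)
        return codes[:, ~self.mask]

    def subset(self, ids: Iterable[str]) -> "SequenceAlignment":
        wanted = list(ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"sample ids not in alignment: {missing}")
        return SequenceAlignment(
            sample_ids=wanted,
            sequences=[self.sequences[index[s]] for s in wanted],
            mask=self.mask.copy(),
        )


@dataclass
class BinaryMarkerMatrix:
    """Presence/absence marker matrix with sample metadata.

    ``data`` holds one row per individual and one column per locus, entries
    strictly in {0, 1} (band present / absent).  Monomorphic loci are
    permitted but reported by :meth:`monomorphic_loci`.
    """

    data: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    species: list[str]
    location: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x loci)")
        if not np.isin(self.data, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.data, (0, 1)))[0]
            raise ValueError(
                f"marker value outside {{0,1}} at sample "
                f"{self.sample_ids[bad[0]]!r}, locus {self.locus_ids[bad[1]]!r}"
            )
        self.data = self.data.astype(np.uint8)
        n, m = self.data.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(self.locus_ids) != m:
            raise ValueError("locus_ids length mismatch")
        if len(self.species) != n:
            raise ValueError("species labels must cover every sample")
        if self.location is not None and len(self.location) != n:
            raise ValueError("location labels must cover every sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]

    def monomorphic_loci(self) -> list[str]:
        """Locus ids whose column is constant across all samples."""
        col_min = self.data.min(axis=0)
        col_max = self.data.max(axis=0)
        mono = np.flatnonzero(col_min == col_max)
        return [self.locus_ids[j] for j in mono]

    def species_groups(self) -> dict[str, np.ndarray]:
        """Row indices per species label, in order of first appearance."""
        groups: dict[str, list[int]] = {}
        for i, sp in enumerate(self.species):
            groups.setdefault(sp, []).append(i)
        return {sp: np.asarray(ix) for sp, ix in groups.items()}

    def subset_samples(self, keep: Sequence[int] | np.ndarray) -> "BinaryMarkerMatrix":
        keep = np.asarray(keep, dtype=int)
        return BinaryMarkerMatrix(
            data=self.data[keep],
            sample_ids=[self.sample_ids[i] for i in keep],
            locus_ids=list(self.locus_ids),
            species=[self.species[i] for i in keep],
            location=None if self.location is None else [self.location[i] for i in keep],
        )

    def subset_loci(self, keep: Sequence[int] | np.ndarray) -> "BinaryMarkerMatrix":
        keep = np.asarray(keep, dtype=int)
        return BinaryMarkerMatrix(
            data=self.data[:, keep],
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[j] for j in keep],
            species=list(self.species),
            location=list(self.location) if self.location is not None else None,
        )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file into a :class:`SequenceAlignment`.

    Order-preserving; sequences are uppercased; the mask starts all-false.
    Raises on empty files, duplicate ids and unequal record lengths.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA file: {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    return SequenceAlignment(sample_ids=ids, sequences=seqs)


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# marker matrix


def _coerce_binary(value: str, row: str, col: str):
    v = value.strip()
    if v in ("0", "1"):
        return int(v)
    raise ValueError(f"value {value!r} outside {{0,1}} at sample {row!r}, locus {col!r}")


def read_marker_matrix(path: str | Path, metadata_path: str | Path) -> BinaryMarkerMatrix:
    """Read a tab-separated presence/absence matrix plus a metadata table.

    The matrix has a header row of locus ids and a first column of sample
    ids.  The metadata table (tab-separated, header ``sample\\tspecies`` and
    optionally ``location``) must cover every sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns or "species" not in meta.columns:
        raise ValueError("metadata must have 'sample' and 'species' columns")
    meta = meta.set_index("sample")

    sample_ids = [str(s) for s in df.index]
    locus_ids = [str(c) for c in df.columns]
    data = np.empty(df.shape, dtype=np.uint8)
    for i, sid in enumerate(sample_ids):
        for j, lid in enumerate(locus_ids):
            data[i, j] = _coerce_binary(str(df.iat[i, j]), sid, lid)

    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    species = [str(meta.at[s, "species"]) for s in sample_ids]
    location = None
    if "location" in meta.columns:
        location = [str(meta.at[s, "location"]) for s in sample_ids]

    m = BinaryMarkerMatrix(data, sample_ids, locus_ids, species, location)
    mono = m.monomorphic_loci()
    if mono:
        warnings.warn(
            f"{len(mono)} monomorphic loci in matrix (e.g. {mono[:5]})",
            stacklevel=2,
        )
    return m


def write_marker_matrix(
    m: BinaryMarkerMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    df = pd.DataFrame(m.data, index=m.sample_ids, columns=m.locus_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    meta = pd.DataFrame({"sample": m.sample_ids, "species": m.species})
    if m.location is not None:
        meta["location"] = m.location
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# newick


def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialise a tree to newick with 6-decimal branch lengths.

    ``tree`` is the node structure produced by :mod:`aflpop.trees` (any
    object with ``children``, ``name``, ``length`` and optional ``support``
    attributes).  Internal-node support values are rendered as node labels,
    as is conventional for bootstrap-annotated trees.
    """

    def render(node) -> str:
        if not node.children:
            if not node.name:
                raise ValueError("unlabeled leaf in tree")
            label = str(node.name)
        else:
            inner = ",".join(render(c) for c in node.children)
            support = getattr(node, "support", None)
            label = f"({inner})" + ("" if support is None else _fmt_num(support))
        length = getattr(node, "length", None)
        if length is not None:
            label += f":{length:.6f}"
        return label

    text = render(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _fmt_num(x) -> str:
    if float(x) == int(float(x)):
        return str(int(float(x)))
    return f"{float(x):g}"


# ---------------------------------------------------------------------------
# NEXUS distance export (for external split-network viewers)


def write_nexus_distances(ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> str:
    """Export a distance matrix as a NEXUS DISTANCES block.

    Intended for loading into external split-network software; the pipeline
    itself does not compute split networks.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match ids")
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"  DIMENSIONS NTAX={n};",
        "  TAXLABELS " + " ".join(f"'{i}'" for i in ids) + ";",
        "END;",
        "BEGIN DISTANCES;",
        "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;",
        "  MATRIX",
    ]
    for i, sid in enumerate(ids):
        row = " ".join(f"{matrix[i, j]:.6f}" for j in range(n))
        lines.append(f"    '{sid}' {row}")
    lines += ["  ;", "END;", ""]
    text = "\n".join(lines)
    Path(path).write_text(text)
    return text
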