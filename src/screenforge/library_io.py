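"""Data model and I/O for sgRNA libraries, screen count tables and CROP-seq bundles.

The central objects are :class:`LibraryManifest` (the sgRNA -> gene map over
which every downstream statistic is computed), :class:`CountsTable`
(sgRNA x sample integer counts for one screen comparison) and
:class:`CellTensorBundle` (cell x gene expression, cell x sgRNA UMIs and cell
metadata for a CROP-seq experiment).  Readers validate invariants on load;
writers round-trip exactly.

Reads are counted against the library by exact protospacer matching on a
fixed trim window (optionally Hamming distance <= 1), which is deterministic
and adequate for error-free synthetic reads.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO
from scipy.io import mmread, mmwrite

#: Reserved target-gene label shared by all non-targeting control sgRNAs.
NTC_LABEL = "NTC"

_BASES = "ACGT"


class ManifestError(ValueError):
    """Raised when a library manifest violates its invariants."""


@dataclass(frozen=True)
class SgrnaEntry:
    sgrna_id: str
    protospacer: str
    target_gene: str
    is_ntc: bool


@dataclass
class LibraryManifest:
    """An sgRNA library: id -> (protospacer, target gene, NTC flag).

    Invariants enforced on construction: unique sgRNA ids, protospacers over
    {A,C,G,T}, non-NTC entries carry a nonempty gene label, NTC entries all
    share the reserved label ``"NTC"``.
    """

    entries: list[SgrnaEntry]
    name: str = "library"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.sgrna_id in seen:
                raise ManifestError(f"duplicate sgrna_id {e.sgrna_id!r}")
            seen.add(e.sgrna_id)
            if not e.protospacer or any(b not in _BASES for b in e.protospacer):
                raise ManifestError(
                    f"protospacer of {e.sgrna_id!r} is not a DNA string over ACGT"
                )
            if e.is_ntc:
                if e.target_gene != NTC_LABEL:
                    raise ManifestError(
                        f"NTC entry {e.sgrna_id!r} must use target_gene {NTC_LABEL!r}"
                    )
            elif not e.target_gene:
                raise ManifestError(f"entry {e.sgrna_id!r} has empty target_gene")

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryManifest):
            return NotImplemented
        return self.name == other.name and self.entries == other.entries

    @property
    def sgrna_ids(self) -> list[str]:
        return [e.sgrna_id for e in self.entries]

    @property
    def ntc_ids(self) -> list[str]:
        return [e.sgrna_id for e in self.entries if e.is_ntc]

    @property
    def target_genes(self) -> list[str]:
        """Targeting genes in first-appearance order (excludes NTC)."""
        out: list[str] = []
        seen: set[str] = set()
        for e in self.entries:
            if not e.is_ntc and e.target_gene not in seen:
                seen.add(e.target_gene)
                out.append(e.target_gene)
        return out

    def gene_to_sgrnas(self) -> dict[str, list[str]]:
        """Map each gene label (including NTC) to its sgRNA ids."""
        out: dict[str, list[str]] = {}
        for e in self.entries:
            out.setdefault(e.target_gene, []).append(e.sgrna_id)
        return out

    def sgrna_to_gene(self) -> dict[str, str]:
        return {e.sgrna_id: e.target_gene for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sgrna_id": [e.sgrna_id for e in self.entries],
                "protospacer": [e.protospacer for e in self.entries],
                "target_gene": [e.target_gene for e in self.entries],
                "is_ntc": [e.is_ntc for e in self.entries],
            }
        )


def read_library_manifest(path: Union[str, Path], name: Optional[str] = None) -> LibraryManifest:
    """Read a library manifest from CSV.

    Expects header columns ``sgrna_id, protospacer, target_gene, is_ntc``;
    ``is_ntc`` is the literal ``true``/``false`` (case-insensitive).
    Malformed rows raise :class:`ManifestError` naming the offending line.
    """
    path = Path(path)
    entries: list[SgrnaEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sgrna_id", "protospacer", "target_gene", "is_ntc"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ManifestError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(k) in (None, "") for k in ("sgrna_id", "protospacer", "is_ntc")):
                raise ManifestError(f"{path}: malformed row at line {lineno}")
            flag = row["is_ntc"].strip().lower()
            if flag not in ("true", "false"):
                raise ManifestError(
                    f"{path}: line {lineno}: is_ntc must be 'true' or 'false', got {row['is_ntc']!r}"
                )
            entries.append(
                SgrnaEntry(
                    sgrna_id=row["sgrna_id"].strip(),
                    protospacer=row["protospacer"].strip().upper(),
                    target_gene=row["target_gene"].strip(),
                    is_ntc=flag == "true",
                )
            )
    return LibraryManifest(entries=entries, name=name if name is not None else path.stem)


def write_library_manifest(manifest: LibraryManifest, path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sgrna_id", "protospacer", "target_gene", "is_ntc"])
        for e in manifest.entries:
            writer.writerow(
                [e.sgrna_id, e.protospacer, e.target_gene, "true" if e.is_ntc else "false"]
            )


def synthetic_protospacer(index: int, length: int = 20) -> str:
    """Deterministic unique protospacer for synthetic libraries (base-4 encoding)."""
    if index < 0 or index >= 4**length:
        raise ValueError("index out of range for protospacer length")
    out = []
    x = index
    for _ in range(length):
        out.append(_BASES[x % 4])
        x //= 4
    return "".join(reversed(out))


_DEFAULT_CROPSEQ_GENES = ["DBF4"] + [f"TARGET{i:02d}" for i in range(2, 40)]


def build_cropseq_manifest(
    genes: Optional[Sequence[str]] = None,
    single_sgrna_gene: Optional[str] = "DBF4",
    n_ntc: int = 4,
    name: str = "cropseq_library",
) -> LibraryManifest:
    """Build a CROP-seq style library: two sgRNAs per target gene, one
    designated gene with a single sgRNA, plus non-targeting controls.

    The default composition (39 genes, one single-sgRNA gene, 4 NTCs) yields
    an 81-element library.  Pass ``single_sgrna_gene=None`` for a uniform
    two-per-gene design.
    """
    if genes is None:
        genes = list(_DEFAULT_CROPSEQ_GENES)
    genes = list(genes)
    if len(genes) < 1:
        raise ValueError("need at least one target gene")
    if len(set(genes)) != len(genes):
        raise ValueError("target gene labels must be unique")
    if single_sgrna_gene is not None and single_sgrna_gene not in genes:
        raise ValueError(f"single_sgrna_gene {single_sgrna_gene!r} not in gene list")
    entries: list[SgrnaEntry] = []
    idx = 0
    for gene in genes:
        n_sg = 1 if gene == single_sgrna_gene else 2
        for j in range(1, n_sg + 1):
            entries.append(
                SgrnaEntry(
                    sgrna_id=f"{gene}_sg{j}",
                    protospacer=synthetic_protospacer(idx),
                    target_gene=gene,
                    is_ntc=False,
                )
            )
            idx += 1
    for j in range(1, n_ntc + 1):
        entries.append(
            SgrnaEntry(
                sgrna_id=f"NTC_sg{j}",
                protospacer=synthetic_protospacer(idx),
                target_gene=NTC_LABEL,
                is_ntc=True,
            )
        )
        idx += 1
    return LibraryManifest(entries=entries, name=name)


@dataclass
class CountsTable:
    """sgRNA x sample nonnegative integer counts for one screen."""

    sgrna_ids: list[str]
    samples: list[str]
    counts: np.ndarray  # shape (n_sgrnas, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sgrna_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sgrna_ids)} sgRNAs x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(set(self.sgrna_ids)) != len(self.sgrna_ids):
            raise ValueError("duplicate sgrna_id in counts table")

    def column(self, sample: str) -> np.ndarray:
        try:
            j = self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in counts table {self.samples}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sgrna_ids, name="sgrna_id"),
                            columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountsTable":
        return cls(
            sgrna_ids=[str(i) for i in df.index],
            samples=[str(c) for c in df.columns],
            counts=df.to_numpy(),
        )

    def validate_against(self, manifest: LibraryManifest) -> None:
        known = set(manifest.sgrna_ids)
        missing = [s for s in self.sgrna_ids if s not in known]
        if missing:
            raise ValueError(f"sgRNAs absent from manifest: {missing[:5]}...")


def read_counts_table(path: Union[str, Path]) -> CountsTable:
    """Read a tab-separated counts table (first column sgrna_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountsTable.from_frame(df)


def write_counts_table(table: CountsTable, path: Union[str, Path]) -> None:
    table.to_frame().to_csv(path, sep="\t")


@dataclass
class CellTensorBundle:
    """CROP-seq tensors sharing one cell ordering.

    ``expr`` is a cell x gene UMI count matrix, ``sgrna_umi`` a cell x sgRNA
    UMI matrix, and ``cells`` the per-cell metadata (``cell_id`` plus, when
    available, ``assigned_sgrna``, ``assigned_gene`` and ``cluster_label``).
    """

    expr: sp.csr_matrix
    genes: list[str]
    sgrna_umi: sp.csr_matrix
    sgrna_ids: list[str]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.expr = sp.csr_matrix(self.expr)
        self.sgrna_umi = sp.csr_matrix(self.sgrna_umi)
        n = len(self.cells)
        if self.expr.shape != (n, len(self.genes)):
            raise ValueError("expr shape inconsistent with cells/genes")
        if self.sgrna_umi.shape != (n, len(self.sgrna_ids)):
            raise ValueError("sgrna_umi shape inconsistent with cells/sgrna_ids")
        if "cell_id" not in self.cells.columns:
            raise ValueError("cell metadata must contain a cell_id column")
        if self.expr.nnz and self.expr.min() < 0:
            raise ValueError("expression UMIs must be nonnegative")
        if self.sgrna_umi.nnz and self.sgrna_umi.min() < 0:
            raise ValueError("sgRNA UMIs must be nonnegative")
        if "assigned_sgrna" in self.cells.columns:
            known = set(self.sgrna_ids)
            bad = [
                s for s in self.cells["assigned_sgrna"].dropna()
                if s != "" and s not in known
            ]
            if bad:
                raise ValueError(f"assigned_sgrna values not in sgrna_umi columns: {bad[:5]}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def write_bundle(bundle: CellTensorBundle, prefix: Union[str, Path]) -> None:
    """Write a bundle as MTX matrices plus companion TSVs sharing ``prefix``."""
    prefix = str(prefix)
    mmwrite(prefix + "expr.mtx", sp.coo_matrix(bundle.expr))
    mmwrite(prefix + "sgrna_umi.mtx", sp.coo_matrix(bundle.sgrna_umi))
    pd.Series(bundle.genes, name="gene").to_csv(prefix + "genes.tsv", sep="\t", index=False)
    pd.Series(bundle.sgrna_ids, name="sgrna_id").to_csv(
        prefix + "sgrnas.tsv", sep="\t", index=False
    )
    bundle.cells.to_csv(prefix + "cells.tsv", sep="\t", index=False)


def read_bundle(prefix: Union[str, Path]) -> CellTensorBundle:
    prefix = str(prefix)
    expr = sp.csr_matrix(mmread(prefix + "expr.mtx"))
    sgrna_umi = sp.csr_matrix(mmread(prefix + "sgrna_umi.mtx"))
    genes = pd.read_csv(prefix + "genes.tsv", sep="\t")["gene"].astype(str).tolist()
    sgrna_ids = pd.read_csv(prefix + "sgrnas.tsv", sep="\t")["sgrna_id"].astype(str).tolist()
    cells = pd.read_csv(prefix + "cells.tsv", sep="\t")
    return CellTensorBundle(
        expr=expr, genes=genes, sgrna_umi=sgrna_umi, sgrna_ids=sgrna_ids, cells=cells
    )


def _iter_read_sequences(reads: Union[str, Path, Iterable[str]]) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        for rec in SeqIO.parse(str(reads), "fastq"):
            yield str(rec.seq)
    else:
        yield from reads


def count_protospacers(
    reads: Union[str, Path, Iterable[str]],
    manifest: LibraryManifest,
    trim: Optional[tuple[int, Optional[int]]] = None,
    max_mismatch: int = 0,
) -> tuple[pd.Series, int]:
    """Count reads per sgRNA by exact protospacer matching.

    ``reads`` is a FASTQ path or an iterable of read sequences.  Each read is
    trimmed to ``trim = (offset, length)`` (default offset 0, length = the
    library's protospacer length) and compared against the library.  With
    ``max_mismatch=1``, an unambiguous best hit at Hamming distance 1 is also
    accepted; ties go to unmatched.

    Returns (counts indexed by sgrna_id in manifest order, n_unmatched).
    The column sum plus the unmatched tally equals the number of reads.
    """
    lengths = {len(e.protospacer) for e in manifest.entries}
    if trim is None:
        if len(lengths) != 1:
            raise ValueError("library has mixed protospacer lengths; pass trim explicitly")
        offset, length = 0, lengths.pop()
    else:
        offset, length = trim
        if length is None:
            if len(lengths) != 1:
                raise ValueError("library has mixed protospacer lengths; pass trim length")
            length = lengths.pop()
    if offset < 0 or length <= 0:
        raise ValueError("trim offset must be >= 0 and length > 0")

    exact = {e.protospacer[:length]: e.sgrna_id for e in manifest.entries}
    if len(exact) != len(manifest):
        raise ValueError("protospacers are not unique within the trim window")
    counts = {e.sgrna_id: 0 for e in manifest.entries}
    spacers = list(exact)
    unmatched = 0
    for seq in _iter_read_sequences(reads):
        if len(seq) < offset + length:
            raise ValueError(
                f"trim window {offset}:{offset + length} exceeds read length {len(seq)}"
            )
        window = seq[offset : offset + length].upper()
        hit = exact.get(window)
        if hit is None and max_mismatch >= 1:
            best = [
                s for s in spacers
                if sum(a != b for a, b in zip(window, s)) <= max_mismatch
            ]
            if len(best) == 1:
                hit = exact[best[0]]
        if hit is None:
            unmatched += 1
        else:
            counts[hit] += 1
    series = pd.Series(counts, name="count").reindex(manifest.sgrna_ids)
    return series, unmatched


def write_reads_fastq(
    path: Union[str, Path],
    manifest: LibraryManifest,
    counts_per_sgrna: dict[str, int],
    seed: int = 0,
    read_length: Optional[int] = None,
) -> None:
    """Write an error-free synthetic FASTQ realizing a given sgRNA count vector.

    Each read is the sgRNA protospacer (padded with ``A`` to ``read_length``
    if requested); reads are emitted in a seeded shuffled order so counting is
    exercised on interleaved input.
    """
    spacer = manifest.sgrna_to_gene()  # validates ids exist
    reads: list[tuple[str, str]] = []
    proto = {e.sgrna_id: e.protospacer for e in manifest.entries}
    for sgrna_id, n in counts_per_sgrna.items():
        if sgrna_id not in spacer:
            raise KeyError(f"unknown sgrna_id {sgrna_id!r}")
        seq = proto[sgrna_id]
        if read_length is not None:
            seq = seq + "A" * (read_length - len(seq))
        for k in range(n):
            reads.append((f"{sgrna_id}:{k}", seq))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    with open(path, "w", encoding="utf-8") as fh:
        for i in order:
            name, seq = reads[i]
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
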