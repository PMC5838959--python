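"""Plain-text file formats used throughout the pipeline.

All genomic coordinates are BED-style 0-based half-open internally; any
1-based interchange happens only at read/write boundaries.  Readers reject
invariant violations (negative TPM, empty intervals, unmatched samples)
rather than silently repairing them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_CATEGORIES = ("tissue", "primary_cell", "cell_line")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicRegion:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def tss_point(self) -> int:
        """Strand-aware 5' end: ``start`` on +, ``end - 1`` on -.

        CAGE peaks are intervals but all TSS-relative window arithmetic
        needs a single representative base.
        """
        return self.start if self.strand == "+" else self.end - 1

    @property
    def midpoint(self) -> int:
        """Midpoint; for even-length regions the left-of-center base."""
        return self.start + (self.end - self.start - 1) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    category: str
    tissue_label: str
    organ: str

    def __post_init__(self):
        if self.category not in SAMPLE_CATEGORIES:
            raise ValueError(
                f"sample {self.sample_id!r}: category {self.category!r} not in "
                f"{SAMPLE_CATEGORIES}"
            )


def read_bed(path) -> list[GenomicRegion]:
    """Read a BED3..BED6 file into :class:`GenomicRegion` records.

    A missing strand column defaults to ``+`` with a warning; malformed
    coordinates raise with the offending line number.
    """
    regions: list[GenomicRegion] = []
    warned_strand = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 else f"{chrom}:{fields[1]}-{fields[2]}"
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric score") from exc
            if len(fields) > 5:
                strand = fields[5]
            else:
                strand = "+"
                if not warned_strand:
                    warnings.warn(
                        f"{path}: line {lineno}: no strand column, defaulting to '+'",
                        stacklevel=2,
                    )
                    warned_strand = True
            try:
                regions.append(
                    GenomicRegion(chrom, start, end, strand, name, score)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def write_bed(regions: Iterable[GenomicRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            score = f"{r.score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


def merge_overlapping_regions(regions: Sequence[GenomicRegion]) -> list[GenomicRegion]:
    """Merge overlapping same-chromosome intervals (strand-blind union).

    Used to de-duplicate pooled foreground windows before counting hits, so
    clustered TSS do not contribute the same genomic sequence twice.
    """
    merged: list[GenomicRegion] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicRegion(
                last.chrom, last.start, max(last.end, r.end), last.strand,
                last.name, last.score,
            )
        else:
            merged.append(r)
    return merged


# ---------------------------------------------------------------------------
# JASPAR PFM text

_BASES = "ACGT"


def read_jaspar_pfm(path) -> list[tuple[str, str, np.ndarray]]:
    """Parse JASPAR-format PFM text.

    Accepts both the bracketed dialect (``A  [ 10  0 ]``) and the plain
    labelled dialect (``A  10 0``).  Returns ``(matrix_id, name, counts)``
    tuples where ``counts`` is a 4 x L float array with rows A, C, G, T.
    Missing base rows or unequal row lengths are hard errors.
    """
    motifs: list[tuple[str, str, np.ndarray]] = []
    header: tuple[str, str] | None = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in _BASES if b not in rows]
        if missing:
            raise ValueError(
                f"{path}: motif {header[0]}: missing base row(s) {missing}"
            )
        lengths = {len(rows[b]) for b in _BASES}
        if len(lengths) != 1:
            raise ValueError(
                f"{path}: motif {header[0]}: unequal row lengths {sorted(lengths)}"
            )
        counts = np.array([rows[b] for b in _BASES], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"{path}: motif {header[0]}: negative counts")
        motifs.append((header[0], header[1], counts))
        header, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
                continue
            if header is None:
                raise ValueError(f"{path}: line {lineno}: counts before header")
            base = line[0].upper()
            if base not in _BASES:
                raise ValueError(f"{path}: line {lineno}: unknown base row {base!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                values = [float(x) for x in body.split()]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric count") from exc
            if base in rows:
                raise ValueError(f"{path}: line {lineno}: duplicate row {base}")
            rows[base] = values
    flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found")
    return motifs


def write_jaspar_pfm(motifs: Iterable[tuple[str, str, np.ndarray]], path) -> None:
    """Write motifs in the bracketed JASPAR dialect."""
    with open(path, "w") as fh:
        for matrix_id, name, counts in motifs:
            counts = np.asarray(counts, dtype=float)
            fh.write(f">{matrix_id} {name}\n")
            for i, base in enumerate(_BASES):
                body = " ".join(f"{v:g}" for v in counts[i])
                fh.write(f"{base} [ {body} ]\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` dict (uppercased)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence before header")
                chunks.append(line.upper())
        if name is not None:
            seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression matrices

@dataclass
class ExpressionMatrix:
    """TPM values for regions (rows) by samples (columns) with metadata.

    ``values`` is a pandas DataFrame indexed by region/TSS id; ``meta`` has
    one row per sample with columns sample_id / category / tissue_label /
    organ, in column order of ``values``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate row ids in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("NaN values in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative TPM values in expression matrix")
        meta = self.meta.set_index("sample_id", drop=False)
        if meta.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        missing = [c for c in self.values.columns if c not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        bad = set(meta["category"]) - set(SAMPLE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown sample categories: {sorted(bad)}")
        # align metadata to column order
        self.meta = meta.loc[list(self.values.columns)].reset_index(drop=True)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[SampleMetadata]:
        return [
            SampleMetadata(r.sample_id, r.category, r.tissue_label, r.organ)
            for r in self.meta.itertuples()
        ]

    def category_mask(self, category: str) -> np.ndarray:
        if category not in SAMPLE_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return (self.meta["category"] == category).to_numpy()

    def category_values(self, category: str) -> pd.DataFrame:
        return self.values.loc[:, self.category_mask(category)]

    def subset_rows(self, rows: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(rows)], self.meta.copy())


def read_expression_matrix(values_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"sample_id", "category", "tissue_label", "organ"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"{metadata_path}: missing columns {sorted(required - set(meta.columns))}"
        )
    return ExpressionMatrix(values, meta)


def write_expression_matrix(expr: ExpressionMatrix, values_path, metadata_path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="region_id")
    expr.meta[["sample_id", "category", "tissue_label", "organ"]].to_csv(
        metadata_path, sep="\t", index=False
    )
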