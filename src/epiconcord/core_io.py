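"""Data model and readers/writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open. GFF3 (1-based closed) is
converted on read; BED and bedGraph are native. Marking flags are tri-state:
``marked`` / ``unmarked`` for species where the gene is present, absent (NA)
otherwise — "unmarked" and "gene lost" are distinct states.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Default species triplet; the first two are the sister pair, the third is
#: the outgroup-most species used by the constrained-marking rule.
DEFAULT_SPECIES = ("Ath", "Aly", "Aal")

MARKS = ("H3K27me3", "H3K4me3")

#: Sentinel written for saturated ("white") contact-matrix cells.
SATURATED_SENTINEL = "W"

ABSENT_TOKENS = {".", "", "NA"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed values violate a semantic invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start > self.end:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneModel:
    """A gene with 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    species: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class OrthologRecord:
    """One protogene with its per-species descendants and marking flags.

    ``marks`` holds ``True`` (marked) / ``False`` (unmarked) keyed by
    ``(species, mark)`` and only for species where a gene is present;
    querying an absent species returns ``None`` (NA).
    """

    protogene_id: str
    gene_by_species: dict[str, str] = field(default_factory=dict)
    marks: dict[tuple[str, str], bool] = field(default_factory=dict)
    outgroup_marked: Optional[bool] = None
    dup_class: str = "single_copy"

    def __post_init__(self) -> None:
        for (sp, mark), _flag in self.marks.items():
            if sp not in self.gene_by_species:
                raise ValidationError(
                    f"{self.protogene_id}: mark flag for absent species {sp}"
                )
            if mark not in MARKS:
                raise ValidationError(f"{self.protogene_id}: unknown mark {mark}")

    def is_marked(self, species: str, mark: str) -> Optional[bool]:
        """Tri-state marking query: True / False / None (gene absent)."""
        if species not in self.gene_by_species:
            return None
        return self.marks.get((species, mark), False)

    @property
    def species_present(self) -> frozenset[str]:
        return frozenset(self.gene_by_species)


@dataclass
class ExpressionMatrix:
    """Genes x tissues expression levels (non-negative)."""

    genes: list[str]
    tissues: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValidationError("expression matrix shape mismatch")
        if (self.values < 0).any():
            raise ValidationError("negative expression values")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.genes.index(gene_id)]


@dataclass
class ContactMatrix:
    """Symmetric binned intra-chromosomal contact scores in [0, 2].

    Saturated ("white") cells are tracked in a boolean mask and carry NaN in
    ``scores``; they classify as strong downstream.
    """

    chrom: str
    scores: np.ndarray
    saturated: np.ndarray
    bin_size: int = 20_000

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        n, m = self.scores.shape
        if n != m or self.saturated.shape != (n, m):
            raise ValidationError("contact matrix must be square")
        if self.bin_size <= 0:
            raise ValidationError("bin_size must be positive")
        finite = self.scores[~self.saturated]
        if np.isnan(finite).any():
            raise ValidationError("NaN score outside the saturated mask")
        if ((finite < 0) | (finite > 2)).any():
            raise ValidationError("contact scores must lie in [0, 2]")

    @property
    def n_bins(self) -> int:
        return self.scores.shape[0]

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chrom, i * self.bin_size, (i + 1) * self.bin_size)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path, species: str = "", feature_type: str = "gene") -> list[GeneModel]:
    """Read gene features from a GFF3 file into 0-based half-open GeneModels.

    Parameters
    ----------
    path : str or Path
        GFF3 file. Only lines whose feature type equals ``feature_type``
        are retained.
    species : str
        Species tag stored on each GeneModel.

    Raises
    ------
    ParseError
        On a malformed line (reported with its line number).
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise ParseError(f"{path}:{lineno}: invalid 1-based range {start}..{end}")
            if strand not in {"+", "-"}:
                import warnings

                warnings.warn(
                    f"{path}:{lineno}: unknown strand {strand!r}, record skipped"
                )
                continue
            gene_id = _gff3_attr(attrs, "ID") or f"line{lineno}"
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id}")
            seen.add(gene_id)
            # GFF3 1-based closed -> 0-based half-open
            genes.append(
                GeneModel(gene_id, chrom, start_i - 1, end_i, strand, species)
            )
    return genes


def _gff3_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff3(genes: Iterable[GeneModel], path, feature_type: str = "gene") -> None:
    """Inverse of :func:`read_gff3` (0-based half-open -> 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tepiconcord\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Marking tables
# ---------------------------------------------------------------------------


def read_marking_table(
    path, species: Sequence[str] = DEFAULT_SPECIES, marks: Sequence[str] = MARKS
) -> list[OrthologRecord]:
    """Read a per-ortholog marking table.

    Expected TSV layout: ``protogene_id``, one gene-id column per species
    (``gene_<sp>``; "." or empty = absent), one flag column per (mark,
    species) pair (``<mark>_<sp>``; 1/0, NA only where the gene is absent),
    and optional ``outgroup_H3K27me3`` and ``dup_class`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df["protogene_id"].duplicated().any():
        dup = df["protogene_id"][df["protogene_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate protogene_id {dup}")
    records = []
    has_outgroup = "outgroup_H3K27me3" in df.columns
    has_dup = "dup_class" in df.columns
    for row in df.itertuples(index=False):
        row = row._asdict()
        pid = row["protogene_id"]
        gene_by_species: dict[str, str] = {}
        mark_flags: dict[tuple[str, str], bool] = {}
        for sp in species:
            gid = row.get(f"gene_{sp}", ".")
            if gid not in ABSENT_TOKENS:
                gene_by_species[sp] = gid
        for mark in marks:
            for sp in species:
                raw = row.get(f"{mark}_{sp}", "NA").strip()
                present = sp in gene_by_species
                if raw in {"NA", "."}:
                    if present:
                        raise ValidationError(
                            f"{pid}: missing {mark} flag for present gene in {sp}"
                        )
                    continue
                if not present:
                    raise ValidationError(
                        f"{pid}: {mark} flag given for absent gene in {sp}"
                    )
                if raw == "":
                    raise ValidationError(
                        f"{pid}: empty {mark} flag for present gene in {sp}"
                    )
                if raw not in {"0", "1"}:
                    raise ParseError(f"{pid}: bad flag value {raw!r}")
                mark_flags[(sp, mark)] = raw == "1"
        outgroup: Optional[bool] = None
        if has_outgroup:
            raw = row["outgroup_H3K27me3"].strip()
            if raw in {"0", "1"}:
                outgroup = raw == "1"
        dup_class = row["dup_class"] if has_dup else "single_copy"
        records.append(
            OrthologRecord(pid, gene_by_species, mark_flags, outgroup, dup_class)
        )
    return records


def write_marking_table(
    records: Iterable[OrthologRecord],
    path,
    species: Sequence[str] = DEFAULT_SPECIES,
    marks: Sequence[str] = MARKS,
) -> None:
    rows = []
    for rec in records:
        row: dict[str, str] = {"protogene_id": rec.protogene_id}
        for sp in species:
            row[f"gene_{sp}"] = rec.gene_by_species.get(sp, ".")
        for mark in marks:
            for sp in species:
                flag = rec.is_marked(sp, mark)
                row[f"{mark}_{sp}"] = "NA" if flag is None else str(int(flag))
        row["outgroup_H3K27me3"] = (
            "NA" if rec.outgroup_marked is None else str(int(rec.outgroup_marked))
        )
        row["dup_class"] = rec.dup_class
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------


def read_contact_matrix(path, bin_size: int = 20_000, chrom: str = "chr1") -> ContactMatrix:
    """Read a dense square contact-score TSV.

    Cells are floats in [0, 2] or the sentinel ``W`` for saturated/"white"
    cells. The matrix is symmetrized by taking max(score[i,j], score[j,i]);
    a saturated cell dominates its mirror.
    """
    raw = [line.rstrip("\n").split("\t") for line in open(path) if line.strip()]
    n = len(raw)
    if any(len(r) != n for r in raw):
        raise ParseError(f"{path}: contact matrix is not square")
    scores = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i, rowvals in enumerate(raw):
        for j, cell in enumerate(rowvals):
            if cell.strip() == SATURATED_SENTINEL:
                saturated[i, j] = True
                scores[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise ParseError(f"{path}: bad cell {cell!r} at ({i},{j})") from exc
            if v < 0 or v > 2:
                raise ValidationError(
                    f"{path}: score {v} at ({i},{j}) outside [0, 2]"
                )
            scores[i, j] = v
    saturated = saturated | saturated.T
    with np.errstate(invalid="ignore"):
        scores = np.fmax(scores, scores.T)
    scores[saturated] = np.nan
    return ContactMatrix(chrom, scores, saturated, bin_size)


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        for i in range(cm.n_bins):
            cells = [
                SATURATED_SENTINEL if cm.saturated[i, j] else repr(float(cm.scores[i, j]))
                for j in range(cm.n_bins)
            ]
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph / expression / blocks / FASTA
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open, native)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            strand = fields[5] if len(fields) >= 6 and fields[5] in {"+", "-"} else None
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track into a DataFrame (chrom, start, end, score)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str, "start": int, "end": int, "score": float},
    )
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x tissue expression TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(list(df.index), list(df.columns), df.to_numpy(float))


def write_expression(em: ExpressionMatrix, path) -> None:
    df = pd.DataFrame(em.values, index=em.genes, columns=em.tissues)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_blocks(path) -> pd.DataFrame:
    """Read synteny-block assignments: block_id, gene_id[, chrom, start, end]."""
    df = pd.read_csv(path, sep="\t", dtype={"block_id": str, "gene_id": str})
    if not {"block_id", "gene_id"}.issubset(df.columns):
        raise ParseError(f"{path}: block table needs block_id and gene_id columns")
    return df


def write_blocks(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def records_to_frame(records: Iterable[OrthologRecord]) -> pd.DataFrame:
    """Flatten OrthologRecords into a tidy DataFrame (one row per record)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "protogene_id": rec.protogene_id,
            "dup_class": rec.dup_class,
            "outgroup_H3K27me3": rec.outgroup_marked,
        }
        for sp, gid in rec.gene_by_species.items():
            row[f"gene_{sp}"] = gid
        for (sp, mark), flag in rec.marks.items():
            row[f"{mark}_{sp}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
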