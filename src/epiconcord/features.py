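"""Promoter- and gene-level covariates.

Promoter extraction (500 bp upstream of the TSS on the gene strand), 4-mer
composition Z-scores of a gene class against a reference class, transposable
element overlap flags, mean nucleosome-occupancy scores, and Shannon-entropy
tissue specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from epiconcord.core_io import GeneModel, GenomicInterval
from epiconcord.seqdist import all_kmers, kmer_counts

PROMOTER_LENGTH = 500


@dataclass(frozen=True)
class PromoterInterval:
    """Region immediately upstream of a gene's TSS (<= 500 bp after clipping)."""

    gene_id: str
    interval: GenomicInterval


@dataclass
class FourmerZscoreTable:
    """Per-4-mer class-vs-reference frequency Z-scores (256 rows)."""

    table: pd.DataFrame  # columns: kmer, f_class, f_ref, z

    def z(self, kmer: str) -> float:
        return float(self.table.set_index("kmer").loc[kmer, "z"])


@dataclass(frozen=True)
class EntropyScore:
    gene_id: str
    H: float


def promoter_interval(
    gene: GeneModel,
    length: int = PROMOTER_LENGTH,
    chrom_len: Optional[int] = None,
) -> PromoterInterval:
    """Promoter of a gene: ``length`` bp immediately upstream of the TSS on
    the gene strand, clipped to the chromosome.

    + strand: [start - length, start); - strand: [end, end + length).
    Raises ValueError if clipping leaves a zero-length interval.
    """
    if gene.strand == "+":
        start, end = max(0, gene.start - length), gene.start
    else:
        start, end = gene.end, gene.end + length
        if chrom_len is not None:
            end = min(end, chrom_len)
    if end <= start:
        raise ValueError(f"{gene.gene_id}: promoter empty after clipping")
    return PromoterInterval(gene.gene_id, GenomicInterval(gene.chrom, start, end, gene.strand))


def extract_promoter_sequences(
    genes: Iterable[GeneModel],
    genome: dict[str, str],
    length: int = PROMOTER_LENGTH,
) -> dict[str, str]:
    """Promoter sequences keyed by gene id (forward-strand sequence of the
    promoter interval; k-mer statistics downstream are strand-pooled)."""
    out = {}
    for gene in genes:
        chrom_seq = genome[gene.chrom]
        prom = promoter_interval(gene, length, chrom_len=len(chrom_seq))
        out[gene.gene_id] = chrom_seq[prom.interval.start : prom.interval.end]
    return out


def fourmer_zscores(
    class_promoters: Sequence[str],
    ref_promoters: Sequence[str],
    k: int = 4,
    method: str = "pooled",
) -> FourmerZscoreTable:
    """Class-vs-reference k-mer composition Z-scores.

    method="pooled" (default): counts are pooled within each promoter set
    and each k-mer gets a two-proportion z-statistic
    z = (f1 - f0) / sqrt(fbar (1 - fbar) (1/n1 + 1/n0)),
    where n is the total number of k-mer windows in each set and fbar the
    pooled frequency. A k-mer absent from both sets gets z = 0.

    method="per_promoter": z = (mean1 - mean0) / SE of the difference of
    per-promoter frequency means (Welch-style).
    """
    if not class_promoters or not ref_promoters:
        raise ValueError("both promoter sets must be non-empty")
    kmers = all_kmers(k)
    if method == "pooled":
        c1 = np.zeros(4**k)
        c0 = np.zeros(4**k)
        for seq in class_promoters:
            c1 += kmer_counts(seq, k)
        for seq in ref_promoters:
            c0 += kmer_counts(seq, k)
        n1, n0 = c1.sum(), c0.sum()
        f1, f0 = c1 / n1, c0 / n0
        fbar = (c1 + c0) / (n1 + n0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(fbar * (1 - fbar) * (1 / n1 + 1 / n0))
            z = np.where(se > 0, (f1 - f0) / se, 0.0)
    elif method == "per_promoter":
        def freq_matrix(seqs):
            rows = []
            for seq in seqs:
                c = kmer_counts(seq, k)
                t = c.sum()
                rows.append(c / t if t else c)
            return np.array(rows)

        m1, m0 = freq_matrix(class_promoters), freq_matrix(ref_promoters)
        f1, f0 = m1.mean(axis=0), m0.mean(axis=0)
        se = np.sqrt(
            m1.var(axis=0, ddof=1) / len(class_promoters)
            + m0.var(axis=0, ddof=1) / len(ref_promoters)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, (f1 - f0) / se, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    table = pd.DataFrame({"kmer": kmers, "f_class": f1, "f_ref": f0, "z": z})
    return FourmerZscoreTable(table)


def te_overlap_flag(promoter: PromoterInterval, te: GenomicInterval) -> bool:
    """True iff the promoter/TE overlap exceeds half the TE length (strict)."""
    overlap = promoter.interval.overlap(te)
    return overlap > 0.5 * len(te)


def harbors_te(promoter: PromoterInterval, tes: Iterable[GenomicInterval]) -> bool:
    """A promoter harbors a TE if any single TE passes the >50% overlap rule."""
    return any(te_overlap_flag(promoter, te) for te in tes)


def mean_noc(
    promoter: PromoterInterval, coverage: pd.DataFrame
) -> Optional[float]:
    """Mean nucleosome-occupancy score over promoter bases with data.

    ``coverage`` is a bedGraph frame (chrom, start, end, score); positions
    without data are excluded from the mean (never zero-filled). Returns
    None if no promoter base is covered.
    """
    iv = promoter.interval
    sub = coverage[
        (coverage["chrom"] == iv.chrom)
        & (coverage["end"] > iv.start)
        & (coverage["start"] < iv.end)
    ]
    total = 0.0
    n = 0
    for row in sub.itertuples(index=False):
        span = min(row.end, iv.end) - max(row.start, iv.start)
        total += span * row.score
        n += span
    return total / n if n else None


def tissue_entropy(expression_row: Sequence[float], n_tissues: int = 5) -> float:
    """Shannon entropy (bits) of a gene's tissue expression profile.

    Bounded in [0, log2(n_tissues)]: 0 for expression confined to a single
    tissue, log2(n_tissues) for perfectly uniform expression. Raises
    ValueError on an all-zero row (entropy undefined).
    """
    e = np.asarray(expression_row, dtype=float)
    if len(e) != n_tissues:
        raise ValueError(f"expected {n_tissues} tissues, got {len(e)}")
    if (e < 0).any():
        raise ValueError("negative expression values")
    total = e.sum()
    if total == 0:
        raise ValueError("all-zero expression row: entropy undefined (NA)")
    p = e / total
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return min(max(h, 0.0), math.log2(n_tissues))


def entropy_table(em, n_tissues: Optional[int] = None) -> list[EntropyScore]:
    """Tissue entropy for every gene of an ExpressionMatrix; all-zero rows
    are skipped."""
    n = n_tissues or len(em.tissues)
    out = []
    for gene, row in zip(em.genes, em.values):
        if row.sum() == 0:
            continue
        out.append(EntropyScore(gene, tissue_entropy(row, n)))
    return out
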