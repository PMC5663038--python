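"""Contact-map analyses.

Classifies binned intra-chromosomal contacts as weak / moderate / strong,
measures co-occurrence of marked gene sets with high-connectivity regions
(with Fisher tests against the all-marked background), and builds
strong-contact distance ECDFs per synteny-block enrichment category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from epiconcord.core_io import ContactMatrix, GeneModel, GenomicInterval
from epiconcord.stats import fisher_cooccurrence

WEAK = "weak"
MODERATE = "moderate"
STRONG = "strong"

#: Score class intervals. The printed two-decimal boundaries (0.59/0.60,
#: 1.29/1.30) imply two-decimal rounding, so intervals are half-open at the
#: upper boundary: [0, 0.60) / [0.60, 1.30) / [1.30, 2] plus saturated.
MODERATE_MIN = 0.60
STRONG_MIN = 1.30

BLOCK_CATEGORIES = ("plastic_enriched", "constrained_enriched", "not_enriched")


@dataclass(frozen=True)
class ContactRecord:
    bin_i: int
    bin_j: int
    score: float  # NaN if saturated
    strength: str
    distance: int  # bp

    def __post_init__(self) -> None:
        if self.bin_i > self.bin_j:
            raise ValueError("store contacts with bin_i <= bin_j")


def classify_contact(score: float, saturated: bool = False) -> str:
    """Weak / moderate / strong class of a contact score.

    Saturated ("white") cells are strong by contract; otherwise the score
    must lie in [0, 2].
    """
    if saturated:
        return STRONG
    if np.isnan(score) or score < 0 or score > 2:
        raise ValueError(f"contact score {score} outside [0, 2] and not saturated")
    if score < MODERATE_MIN:
        return WEAK
    if score < STRONG_MIN:
        return MODERATE
    return STRONG


def contact_records(cm: ContactMatrix, min_distance_bins: int = 1) -> list[ContactRecord]:
    """Upper-triangle contacts of a matrix as classified records."""
    out = []
    n = cm.n_bins
    for i in range(n):
        for j in range(i + min_distance_bins, n):
            sat = bool(cm.saturated[i, j])
            score = float(cm.scores[i, j])
            out.append(
                ContactRecord(i, j, score, classify_contact(score, sat), (j - i) * cm.bin_size)
            )
    return out


def _overlaps_any(
    iv: GenomicInterval, regions: Sequence[GenomicInterval], min_overlap: int = 1
) -> bool:
    return any(iv.overlap(r) >= min_overlap for r in regions)


def overlap_proportions(
    gene_sets: Mapping[str, Sequence[GeneModel]],
    regions: Sequence[GenomicInterval],
    block_intervals: Optional[Mapping[str, list[GenomicInterval]]] = None,
    background: str = "all_marked",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Proportion of genes of each set overlapping high-connectivity regions.

    ``gene_sets`` maps a set name (e.g. all_marked / plastic / constrained)
    to its genes; when ``block_intervals`` (category -> intervals) is given
    the proportions are additionally computed within each block category.
    Each non-background set gets a Fisher exact test of its
    overlap/no-overlap split against the background set.

    Returns a tidy frame with columns: gene_set, block_category, n_genes,
    n_overlap, proportion, odds_ratio, p_value.
    """
    if background not in gene_sets:
        raise ValueError(f"background set {background!r} missing from gene_sets")

    categories: dict[str, Optional[list[GenomicInterval]]] = {"all_blocks": None}
    if block_intervals is not None:
        categories.update(block_intervals)

    rows = []
    for cat, blocks in categories.items():
        counts: dict[str, tuple[int, int]] = {}
        for name, genes in gene_sets.items():
            if blocks is not None:
                genes = [g for g in genes if _overlaps_any(g.interval, blocks)]
            n = len(genes)
            k = sum(
                1 for g in genes if _overlaps_any(g.interval, regions, min_overlap)
            )
            counts[name] = (n, k)
        bg_n, bg_k = counts[background]
        for name, (n, k) in counts.items():
            odds = p = None
            if name != background and n > 0 and bg_n > 0:
                odds, p = fisher_cooccurrence([[k, n - k], [bg_k, bg_n - bg_k]])
            rows.append(
                {
                    "gene_set": name,
                    "block_category": cat,
                    "n_genes": n,
                    "n_overlap": k,
                    "proportion": k / n if n else None,
                    "odds_ratio": odds,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Ecdf:
    """Right-continuous empirical CDF over contact distances (bp)."""

    values: np.ndarray  # sorted distances

    @property
    def n(self) -> int:
        return len(self.values)

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(x)
        return np.searchsorted(self.values, x, side="right") / max(self.n, 1)


def strong_contact_distance_ecdf(
    contacts: Iterable[ContactRecord],
    block_categories_by_bin: Mapping[int, set[str]],
    categories: Sequence[str] = BLOCK_CATEGORIES,
) -> tuple[dict[str, Ecdf], pd.DataFrame]:
    """Distance ECDF of strong contacts per block-enrichment category.

    A contact is attributed to a category if either anchor bin intersects a
    block of that category (a contact may count in several categories).
    Also returns pairwise two-sample Kolmogorov-Smirnov statistics between
    category ECDFs (NA when either sample is empty).
    """
    dists: dict[str, list[int]] = {cat: [] for cat in categories}
    for c in contacts:
        if c.strength != STRONG:
            continue
        cats = block_categories_by_bin.get(c.bin_i, set()) | block_categories_by_bin.get(
            c.bin_j, set()
        )
        for cat in cats:
            if cat in dists:
                dists[cat].append(c.distance)
    ecdfs = {cat: Ecdf(np.sort(np.array(v, dtype=float))) for cat, v in dists.items()}
    rows = []
    for i, a in enumerate(categories):
        for b in categories[i + 1 :]:
            if ecdfs[a].n == 0 or ecdfs[b].n == 0:
                rows.append({"cat_a": a, "cat_b": b, "ks_stat": None, "p_value": None})
                continue
            ks = sps.ks_2samp(ecdfs[a].values, ecdfs[b].values)
            rows.append(
                {
                    "cat_a": a,
                    "cat_b": b,
                    "ks_stat": float(ks.statistic),
                    "p_value": float(ks.pvalue),
                }
            )
    return ecdfs, pd.DataFrame(rows)


def bin_block_categories(
    cm: ContactMatrix,
    block_intervals: Mapping[str, list[GenomicInterval]],
) -> dict[int, set[str]]:
    """Map each matrix bin to the block categories its interval intersects."""
    out: dict[int, set[str]] = {}
    for i in range(cm.n_bins):
        iv = cm.bin_interval(i)
        cats = {
            cat
            for cat, blocks in block_intervals.items()
            if _overlaps_any(iv, blocks)
        }
        if cats:
            out[i] = cats
    return out
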