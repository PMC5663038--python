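"""Ohnolog detection via double conserved synteny (DCS).

A DCS block is a run of outgroup genes whose orthologs in the duplicated
species fall into two gene runs on distinct chromosomes — the signature of a
whole-genome duplication. Ohnolog pairs are the per-anchor duplicates on the
block's two chromosomes, with tandem duplicates excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from epiconcord.core_io import GenomicInterval

DEFAULT_WINDOW = 20
DEFAULT_MIN_SUPPORT = 3
DEFAULT_TANDEM_MAX_GAP = 1


@dataclass
class DcsBlock:
    """Two regions of a duplicated genome syntenic to one outgroup region.

    Regions are expressed in gene-index coordinates (ordinal position along
    the gene order, 0-based half-open).
    """

    block_id: str
    outgroup_region: GenomicInterval
    dup_regions: tuple[GenomicInterval, GenomicInterval]
    anchors: list[str]  # outgroup gene ids supporting the block

    def __post_init__(self) -> None:
        if self.dup_regions[0].chrom == self.dup_regions[1].chrom:
            raise ValueError("DCS dup regions must lie on distinct chromosomes")


@dataclass(frozen=True)
class OhnologPair:
    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    dcs_block_id: str

    def __post_init__(self) -> None:
        if self.chrom_a == self.chrom_b:
            raise ValueError("ohnolog pair members must lie on distinct chromosomes")


def _window_chrom_support(
    window_genes: Sequence[str],
    ortholog_map: Mapping[str, Sequence[str]],
    dup_positions: Mapping[str, tuple[str, int]],
) -> dict[str, set[str]]:
    """chromosome -> set of outgroup anchors with >=1 mapped gene there."""
    support: dict[str, set[str]] = {}
    for og in window_genes:
        for dup_gene in ortholog_map.get(og, ()):  # up to 2 mapped genes
            if dup_gene not in dup_positions:
                continue
            chrom, _idx = dup_positions[dup_gene]
            support.setdefault(chrom, set()).add(og)
    return support


def find_dcs_blocks(
    outgroup_order: Sequence[str],
    ortholog_map: Mapping[str, Sequence[str]],
    dup_positions: Mapping[str, tuple[str, int]],
    window: int = DEFAULT_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[DcsBlock]:
    """Scan the outgroup gene order for double-conserved-synteny blocks.

    Parameters
    ----------
    outgroup_order : sequence of outgroup gene ids in genome order.
    ortholog_map : outgroup gene id -> up to 2 duplicated-species gene ids.
    dup_positions : duplicated-species gene id -> (chromosome, gene index).
    window : number of consecutive outgroup genes per sliding window.
    min_support : minimum anchors per duplicated region.

    Each window whose mapped genes concentrate on two distinct chromosomes
    (the top two by anchor count, each with >= min_support anchors) becomes
    a candidate; overlapping candidates with the same chromosome pair merge
    into one block.
    """
    n = len(outgroup_order)
    candidates: list[tuple[int, int, tuple[str, str]]] = []  # start, end, chrom pair
    for start in range(0, max(1, n - window + 1)):
        genes = outgroup_order[start : start + window]
        support = _window_chrom_support(genes, ortholog_map, dup_positions)
        ranked = sorted(support.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        # Only the top two chromosomes are considered per window.
        if len(ranked) < 2:
            continue
        (chrom1, sup1), (chrom2, sup2) = ranked[0], ranked[1]
        if len(sup1) >= min_support and len(sup2) >= min_support:
            pair = tuple(sorted((chrom1, chrom2)))
            candidates.append((start, start + len(genes), pair))

    blocks: list[DcsBlock] = []
    merged: list[tuple[int, int, tuple[str, str]]] = []
    for start, end, pair in candidates:
        if merged and pair == merged[-1][2] and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], end, pair)
        else:
            merged.append((start, end, pair))

    for b, (start, end, pair) in enumerate(merged):
        anchors = []
        dup_idx: dict[str, list[int]] = {pair[0]: [], pair[1]: []}
        for og in outgroup_order[start:end]:
            hit_chroms = set()
            for dup_gene in ortholog_map.get(og, ()):
                if dup_gene not in dup_positions:
                    continue
                chrom, idx = dup_positions[dup_gene]
                if chrom in dup_idx:
                    hit_chroms.add(chrom)
                    dup_idx[chrom].append(idx)
            if hit_chroms:
                anchors.append(og)
        if not dup_idx[pair[0]] or not dup_idx[pair[1]]:
            continue
        regions = tuple(
            GenomicInterval(chrom, min(dup_idx[chrom]), max(dup_idx[chrom]) + 1)
            for chrom in pair
        )
        blocks.append(
            DcsBlock(
                f"dcs{b}",
                GenomicInterval("outgroup", start, end),
                regions,  # type: ignore[arg-type]
                anchors,
            )
        )
    return blocks


def call_ohnolog_pairs(
    blocks: Sequence[DcsBlock],
    ortholog_map: Mapping[str, Sequence[str]],
    dup_positions: Mapping[str, tuple[str, int]],
    tandem_max_gap: int = DEFAULT_TANDEM_MAX_GAP,
) -> list[OhnologPair]:
    """Ohnolog pairs: per outgroup anchor of a DCS block, the duplicate on
    each of the block's two chromosomes.

    Anchors mapping to a single chromosome yield no pair. Members within
    ``tandem_max_gap`` gene positions on the same chromosome are tandem
    duplicates and excluded (redundant with the distinct-chromosome rule,
    retained for safety). Pairs are deduplicated across blocks.
    """
    seen: set[tuple[str, str]] = set()
    pairs: list[OhnologPair] = []
    for block in blocks:
        chrom_pair = {r.chrom for r in block.dup_regions}
        for og in block.anchors:
            by_chrom: dict[str, str] = {}
            for dup_gene in ortholog_map.get(og, ()):
                if dup_gene not in dup_positions:
                    continue
                chrom, _idx = dup_positions[dup_gene]
                if chrom in chrom_pair and chrom not in by_chrom:
                    by_chrom[chrom] = dup_gene
            if len(by_chrom) != 2:
                continue
            (ca, ga), (cb, gb) = sorted(by_chrom.items())
            if ca == cb and abs(dup_positions[ga][1] - dup_positions[gb][1]) <= tandem_max_gap:
                continue  # tandem duplicate
            key = tuple(sorted((ga, gb)))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(OhnologPair(ga, gb, ca, cb, block.block_id))
    return pairs
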