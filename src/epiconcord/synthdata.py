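"""Seeded generators for every input the pipeline consumes.

All generators draw from a single integer-seeded ``numpy.random.Generator``
(PCG64), so outputs are byte-reproducible across platforms. Each generator
can record its true parameters in a manifest, enabling parameter-recovery
tests. The marking generator uses a latent ancestral-target mechanism: a
stand-in for unmodeled evolution that spans the observed pattern space
(high realization probability -> constrained-like patterns, independent
switching -> plastic-like patterns).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from epiconcord.core_io import (
    DEFAULT_SPECIES,
    ContactMatrix,
    ExpressionMatrix,
    OrthologRecord,
)

#: Table of per-pattern ortholog counts used by the exact fixture, keyed by
#: canonical pattern name. ``outgroup`` gives, per pattern, how many records
#: carry the distant-clade (outgroup) repressive mark as well.
FIXTURE_PATTERN_COUNTS = {
    "H3K27me3": {
        "Ath-Aly-Aal": 1464,
        "Ath-Aly": 512,
        "Aly-Aal": 97,
        "Ath-Aal": 197,
        "Ath": 775,
        "Aly": 327,
        "Aal": 301,
        "none": 9842,
    },
    "H3K4me3": {
        "Ath-Aly-Aal": 10010,
        "Ath-Aly": 505,
        "Aly-Aal": 280,
        "Ath-Aal": 188,
        "Ath": 201,
        "Aly": 291,
        "Aal": 289,
        "none": 1751,
    },
    "outgroup": {
        "Ath-Aly-Aal": 384,
        "Ath-Aly": 68,
        "Aly-Aal": 10,
        "Ath-Aal": 31,
        "Ath": 121,
        "Aly": 44,
        "Aal": 46,
        "none": 0,
    },
}

FIXTURE_TOTAL = 13_515


@dataclass
class SyntheticConfig:
    """All generator parameters. ``seed`` is mandatory."""

    seed: int
    n_orthologs: int = 1000
    species: tuple[str, ...] = DEFAULT_SPECIES
    # marking model
    theta: float = 0.15  # ancestral-target probability
    rho: float = 0.9  # per-species realization probability for targets
    switch_rate: float = 0.05  # independent per-species marking otherwise
    k4_rate: float = 0.8  # independent active-mark rate per species
    outgroup_rate_target: float = 0.25
    outgroup_rate_other: float = 0.1
    # promoters
    promoter_length: int = 500
    at_boost: float = 0.05  # AT-probability boost for the constrained class
    base_gc: float = 0.5
    # expression
    n_tissues: int = 5
    alpha_constrained: float = 0.3  # low concentration -> tissue-specific
    alpha_plastic: float = 3.0
    expression_scale: float = 100.0
    # synteny blocks
    block_length_mean: int = 30
    block_length_fixed: bool = False
    enrichment_factor: float = 3.0
    n_enriched_blocks: int = 2
    # contacts
    bin_size: int = 20_000
    decay_gamma: float = 0.8
    decay_scale: float = 1.2
    contact_noise: float = 0.05
    long_range_boost: float = 0.8
    long_range_min_bins: int = 25
    # ohnologs
    anchor_loss_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "theta", "rho", "switch_rate", "k4_rate", "outgroup_rate_target",
            "outgroup_rate_other", "at_boost", "anchor_loss_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["species"] = list(d["species"])
        return d


def write_manifest(config: SyntheticConfig, path, extra: Optional[dict] = None) -> None:
    """Sidecar manifest with the true generator parameters."""
    doc = {"config": config.manifest()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Ortholog marking tables
# ---------------------------------------------------------------------------


def generate_ortholog_table(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[OrthologRecord], dict[str, str]]:
    """Single-copy ortholog records with correlated repressive marking.

    Latent ancestral-target state drawn with probability ``theta``; targets
    are marked per species with probability ``rho`` (high rho yields
    constrained-like patterns), non-targets independently at
    ``switch_rate``. The active mark is independent at ``k4_rate``. Returns
    the records and the true latent labels (``target`` / ``non_target``).
    """
    rng = rng or config.rng()
    sp = config.species
    records: list[OrthologRecord] = []
    truth: dict[str, str] = {}
    for i in range(config.n_orthologs):
        pid = f"proto{i:06d}"
        is_target = rng.random() < config.theta
        rate = config.rho if is_target else config.switch_rate
        marks: dict[tuple[str, str], bool] = {}
        genes = {s: f"{s}_g{i:06d}" for s in sp}
        for s in sp:
            marks[(s, "H3K27me3")] = bool(rng.random() < rate)
            marks[(s, "H3K4me3")] = bool(rng.random() < config.k4_rate)
        out_rate = (
            config.outgroup_rate_target if is_target else config.outgroup_rate_other
        )
        outgroup = bool(rng.random() < out_rate)
        records.append(OrthologRecord(pid, genes, marks, outgroup))
        truth[pid] = "target" if is_target else "non_target"
    return records, truth


def table1_fixture(species: Sequence[str] = DEFAULT_SPECIES) -> list[OrthologRecord]:
    """Deterministic fixture whose pattern tabulation is exact.

    Patterns are assigned in blocks (the first 1464 records carry the
    three-species repressive pattern, the next 512 the sister-pair pattern,
    and so on), independently for each mark, and outgroup flags fill the
    head of each repressive-pattern block. No sampling is involved, so the
    tabulation reproduces the reference counts cell for cell.
    """
    def expand(counts: dict[str, int]) -> list[frozenset[str]]:
        out = []
        for key, n in counts.items():
            marked = frozenset() if key == "none" else frozenset(key.split("-"))
            out.extend([marked] * n)
        return out

    k27 = expand(FIXTURE_PATTERN_COUNTS["H3K27me3"])
    k4 = expand(FIXTURE_PATTERN_COUNTS["H3K4me3"])
    outgroup_flags: list[Optional[bool]] = []
    for key, n in FIXTURE_PATTERN_COUNTS["H3K27me3"].items():
        if key == "none":
            outgroup_flags.extend([None] * n)
        else:
            n_out = FIXTURE_PATTERN_COUNTS["outgroup"][key]
            outgroup_flags.extend([True] * n_out + [False] * (n - n_out))
    assert len(k27) == len(k4) == len(outgroup_flags) == FIXTURE_TOTAL

    records = []
    for i, (m27, m4, og) in enumerate(zip(k27, k4, outgroup_flags)):
        genes = {s: f"{s}_g{i:06d}" for s in species}
        marks: dict[tuple[str, str], bool] = {}
        for s in species:
            marks[(s, "H3K27me3")] = s in m27
            marks[(s, "H3K4me3")] = s in m4
        records.append(OrthologRecord(f"proto{i:06d}", genes, marks, og))
    return records


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------


def class_base_probs(config: SyntheticConfig, label: str) -> np.ndarray:
    """Per-class nucleotide probabilities over (A, C, G, T)."""
    at = (1.0 - config.base_gc) / 2.0
    gc = config.base_gc / 2.0
    if label == "constrained":
        at += config.at_boost / 2.0
        gc -= config.at_boost / 2.0
    if gc < 0:
        raise ValueError("at_boost too large for base_gc")
    return np.array([at, gc, gc, at])


def generate_promoters(
    config: SyntheticConfig,
    class_labels: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> dict[str, str]:
    """Multinomial promoter sequences per gene, with the constrained class
    AT-boosted by ``at_boost``; returned in the order of ``class_labels``."""
    rng = rng or config.rng()
    bases = np.array(list("ACGT"))
    out = {}
    for gene_id, label in class_labels.items():
        probs = class_base_probs(config, label)
        idx = rng.choice(4, size=config.promoter_length, p=probs)
        out[gene_id] = "".join(bases[idx])
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    config: SyntheticConfig,
    class_labels: dict[str, str],
    rng: Optional[np.random.Generator] = None,
) -> ExpressionMatrix:
    """Tissue-profile matrix with Dirichlet-distributed tissue proportions.

    Constrained-class genes draw from a lower-concentration Dirichlet
    (alpha_constrained < alpha_plastic), hence lower tissue entropy.
    """
    rng = rng or config.rng()
    tissues = [f"tissue{i+1}" for i in range(config.n_tissues)]
    genes = list(class_labels)
    values = np.zeros((len(genes), config.n_tissues))
    for i, gene in enumerate(genes):
        alpha = (
            config.alpha_constrained
            if class_labels[gene] == "constrained"
            else config.alpha_plastic
        )
        p = rng.dirichlet(np.full(config.n_tissues, alpha))
        values[i] = p * config.expression_scale
    return ExpressionMatrix(genes, tissues, values)


# ---------------------------------------------------------------------------
# Synteny blocks
# ---------------------------------------------------------------------------


def generate_blocks(
    config: SyntheticConfig,
    n_genes: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[str]], dict[str, str], dict[str, str]]:
    """Consecutive gene runs with class enrichment injected into designated
    blocks.

    Genes are laid out in genome order and cut into blocks of geometric
    length (mean ``block_length_mean``). The first ``n_enriched_blocks``
    blocks are designated constrained-enriched and the next as many
    plastic-enriched: their genes carry the class at ``enrichment_factor``
    times the background rate. Returns (blocks, gene classes, true block
    categories).
    """
    rng = rng or config.rng()
    n_genes = n_genes or config.n_orthologs
    base_rate = min(1.0, config.theta)
    boosted = min(1.0, base_rate * config.enrichment_factor)

    gene_ids = [f"g{i:06d}" for i in range(n_genes)]
    blocks: dict[str, list[str]] = {}
    i = 0
    b = 0
    while i < n_genes:
        if config.block_length_fixed:
            length = config.block_length_mean
        else:
            length = 1 + rng.geometric(1.0 / config.block_length_mean)
        blocks[f"block{b:04d}"] = gene_ids[i : i + length]
        i += length
        b += 1

    block_ids = list(blocks)
    categories: dict[str, str] = {bid: "not_enriched" for bid in block_ids}
    for bid in block_ids[: config.n_enriched_blocks]:
        categories[bid] = "constrained_enriched"
    for bid in block_ids[config.n_enriched_blocks : 2 * config.n_enriched_blocks]:
        categories[bid] = "plastic_enriched"

    classes: dict[str, str] = {}
    for bid, genes in blocks.items():
        cat = categories[bid]
        for g in genes:
            r = rng.random()
            if cat == "constrained_enriched":
                classes[g] = "constrained" if r < boosted else (
                    "plastic" if r < boosted + base_rate else "unmarked"
                )
            elif cat == "plastic_enriched":
                classes[g] = "plastic" if r < boosted else (
                    "constrained" if r < boosted + base_rate else "unmarked"
                )
            else:
                classes[g] = "constrained" if r < base_rate else (
                    "plastic" if r < 2 * base_rate else "unmarked"
                )
    return blocks, classes, categories


# ---------------------------------------------------------------------------
# Contact matrices
# ---------------------------------------------------------------------------


def generate_contacts(
    config: SyntheticConfig,
    n_bins: int,
    boosted_bins: Optional[set[int]] = None,
    chrom: str = "chr1",
    rng: Optional[np.random.Generator] = None,
) -> ContactMatrix:
    """Distance-decaying symmetric contact matrix with boosted long-range
    contacts for designated bins.

    score(i, j) = clip(scale * |i-j|^-gamma + boost * 1[long-range and both
    anchor bins designated] + noise, 0, 2), symmetrized. Designating two
    distant bin runs therefore wires boosted long-range contacts between
    them.
    """
    rng = rng or config.rng()
    boosted_bins = boosted_bins or set()
    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        scores = config.decay_scale * np.power(
            np.maximum(dist, 1.0), -config.decay_gamma
        )
    np.fill_diagonal(scores, 2.0)
    if boosted_bins:
        in_set = np.zeros(n_bins, dtype=bool)
        in_set[sorted(boosted_bins)] = True
        mask_boost = in_set[:, None] & in_set[None, :]
        long_range = dist >= config.long_range_min_bins
        scores = scores + config.long_range_boost * (mask_boost & long_range)
    noise = rng.normal(0.0, config.contact_noise, size=(n_bins, n_bins))
    scores = scores + (noise + noise.T) / 2.0
    scores = np.clip((scores + scores.T) / 2.0, 0.0, 2.0)
    saturated = np.zeros((n_bins, n_bins), dtype=bool)
    return ContactMatrix(chrom, scores, saturated, config.bin_size)


# ---------------------------------------------------------------------------
# Ohnolog fixtures
# ---------------------------------------------------------------------------


def generate_ohnologs(
    config: SyntheticConfig,
    n_outgroup_genes: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[str], dict[str, list[str]], dict[str, tuple[str, int]], list[tuple[str, str]]]:
    """Toy whole-genome duplication: the outgroup gene order is copied onto
    two chromosomes and each copy loses anchors at rate ``anchor_loss_rate``.

    Returns (outgroup gene order, ortholog map, duplicated-gene positions,
    true ohnolog pairs — the anchors retained on both chromosomes).
    """
    rng = rng or config.rng()
    outgroup_order = [f"og{i:05d}" for i in range(n_outgroup_genes)]
    ortholog_map: dict[str, list[str]] = {}
    dup_positions: dict[str, tuple[str, int]] = {}
    true_pairs: list[tuple[str, str]] = []
    idx_a = idx_b = 0
    for og in outgroup_order:
        keep_a = rng.random() >= config.anchor_loss_rate
        keep_b = rng.random() >= config.anchor_loss_rate
        mapped = []
        if keep_a:
            ga = f"dupA_{og}"
            dup_positions[ga] = ("chrA", idx_a)
            idx_a += 1
            mapped.append(ga)
        if keep_b:
            gb = f"dupB_{og}"
            dup_positions[gb] = ("chrB", idx_b)
            idx_b += 1
            mapped.append(gb)
        if mapped:
            ortholog_map[og] = mapped
        if keep_a and keep_b:
            true_pairs.append((f"dupA_{og}", f"dupB_{og}"))
    return outgroup_order, ortholog_map, dup_positions, true_pairs
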