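"""Per-ortholog marking-pattern classification and concordance statistics.

A marking *pattern* is the subset of species in which an ortholog carries a
given mark. Patterns with the mark in at least two species are *concordant*.
For the repressive mark, patterns split into two classes: *constrained*
(marked in the outgroup-most species and at least one sister species) and
*plastic* (marked somewhere, but not constrained). For the active mark the
analogous split is concordant vs lineage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

from epiconcord.core_io import DEFAULT_SPECIES, OrthologRecord, ValidationError

#: Class labels for the repressive mark.
PLASTIC = "plastic"
CONSTRAINED = "constrained"
UNMARKED = "unmarked"

#: Class labels for the active mark.
LINEAGE_SPECIFIC = "lineage_specific"
CONCORDANT = "concordant"


@dataclass(frozen=True)
class MarkingPattern:
    """Which species carry a mark for one ortholog."""

    species_marked: frozenset[str]
    species: tuple[str, ...] = DEFAULT_SPECIES

    @property
    def n_marked(self) -> int:
        return len(self.species_marked)

    @property
    def concordant(self) -> bool:
        return self.n_marked >= 2

    @property
    def key(self) -> str:
        """Canonical pattern name, e.g. ``Ath-Aly`` or ``none``."""
        marked = [sp for sp in self.species if sp in self.species_marked]
        return "-".join(marked) if marked else "none"


def all_pattern_keys(species: Sequence[str] = DEFAULT_SPECIES) -> list[str]:
    """The 8 pattern names in canonical order (triple, pairs, singles, none)."""
    keys = []
    for bits in product([True, False], repeat=len(species)):
        marked = frozenset(sp for sp, b in zip(species, bits) if b)
        keys.append(MarkingPattern(marked, tuple(species)).key)
    keys.sort(key=lambda k: (-(k.count("-") + 1) if k != "none" else 1, k == "none"))
    # stable, explicit ordering for the default triplet
    return keys


@dataclass
class PatternTable:
    """Ortholog counts per marking pattern, with optional outgroup counts."""

    counts: dict[str, int]
    outgroup_counts: dict[str, int] = field(default_factory=dict)
    species: tuple[str, ...] = DEFAULT_SPECIES

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        for key, n in self.outgroup_counts.items():
            if n > self.counts.get(key, 0):
                raise ValidationError(
                    f"outgroup count exceeds pattern count for {key}"
                )


@dataclass
class PatternNull:
    """Independence null over patterns, conditioned on >=1 species marked."""

    marginals: dict[str, float]
    expected_fraction: dict[str, float]


# ---------------------------------------------------------------------------


def classify_pattern(
    record: OrthologRecord, mark: str, species: Sequence[str] = DEFAULT_SPECIES
) -> MarkingPattern:
    """Marking pattern of a single-copy ortholog for one mark.

    Raises
    ------
    ValidationError
        If any of the three species lacks a gene (only single-copy records
        are admissible).
    """
    flags = {}
    for sp in species:
        flag = record.is_marked(sp, mark)
        if flag is None:
            raise ValidationError(
                f"{record.protogene_id}: {sp} absent — not a single-copy record"
            )
        flags[sp] = flag
    return MarkingPattern(
        frozenset(sp for sp, f in flags.items() if f), tuple(species)
    )


def classify_h3k27(
    pattern: MarkingPattern,
    reference_species: str = "Aal",
    sister_species: Sequence[str] = ("Ath", "Aly"),
) -> str:
    """Plastic / constrained / unmarked label for a repressive-mark pattern.

    Constrained: marked in ``reference_species`` and in at least one sister
    species. Plastic: marked somewhere but not constrained (sister species
    only, or reference species exclusively). Unmarked: no species marked.
    """
    if pattern.n_marked == 0:
        return UNMARKED
    if reference_species in pattern.species_marked and any(
        sp in pattern.species_marked for sp in sister_species
    ):
        return CONSTRAINED
    return PLASTIC


def classify_h3k4(pattern: MarkingPattern) -> str:
    """Lineage-specific / concordant / unmarked label for the active mark."""
    if pattern.n_marked == 0:
        return UNMARKED
    return CONCORDANT if pattern.concordant else LINEAGE_SPECIFIC


def tabulate_patterns(
    records: Iterable[OrthologRecord],
    mark: str,
    species: Sequence[str] = DEFAULT_SPECIES,
) -> PatternTable:
    """Count orthologs per marking pattern (and per pattern with the
    outgroup flag set, for the repressive mark)."""
    counts = {key: 0 for key in all_pattern_keys(species)}
    outgroup = {key: 0 for key in all_pattern_keys(species)}
    for rec in records:
        key = classify_pattern(rec, mark, species).key
        counts[key] += 1
        if rec.outgroup_marked:
            outgroup[key] += 1
    return PatternTable(counts, outgroup, tuple(species))


def _pattern_category(key: str, table: PatternTable) -> str:
    if key == "none":
        return "none"
    n = key.count("-") + 1
    return {1: "single", 2: "double", 3: "triple"}[n]


def concordance_summary(
    table: PatternTable, sister_pair: Sequence[str] = ("Ath", "Aly")
) -> dict[str, Optional[float]]:
    """Summary fractions of a pattern table.

    Returns a dict with ``marked_any`` (fraction of all orthologs marked in
    >=1 species), ``concordant`` / ``single_species`` / ``three_species``
    (fractions of the marked set), and ``sister_pair_share`` (among
    two-species patterns, fraction marked in the sister pair). Empty
    denominators yield ``None``, never 0.
    """
    total = table.total
    marked = {k: v for k, v in table.counts.items() if k != "none"}
    n_marked = sum(marked.values())
    by_cat: dict[str, int] = {"single": 0, "double": 0, "triple": 0}
    for key, n in marked.items():
        by_cat[_pattern_category(key, table)] += n
    sister_key = "-".join(sp for sp in table.species if sp in set(sister_pair))
    out: dict[str, Optional[float]] = {
        "n_total": total,
        "n_marked": n_marked,
        "marked_any": n_marked / total if total else None,
    }
    if n_marked == 0:
        out.update(
            concordant=None, single_species=None, three_species=None,
            sister_pair_share=None,
        )
        return out
    out["concordant"] = (by_cat["double"] + by_cat["triple"]) / n_marked
    out["single_species"] = by_cat["single"] / n_marked
    out["three_species"] = by_cat["triple"] / n_marked
    out["sister_pair_share"] = (
        marked.get(sister_key, 0) / by_cat["double"] if by_cat["double"] else None
    )
    return out


def class_counts(
    table: PatternTable,
    reference_species: str = "Aal",
    sister_species: Sequence[str] = ("Ath", "Aly"),
) -> dict[str, int]:
    """Plastic / constrained / unmarked counts from a pattern table."""
    out = {PLASTIC: 0, CONSTRAINED: 0, UNMARKED: 0}
    for key, n in table.counts.items():
        marked = frozenset() if key == "none" else frozenset(key.split("-"))
        label = classify_h3k27(
            MarkingPattern(marked, table.species), reference_species, sister_species
        )
        out[label] += n
    return out


def expected_pattern_fractions(table: PatternTable) -> PatternNull:
    """Independence null for pattern frequencies.

    Per-species marginal marking probabilities are computed among orthologs
    marked in >=1 species; the 8 independent-pattern probabilities are then
    renormalized by 1 - P(no species marked), so the expected fractions over
    the 7 non-empty patterns sum to 1.
    """
    marked = {k: v for k, v in table.counts.items() if k != "none"}
    n_marked = sum(marked.values())
    if n_marked == 0:
        raise ValidationError("cannot build a null from zero marked orthologs")
    marginals = {}
    for sp in table.species:
        marginals[sp] = (
            sum(n for key, n in marked.items() if sp in key.split("-")) / n_marked
        )
    return null_from_marginals(marginals, table.species)


def null_from_marginals(
    marginals: Mapping[str, float], species: Sequence[str] = DEFAULT_SPECIES
) -> PatternNull:
    """Independence null over the 7 non-empty patterns from explicit
    per-species marking probabilities, conditioned on >=1 species marked."""
    species = tuple(species)
    raw = {}
    for bits in product([True, False], repeat=len(species)):
        sub = frozenset(sp for sp, b in zip(species, bits) if b)
        p = 1.0
        for sp in species:
            p *= marginals[sp] if sp in sub else 1 - marginals[sp]
        raw[MarkingPattern(sub, species).key] = p
    p_none = raw.pop("none")
    denom = 1.0 - p_none
    if denom <= 0:
        raise ValidationError("all marginals zero: null undefined")
    per_pattern = {key: p / denom for key, p in raw.items()}
    expected = dict(per_pattern)
    # category-level aggregates, the quantities quoted downstream
    for cat, n_species in (("single", 1), ("double", 2), ("triple", 3)):
        expected[cat] = sum(
            p for key, p in per_pattern.items() if key.count("-") + 1 == n_species
        )
    return PatternNull(dict(marginals), expected)


def cross_clade_fraction(
    table: PatternTable,
    pattern_category: str,
    reference_species: str = "Aal",
    sister_species: Sequence[str] = ("Ath", "Aly"),
) -> Optional[float]:
    """Among orthologs in a pattern category, the fraction whose distant-clade
    (outgroup) counterpart also carries the mark.

    ``pattern_category`` may be a pattern key (``Ath-Aly-Aal``), a cardinality
    category (``single``/``double``/``triple``), or a class label
    (``plastic``/``constrained``). Returns None for an empty category.
    """
    def in_category(key: str) -> bool:
        if key == "none":
            return False
        if pattern_category == key:
            return True
        n = key.count("-") + 1
        if pattern_category in {"single", "double", "triple"}:
            return {1: "single", 2: "double", 3: "triple"}[n] == pattern_category
        if pattern_category in {PLASTIC, CONSTRAINED}:
            label = classify_h3k27(
                MarkingPattern(frozenset(key.split("-")), table.species),
                reference_species,
                sister_species,
            )
            return label == pattern_category
        return False

    members = sum(n for key, n in table.counts.items() if in_category(key))
    if members == 0:
        return None
    hits = sum(n for key, n in table.outgroup_counts.items() if in_category(key))
    return hits / members


def marking_frequency(
    records: Iterable[OrthologRecord], species: str, mark: str = "H3K27me3"
) -> Optional[float]:
    """Fraction of records carrying the mark in one species (NA-aware:
    records where the gene is absent do not enter the denominator)."""
    n = k = 0
    for rec in records:
        flag = rec.is_marked(species, mark)
        if flag is None:
            continue
        n += 1
        k += int(flag)
    return k / n if n else None


def species_restriction_fraction(
    records: Sequence[OrthologRecord],
    dup_species: Mapping[str, frozenset[str]],
    mark: str = "H3K27me3",
    species: Sequence[str] = DEFAULT_SPECIES,
) -> Optional[float]:
    """Among records marked in >=1 species, the fraction whose full marked
    set is contained in the species that hold the record's duplicates.

    ``dup_species`` maps protogene_id -> set of duplicate-containing species.
    """
    n = k = 0
    for rec in records:
        marked = frozenset(
            sp for sp in species if rec.is_marked(sp, mark) is True
        )
        if not marked:
            continue
        n += 1
        if marked <= dup_species.get(rec.protogene_id, frozenset()):
            k += 1
    return k / n if n else None
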