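"""Inferential statistics around the marking classifications.

Two-way ANOVA with omega-squared effect sizes, per-synteny-block exact
binomial enrichment tests, Fisher exact co-occurrence tests, and
duplicate-pair class-concordance chi-square tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class AnovaResult:
    """Type II two-way ANOVA table with omega-squared effect sizes."""

    table: pd.DataFrame  # index: effect names + Residual; cols: sum_sq, df, F, p
    omega_squared: dict[str, float]

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass(frozen=True)
class BlockEnrichment:
    block_id: str
    n_genes: int
    n_class: int
    p0: float
    p_value: float
    enriched: bool


@dataclass
class PairConcordance:
    n_pairs: int
    observed: dict[str, float]  # both_plastic, both_constrained, other
    expected: dict[str, float]
    chi_square: float
    p_value: float


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def twoway_anova(
    similarity: Sequence[float],
    concordance_factor: Sequence,
    uniqueness_factor: Sequence,
    interaction: bool = False,
) -> AnovaResult:
    """Two-way ANOVA of a response on two categorical factors.

    Uses Type II sums of squares (the groups here are always unbalanced) via
    OLS on dummy-coded factors. Omega squared per effect is
    (SS_eff - df_eff * MS_err) / (SS_total + MS_err), clipped at 0.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(similarity, dtype=float),
            "A": pd.Categorical(concordance_factor),
            "B": pd.Categorical(uniqueness_factor),
        }
    )
    for fac in ("A", "B"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac} has fewer than 2 levels")
    if interaction:
        cells = df.groupby(["A", "B"], observed=False).size()
        if (cells == 0).any():
            raise ValueError("empty factor cell: interaction model not estimable")
        formula = "y ~ C(A) + C(B) + C(A):C(B)"
    else:
        formula = "y ~ C(A) + C(B)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(A)": "concordance",
            "C(B)": "uniqueness",
            "C(A):C(B)": "interaction",
        }
    )
    ss_total = float(((df["y"] - df["y"].mean()) ** 2).sum())
    ms_err = float(table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"])
    omega = {}
    for eff in table.index:
        if eff == "Residual":
            continue
        ss, dof = float(table.loc[eff, "sum_sq"]), float(table.loc[eff, "df"])
        omega[eff] = max(0.0, (ss - dof * ms_err) / (ss_total + ms_err))
    return AnovaResult(table, omega)


# ---------------------------------------------------------------------------
# Synteny-block binomial enrichment
# ---------------------------------------------------------------------------


def block_binomial_enrichment(
    blocks: Mapping[str, Sequence[str]],
    gene_classes: Mapping[str, str],
    class_label: str,
    alpha: float = ALPHA,
    p0: Optional[float] = None,
    bh_correct: bool = False,
) -> list[BlockEnrichment]:
    """One-sided exact binomial enrichment test per synteny block.

    For each block: trials = genes in the block, successes = genes whose
    class equals ``class_label``, expected success probability ``p0`` = the
    per-block class proportion averaged over all (non-empty) blocks unless
    given. A block is enriched iff its upper-tail exact p-value is < alpha
    (raw by default; ``bh_correct`` switches to Benjamini-Hochberg).
    """
    trials: dict[str, tuple[int, int]] = {}
    for block_id, genes in blocks.items():
        n = len(genes)
        if n == 0:
            warnings.warn(f"block {block_id} has no genes; skipped")
            continue
        k = sum(1 for g in genes if gene_classes.get(g) == class_label)
        trials[block_id] = (n, k)
    if not trials:
        return []
    if p0 is None:
        props = [k / n for n, k in trials.values()]
        p0 = float(np.mean(props))
    if not 0 < p0 < 1:
        raise ValueError(f"expected success probability p0={p0} outside (0, 1)")
    results = []
    pvals = []
    for block_id, (n, k) in trials.items():
        p = float(sps.binomtest(k, n, p0, alternative="greater").pvalue)
        pvals.append(p)
        results.append(BlockEnrichment(block_id, n, k, p0, p, p < alpha))
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        results = [
            BlockEnrichment(r.block_id, r.n_genes, r.n_class, r.p0, float(pa), bool(rej))
            for r, pa, rej in zip(results, p_adj, reject)
        ]
    return results


def block_categories(
    blocks: Mapping[str, Sequence[str]],
    gene_classes: Mapping[str, str],
    plastic_label: str = "plastic",
    constrained_label: str = "constrained",
    alpha: float = ALPHA,
) -> dict[str, str]:
    """Per-block category from two one-sided enrichment tests:
    plastic_enriched / constrained_enriched / not_enriched.

    A block significant for both classes is assigned the class with the
    smaller p-value. A class absent from every block (degenerate p0 = 0)
    enriches nothing.
    """
    def run(label):
        try:
            return {
                r.block_id: r
                for r in block_binomial_enrichment(blocks, gene_classes, label, alpha)
            }
        except ValueError:
            return {}

    enr_p = run(plastic_label)
    enr_c = run(constrained_label)
    out = {}
    for block_id in blocks:
        if not blocks[block_id]:
            continue
        rp, rc = enr_p.get(block_id), enr_c.get(block_id)
        p_enr = rp is not None and rp.enriched
        c_enr = rc is not None and rc.enriched
        if p_enr and (not c_enr or rp.p_value <= rc.p_value):
            out[block_id] = "plastic_enriched"
        elif c_enr:
            out[block_id] = "constrained_enriched"
        else:
            out[block_id] = "not_enriched"
    return out


# ---------------------------------------------------------------------------
# Fisher / pair concordance
# ---------------------------------------------------------------------------


def fisher_cooccurrence(table2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    Returns (sample odds ratio, exact two-sided p). A table with a zero
    margin is uninformative: p = 1.
    """
    t = np.asarray(table2x2, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def ohnolog_pair_concordance(
    pairs: Sequence[tuple[str, str]],
    classes: Mapping[str, str],
    class_fractions: Mapping[str, float],
    plastic_label: str = "plastic",
    constrained_label: str = "constrained",
) -> PairConcordance:
    """Do duplicate pairs share a marking class more often than chance?

    Observed: fraction of pairs with both members plastic / both
    constrained. Expected under independence: the squared class fraction
    (``class_fractions`` taken over the base gene population). Chi-square
    goodness of fit over {both-plastic, both-constrained, other}.
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    n = len(pairs)
    both_p = sum(
        1 for a, b in pairs
        if classes.get(a) == plastic_label and classes.get(b) == plastic_label
    )
    both_c = sum(
        1 for a, b in pairs
        if classes.get(a) == constrained_label and classes.get(b) == constrained_label
    )
    observed = {
        "both_plastic": both_p / n,
        "both_constrained": both_c / n,
        "other": (n - both_p - both_c) / n,
    }
    ep = class_fractions[plastic_label] ** 2
    ec = class_fractions[constrained_label] ** 2
    expected = {"both_plastic": ep, "both_constrained": ec, "other": 1 - ep - ec}
    f_obs = np.array([both_p, both_c, n - both_p - both_c], dtype=float)
    f_exp = np.array([ep, ec, 1 - ep - ec]) * n
    chi2, p = sps.chisquare(f_obs, f_exp)
    return PairConcordance(n, observed, expected, float(chi2), float(p))
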