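"""Enrichment testing: Fisher's exact QTL-trait enrichment and binomial
term overrepresentation, both with Benjamini-Hochberg FDR correction.

The QTL mode asks, trait by trait, whether that trait's QTL records are
overlapped by CNVRs more often than the QTL of all other traits: a 2x2
table (trait overlapped, trait not overlapped, others overlapped,
others not overlapped) tested two-sided. The table construction follows
the convention of counting QTL records, and the BH family is every
trait with at least one overlapped QTL in the run.

The binomial mode is the classic term-overrepresentation test on gene
sets: for a term with reference probability p0 = |term genes| /
|universe| and a study set of n genes of which k hit the term, the
one-sided p-value is P(X >= k) for X ~ Binomial(n, p0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "fisher_exact_two_sided",
    "bh_adjust",
    "qtl_enrichment",
    "binomial_overrep",
    "null_qtl_significance_fraction",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's test outcome.

    Fisher mode fills the 2x2 counts (a, b, c, d) and the odds ratio;
    binomial mode fills (k, n, p0). ``odds_ratio`` is (a*d)/(b*c),
    infinite when b*c == 0 with a*d > 0, NaN when both are 0.
    """

    label: str
    p: float
    p_adj: float
    significant: bool
    a: Optional[int] = None
    b: Optional[int] = None
    c: Optional[int] = None
    d: Optional[int] = None
    k: Optional[int] = None
    n: Optional[int] = None
    p0: Optional[float] = None
    odds_ratio: Optional[float] = None


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Two-sidedness follows the standard "probability mass <= observed"
    rule: sum hypergeometric probabilities, at the observed margins, of
    every table no more likely than the observed one.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError(f"counts must be non-negative, got {(a, b, c, d)}")
    if a + b + c + d == 0:
        raise ValueError("degenerate 2x2 table: all margins are zero")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher's exact p for [[a, b], [c, d]]."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError(f"counts must be non-negative, got {(a, b, c, d)}")
    if a + b + c + d == 0:
        raise ValueError("degenerate 2x2 table: all margins are zero")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p(i) by m/i, enforce monotone
    non-decreasing from the largest rank down, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def qtl_enrichment(
    overlapped_qtl_ids: set[str],
    qtl: pd.DataFrame,
    *,
    alpha: float = 0.05,
    one_sided: bool = False,
) -> pd.DataFrame:
    """Per-trait Fisher enrichment of CNVR-overlapped QTL.

    Parameters
    ----------
    overlapped_qtl_ids
        Ids of QTL records overlapped by >= 1 CNVR (e.g. the
        ``feature_id`` column of an annotation overlap table).
    qtl
        QTL track as a DataFrame with columns ``feature_id`` and
        ``label`` (the trait name); one row per QTL record.
    alpha
        Significance level applied to BH-adjusted p-values.
    one_sided
        Test "greater" enrichment only instead of the default
        two-sided test.

    Returns a table with one row per trait having >= 1 overlapped QTL
    (that is the BH family), sorted by overlap count (desc) then
    adjusted p (asc).
    """
    if qtl.empty:
        raise ValueError("QTL track is empty")
    total = len(qtl)
    total_overlapped = int(qtl["feature_id"].isin(overlapped_qtl_ids).sum())
    test = fisher_exact_one_sided if one_sided else fisher_exact_two_sided

    rows = []
    for trait, grp in qtl.groupby("label", sort=True):
        n_trait = len(grp)
        a = int(grp["feature_id"].isin(overlapped_qtl_ids).sum())
        if a == 0:
            continue  # traits with no overlapped QTL are outside the tested family
        b = n_trait - a
        c = total_overlapped - a
        d = (total - n_trait) - c
        rows.append(
            {
                "label": trait,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "n_qtl": n_trait,
                "odds_ratio": _odds_ratio(a, b, c, d),
                "p": test(a, b, c, d),
            }
        )
    out = pd.DataFrame(
        rows, columns=["label", "a", "b", "c", "d", "n_qtl", "odds_ratio", "p"]
    )
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(
        ["a", "p_adj", "label"], ascending=[False, True, True]
    ).reset_index(drop=True)


def binomial_overrep(
    study: set[str],
    terms: Mapping[str, set[str]],
    universe: set[str],
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided binomial overrepresentation of annotation terms in a
    study gene set, BH-corrected across terms with >= 1 study hit.

    ``p0`` for each term is its share of the universe; the p-value is
    the upper binomial tail P(X >= k) at n = |study|.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    n = len(study)
    rows = []
    for term, genes in sorted(terms.items()):
        if not genes <= universe:
            raise ValueError(f"term {term!r}: genes outside the universe")
        k = len(study & genes)
        if k == 0:
            continue
        p0 = len(genes) / len(universe)
        p = float(sps.binom.sf(k - 1, n, p0))  # P(X >= k)
        rows.append({"label": term, "k": k, "n": n, "p0": p0, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["label", "k", "n", "p0", "p"])
    if out.empty:
        out["p_adj"] = []
        out["significant"] = []
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out.sort_values(["p_adj", "label"]).reset_index(drop=True)


def null_qtl_significance_fraction(
    rng: np.random.Generator,
    *,
    n_traits: int = 40,
    qtl_per_trait: tuple[int, int] = (5, 30),
    overlap_prob: float = 0.3,
    alpha: float = 0.05,
) -> float:
    """Fraction of traits flagged significant on one null replicate.

    CNVR overlap is assigned to QTL records uniformly at random with no
    trait effect, so any significant trait is a false discovery; with
    BH control the expected fraction stays at or below alpha. Used as a
    type-I error control experiment.
    """
    rows = []
    qid = 0
    for t in range(n_traits):
        n_q = int(rng.integers(qtl_per_trait[0], qtl_per_trait[1] + 1))
        for _ in range(n_q):
            rows.append({"feature_id": f"Q{qid}", "label": f"trait{t:03d}"})
            qid += 1
    qtl = pd.DataFrame(rows)
    hit = rng.random(len(qtl)) < overlap_prob
    overlapped = set(qtl.loc[hit, "feature_id"])
    res = qtl_enrichment(overlapped, qtl, alpha=alpha)
    if res.empty:
        return 0.0
    # traits never overlapped are untested; they cannot be false discoveries
    return float(res["significant"].sum()) / n_traits
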