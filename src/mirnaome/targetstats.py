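"""Set-level statistics over target-prediction score tables.

Score tables are tidy DataFrames with columns ``gene``, ``predictor``,
``score`` (in [0, 1]), as emitted by affinity-score predictors; this module
filters them to high-confidence target sets, computes Venn overlaps and
target-multiplicity histograms, correlates scores between predictors over
their common genes, and runs hypergeometric over-representation of a query
gene list against user-supplied gene sets.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "validate_score_table",
    "filter_targets",
    "overlap_counts",
    "multiplicity_histogram",
    "score_correlation",
    "enrich_hypergeometric",
]


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene", "predictor", "score"):
        if col not in table.columns:
            raise ValueError(f"score table lacks column {col!r}")
    if ((table["score"] < 0) | (table["score"] > 1)).any():
        raise ValueError("scores outside [0, 1]")
    if table.duplicated(["gene", "predictor"]).any():
        raise ValueError("duplicate (gene, predictor) rows")
    return table


def filter_targets(
    table: pd.DataFrame, min_score: float = 0.8, inclusive: bool = False
) -> dict[str, set[str]]:
    """High-confidence target genes per predictor.

    Keeps rows with ``score > min_score`` (strictly above the threshold;
    ``inclusive=True`` switches to >=). Raising ``min_score`` never adds a
    gene. Every predictor in the table appears in the result, possibly with
    an empty set.
    """
    validate_score_table(table)
    keep = table["score"] >= min_score if inclusive else table["score"] > min_score
    out: dict[str, set[str]] = {p: set() for p in table["predictor"].unique()}
    for p, sub in table.loc[keep].groupby("predictor"):
        out[p] = set(sub["gene"])
    return out


def overlap_counts(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Disjoint Venn region counts for 2 or 3 named sets.

    Keys are sorted tuples of the set names whose exclusive intersection the
    region is; values sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("overlap_counts handles 2 or 3 sets")
    names = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(
                *(sets[n] for n in names if n not in combo), set()
            )
            regions[combo] = len(inside - outside)
    return regions


def multiplicity_histogram(sets: dict[str, set[str]]) -> pd.Series:
    """How many genes are targeted by exactly k of the given predictors.

    Indexed by multiplicity k >= 1; values sum to the union size.
    """
    union: dict[str, int] = {}
    for members in sets.values():
        for g in members:
            union[g] = union.get(g, 0) + 1
    hist = pd.Series(union, dtype=int).value_counts().sort_index()
    hist.index.name = "n_predictors"
    return hist


def score_correlation(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    method: str = "pearson",
    min_common: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation of target scores over genes scored by both
    predictors.

    Genes scored by only one predictor are excluded (no zero-filling, which
    would fabricate agreement). Pairs with fewer than ``min_common`` common
    genes are undefined (NaN). Returns ``(correlation, n_common)`` matrices.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    validate_score_table(table)
    known = set(table["predictor"].unique())
    if predictors is None:
        predictors = sorted(known)
    unknown = set(predictors) - known
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    wide = table.pivot(index="gene", columns="predictor", values="score")
    corr = pd.DataFrame(np.nan, index=predictors, columns=predictors)
    ncom = pd.DataFrame(0, index=predictors, columns=predictors, dtype=int)
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for a in predictors:
        for b in predictors:
            both = wide[[a, b]].dropna()
            ncom.loc[a, b] = len(both)
            if a == b:
                corr.loc[a, b] = 1.0
            elif len(both) >= min_common:
                corr.loc[a, b] = fn(both[a], both[b])[0]
    return corr, ncom


def enrich_hypergeometric(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH correction.

    For each gene set of size K in a universe of size N, with a query of
    size n overlapping it in k genes, p = P(X >= k) for
    X ~ Hypergeom(N, K, n). ``significant`` flags padj <= alpha.
    """
    query = set(query)
    bad = query - set(universe)
    if bad:
        raise ValueError(f"query genes outside universe: {sorted(bad)}")
    for name, members in gene_sets.items():
        out = set(members) - set(universe)
        if out:
            raise ValueError(f"gene set {name}: members outside universe: {sorted(out)}")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name])
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"gene_set": name, "k": k, "K": K, "n": n, "N": N, "pvalue": p})
    result = pd.DataFrame(rows).set_index("gene_set")
    if len(result):
        result["padj"] = multipletests(result["pvalue"], method="fdr_bh")[1]
        result["significant"] = result["padj"] <= alpha
    return result
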