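"""Count-matrix quantification and differential expression.

Count matrices are pandas DataFrames (features x samples, non-negative
integers); the sample design is a DataFrame indexed by sample with a
``population`` column (and optionally ``replicate``).

Differential expression is a transparent negative-binomial Wald pipeline:
median-of-ratios size factors, method-of-moments dispersion with a common-
dispersion floor, a log2 fold change with pseudocount, a delta-method
standard error and a two-sided normal p-value with Benjamini-Hochberg
adjustment.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "validate_counts",
    "make_design",
    "filter_expressed",
    "cpm_normalize",
    "log_cpm",
    "estimate_size_factors",
    "differential_expression",
    "volcano_classify",
    "sample_distances",
    "pca_project",
]

LN2 = np.log(2.0)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.index.has_duplicates:
        raise ValueError("duplicate feature names")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample names")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts


def make_design(samples: list[str], populations: list[str]) -> pd.DataFrame:
    """Build a design table from parallel sample/population lists."""
    df = pd.DataFrame({"population": populations}, index=pd.Index(samples, name="sample"))
    df["replicate"] = df.groupby("population").cumcount() + 1
    return df


def _check_design(counts: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    missing = set(counts.columns) - set(design.index)
    if missing:
        raise ValueError(f"samples missing from design: {sorted(missing)}")
    return design.loc[counts.columns, "population"]


def filter_expressed(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_reads: float = 5,
    rule: str = "strict",
) -> pd.DataFrame:
    """Expression filter: keep features adequately covered in some population.

    ``strict``: some population has every replicate >= ``min_reads``.
    ``mean_only``: some population has a replicate mean >= ``min_reads``.
    The strict feature set is always a subset of the mean_only one.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    if rule not in ("strict", "mean_only"):
        raise ValueError(f"unknown rule {rule!r}")
    pops = _check_design(validate_counts(counts), design)
    keep = np.zeros(len(counts), dtype=bool)
    for pop in pops.unique():
        sub = counts.loc[:, pops[pops == pop].index]
        if rule == "strict":
            keep |= (sub >= min_reads).all(axis=1).to_numpy()
        else:
            keep |= (sub.mean(axis=1) >= min_reads).to_numpy()
    return counts.loc[keep]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled to a library size of 1e6."""
    validate_counts(counts)
    totals = counts.sum(axis=0).astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"all-zero samples: {list(counts.columns[zero])}")
        totals[zero] = 1.0
    return counts / totals * 1e6


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1), the transform used for distances, PCA and profiles."""
    return np.log2(cpm_normalize(counts) + 1.0)


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses features with nonzero counts in every sample as the pseudo-reference;
    raises if none exists (consider adding a pseudocount or using CPM).
    """
    validate_counts(counts)
    K = counts.to_numpy(float)
    ok = (K > 0).all(axis=1)
    if not ok.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; "
            "add a pseudocount or normalize by CPM instead"
        )
    logK = np.log(K[ok])
    ratios = logK - logK.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(ratios, axis=0))
    sf /= np.exp(np.log(sf).mean())
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _pooled_dispersion(
    qA: np.ndarray, qB: np.ndarray, min_dispersion: float, mode: str
) -> np.ndarray:
    """Per-feature NB dispersion by method of moments on normalized counts.

    The raw estimate uses the within-group pooled variance. With
    ``mode="max-common"`` (default) each feature's dispersion is floored at
    the median raw estimate across features: with 2-3 replicates per group
    the per-feature moment estimate is so noisy that the plain Wald test is
    badly anticonservative, and flooring at the common dispersion restores
    calibration (the classic conservative rule of the DESeq lineage).
    ``mode="per-feature"`` keeps the raw estimate.
    """
    nA, nB = qA.shape[1], qB.shape[1]
    mA, mB = qA.mean(axis=1), qB.mean(axis=1)
    vA = qA.var(axis=1, ddof=1)
    vB = qB.var(axis=1, ddof=1)
    s2 = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    mg = (nA * mA + nB * mB) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - mg) / mg**2
    raw = np.where(np.isfinite(raw), raw, min_dispersion)
    alpha = np.maximum(raw, min_dispersion)
    if mode == "max-common":
        common = max(float(np.median(raw[mg > 0])), min_dispersion)
        alpha = np.maximum(alpha, common)
    elif mode != "per-feature":
        raise ValueError(f"unknown dispersion_mode {mode!r}")
    return alpha


def differential_expression(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    pseudocount: float = 0.5,
    min_dispersion: float = 1e-8,
    dispersion_mode: str = "max-common",
) -> pd.DataFrame:
    """Negative-binomial Wald test of population B vs A.

    Counts are normalized by median-of-ratios size factors; per-feature NB
    dispersion comes from within-group moments (see ``_pooled_dispersion``);
    ``log2FC = log2((meanB + pc) / (meanA + pc))``; the Wald statistic divides
    it by a delta-method standard error and is referred to a standard normal,
    with BH adjustment across tested features.

    Returns a DataFrame with columns baseMeanA, baseMeanB, log2FC, se, stat,
    pvalue, padj.
    """
    pops = _check_design(validate_counts(counts), design)
    cols_a = pops[pops == pop_a].index
    cols_b = pops[pops == pop_b].index
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each compared population needs >=2 replicates")
    sub = counts.loc[:, list(cols_a) + list(cols_b)]
    sf = estimate_size_factors(sub)
    q = sub.to_numpy(float) / sf.to_numpy()
    qA, qB = q[:, : len(cols_a)], q[:, len(cols_a) :]
    nA, nB = qA.shape[1], qB.shape[1]
    mA, mB = qA.mean(axis=1), qB.mean(axis=1)
    alpha = _pooled_dispersion(qA, qB, min_dispersion, dispersion_mode)

    lfc = np.log2((mB + pseudocount) / (mA + pseudocount))
    # delta method: Var(log2(mean+pc)) ~ Var(mean) / ((mean+pc) ln2)^2,
    # with the NB variance mu + alpha mu^2 for each replicate
    varA = (mA + alpha * mA**2) / nA / ((mA + pseudocount) ** 2 * LN2**2)
    varB = (mB + alpha * mB**2) / nB / ((mB + pseudocount) ** 2 * LN2**2)
    se = np.sqrt(varA + varB)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.norm.sf(np.abs(z))
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "baseMeanA": mA,
            "baseMeanB": mB,
            "log2FC": lfc,
            "se": se,
            "stat": z,
            "pvalue": p,
            "padj": padj,
        },
        index=counts.index,
    )


def volcano_classify(
    de: pd.DataFrame,
    lfc_cut: float = 3.0,
    p_cut: float = 0.01,
    use: str = "p",
) -> pd.Series:
    """Label features up/down/ns at |log2FC| >= lfc_cut and p <= p_cut."""
    if use not in ("p", "padj"):
        raise ValueError(f"unknown p-value column mode {use!r}")
    p = de["pvalue"] if use == "p" else de["padj"]
    sig = p <= p_cut
    label = pd.Series("ns", index=de.index, name="label")
    label[sig & (de["log2FC"] >= lfc_cut)] = "up"
    label[sig & (de["log2FC"] <= -lfc_cut)] = "down"
    return label


def sample_distances(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between samples over (log-scale) feature values."""
    d = squareform(pdist(log_matrix.to_numpy(float).T, metric="euclidean"))
    return pd.DataFrame(d, index=log_matrix.columns, columns=log_matrix.columns)


def pca_project(
    matrix: pd.DataFrame, n_components: int = 2, scale: bool = False
):
    """PCA of samples in feature space (features x samples input).

    Returns ``(scores, loadings, explained_variance_ratio)``: scores are
    samples x components, loadings features x components with orthonormal
    columns. ``scale=True`` standardizes each feature first.
    """
    X = matrix.to_numpy(float).T  # samples x features
    n_samples, n_features = X.shape
    if n_components > min(n_samples - 1, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, features)="
            f"{min(n_samples - 1, n_features)}"
        )
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.columns, columns=pcs),
        pd.DataFrame(pca.components_.T, index=matrix.index, columns=pcs),
        pd.Series(pca.explained_variance_ratio_, index=pcs, name="explained"),
    )
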