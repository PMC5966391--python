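"""Group-level expression analysis and miRNAome selection.

miRNAs act in concert: members of a genomic cluster are co-transcribed and
members of a seed family hit overlapping target sets. This module aggregates
per-miRNA expression to those groups, links clusters to the families their
members belong to, ranks groups for word-cloud display, and assembles the
three-tier cardiac-style miRNAome report (top expressed / up versus every
other population / exclusively expressed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable

import pandas as pd

from .refmodel import GenomicCluster, SeedFamily
from .quant import (
    cpm_normalize,
    differential_expression,
    filter_expressed,
    volcano_classify,
)

__all__ = [
    "GroupExpression",
    "ClusterFamilyLink",
    "MiRNAomeReport",
    "aggregate_by_group",
    "cluster_family_links",
    "rank_for_wordcloud",
    "select_mirnaome",
]


@dataclass
class GroupExpression:
    values: pd.DataFrame  # groups x samples, summed CPM
    members: dict[str, list[str]]
    ungrouped: pd.DataFrame  # features in no group, original values


@dataclass
class ClusterFamilyLink:
    cluster_name: str
    families: frozenset[str]

    @property
    def link_type(self) -> str:
        return "single_family" if len(self.families) == 1 else "multi_family"


@dataclass
class MiRNAomeReport:
    """Three-tier selection, each tier ranked by target-population mean CPM."""

    top_expressed: pd.DataFrame
    de_vs_all: pd.DataFrame
    unique: pd.DataFrame
    target_population: str = ""


def _as_partition(grouping) -> dict[str, list[str]]:
    if isinstance(grouping, dict):
        return {g: list(m) for g, m in grouping.items()}
    out: dict[str, list[str]] = {}
    for g in grouping:
        if isinstance(g, GenomicCluster):
            out[g.name] = list(g.members)
        elif isinstance(g, SeedFamily):
            out[g.family_id] = list(g.members)
        else:
            raise TypeError(f"cannot interpret group {g!r}")
    return out


def aggregate_by_group(cpm: pd.DataFrame, grouping) -> GroupExpression:
    """Per-sample sum of member expression for each group.

    ``grouping`` is a dict group -> members or a list of clusters/families
    forming a partition (a feature may appear in at most one group). Members
    absent from the matrix contribute 0 with a warning; features in no group
    are returned separately so column totals are conserved.
    """
    part = _as_partition(grouping)
    seen: set[str] = set()
    for g, members in part.items():
        dup = seen & set(members)
        if dup:
            raise ValueError(f"features in more than one group: {sorted(dup)}")
        seen |= set(members)
    rows = {}
    for g, members in part.items():
        present = [m for m in members if m in cpm.index]
        absent = set(members) - set(present)
        if absent:
            warnings.warn(f"group {g}: members not in matrix: {sorted(absent)}")
        if not members:
            warnings.warn(f"group {g}: empty group")
        rows[g] = cpm.loc[present].sum(axis=0) if present else pd.Series(
            0.0, index=cpm.columns
        )
    values = pd.DataFrame(rows).T
    values.index.name = "group"
    if values.empty:
        values = pd.DataFrame(columns=cpm.columns)
    ungrouped = cpm.loc[[f for f in cpm.index if f not in seen]]
    return GroupExpression(values=values, members=part, ungrouped=ungrouped)


def cluster_family_links(
    clusters: Iterable[GenomicCluster], families: Iterable[SeedFamily]
) -> list[ClusterFamilyLink]:
    """For each genomic cluster, the set of seed families of its members."""
    fam_of: dict[str, str] = {}
    for fam in families:
        for m in fam.members:
            fam_of[m] = fam.family_id
    return [
        ClusterFamilyLink(
            cluster_name=c.name,
            families=frozenset(fam_of[m] for m in c.members if m in fam_of),
        )
        for c in clusters
    ]


def rank_for_wordcloud(
    group_values: pd.DataFrame, population: str, design: pd.DataFrame
) -> pd.DataFrame:
    """Rank groups by population-mean CPM, weights normalized to max 1."""
    pops = design["population"]
    cols = pops[pops == population].index.intersection(group_values.columns)
    if len(cols) == 0:
        raise ValueError(f"unknown population {population!r}")
    means = group_values.loc[:, cols].mean(axis=1)
    top = means.max()
    weights = means / top if top > 0 else means * 0.0
    out = pd.DataFrame({"mean_cpm": means, "weight": weights})
    out = out.sort_values(["weight", "mean_cpm"], ascending=False, kind="stable")
    # deterministic: weight desc, then name
    out["_name"] = out.index
    out = out.sort_values(["weight", "_name"], ascending=[False, True],
                          kind="stable").drop(columns="_name")
    return out


def select_mirnaome(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    target_population: str,
    de_runner: Callable = differential_expression,
    top_n: int = 10,
    lfc_cut: float = 3.0,
    p_cut: float = 0.01,
    min_reads: float = 5,
    min_mean: float = 5.0,
) -> MiRNAomeReport:
    """Three-tier miRNAome of a target cell population.

    * ``top_expressed`` — the ``top_n`` expressed features (standard
      expression filter) by target-population mean CPM.
    * ``de_vs_all`` — features labeled *up* (log2FC >= ``lfc_cut``,
      p <= ``p_cut``) in the target against **every** other population
      separately.
    * ``unique`` — features with zero raw counts in every sample of every
      other population and a target mean CPM of at least ``min_mean``.
    """
    pops = design.loc[counts.columns, "population"]
    others = [p for p in pops.unique() if p != target_population]
    if target_population not in set(pops):
        raise ValueError(f"unknown target population {target_population!r}")
    if not others:
        raise ValueError("need at least 2 populations")
    cpm = cpm_normalize(counts)
    target_cols = pops[pops == target_population].index
    target_mean = cpm.loc[:, target_cols].mean(axis=1)

    expressed = filter_expressed(counts, design, min_reads=min_reads).index
    top = (
        target_mean.loc[expressed]
        .sort_values(ascending=False)
        .head(top_n)
        .rename("mean_cpm")
        .to_frame()
    )

    up_everywhere = pd.Series(True, index=counts.index)
    evidence = {}
    for other in others:
        de = de_runner(counts, design, other, target_population)
        labels = volcano_classify(de, lfc_cut=lfc_cut, p_cut=p_cut)
        up_everywhere &= labels == "up"
        evidence[f"log2FC_vs_{other}"] = de["log2FC"]
        evidence[f"p_vs_{other}"] = de["pvalue"]
    de_vs_all = pd.DataFrame({"mean_cpm": target_mean, **evidence})
    de_vs_all = de_vs_all.loc[up_everywhere].sort_values(
        "mean_cpm", ascending=False
    )

    other_cols = pops[pops != target_population].index
    zero_outside = (counts.loc[:, other_cols] == 0).all(axis=1)
    unique = (
        target_mean.loc[zero_outside & (target_mean >= min_mean)]
        .sort_values(ascending=False)
        .rename("mean_cpm")
        .to_frame()
    )
    return MiRNAomeReport(
        top_expressed=top,
        de_vs_all=de_vs_all,
        unique=unique,
        target_population=target_population,
    )
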