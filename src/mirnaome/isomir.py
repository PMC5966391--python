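"""isomiR / ADAR classification of collapsed small-RNA reads.

Each distinct read sequence is aligned against every mature miRNA embedded in
its hairpin, allowing end-shifts of up to ``max_shift`` bases on either side
(negative = trimmed relative to the canonical end, positive = added) and at
most ``max_sub`` internal substitutions. Bases added at an end are compared
against the flanking hairpin sequence: if they match it the addition is
*templated* (imprecise Drosha/Dicer cleavage); if not, it is *non-templated*
tailing by a nucleotidyl transferase and does not consume the substitution
budget. A-to-I editing by ADAR deaminases is read out as A>G substitutions at
reference-A positions of the mature.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .refmodel import ReferenceIndex, normalize_rna

__all__ = [
    "ReadRecord",
    "EndShift",
    "Substitution",
    "IsomiRCall",
    "AdarSite",
    "IsomiRTable",
    "classify_read",
    "call_isomirs",
    "isoform_class_counts",
    "end_position_summary",
    "substitution_spectrum",
    "detect_adar",
    "compare_adar_between_groups",
]

ISO_CLASSES = ("exact", "iso5", "iso3", "iso5_iso3")

MIN_READ_LEN = 16


@dataclass
class ReadRecord:
    """One collapsed read sequence with per-sample multiplicities."""

    read_id: str
    sequence: str
    count_per_sample: dict[str, int]

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        if any(c < 0 for c in self.count_per_sample.values()):
            raise ValueError(f"read {self.read_id}: negative count")
        if not any(self.count_per_sample.values()):
            raise ValueError(f"read {self.read_id}: all counts zero")

    @property
    def total(self) -> int:
        return sum(self.count_per_sample.values())


@dataclass(frozen=True)
class EndShift:
    """Signed end displacement: negative = trimmed, positive = added bases."""

    shift5: int
    shift3: int

    def __post_init__(self) -> None:
        for s in (self.shift5, self.shift3):
            if not -3 <= s <= 3:
                raise ValueError(f"end shift {s} outside [-3, 3]")


@dataclass(frozen=True)
class Substitution:
    """Single-base change at a 1-based canonical-mature position."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("substitution with ref == alt")


@dataclass
class IsomiRCall:
    mature_name: str
    shifts: EndShift
    substitutions: list[Substitution]
    added5_templated: bool | None  # None unless shift5 > 0
    added3_templated: bool | None
    read_id: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def iso_class(self) -> str:
        s5, s3 = self.shifts.shift5, self.shifts.shift3
        if s5 == 0 and s3 == 0:
            return "exact"
        if s5 != 0 and s3 != 0:
            return "iso5_iso3"
        return "iso5" if s5 != 0 else "iso3"


@dataclass
class AdarSite:
    """One A>G edited position of one mature, with per-sample read support."""

    mature_name: str
    position: int  # 1-based in the canonical mature
    edited_counts: dict[str, int]
    total_counts: dict[str, int]

    def fraction(self, sample: str) -> float:
        tot = self.total_counts.get(sample, 0)
        return self.edited_counts.get(sample, 0) / tot if tot else np.nan


@dataclass
class IsomiRTable:
    calls: list[IsomiRCall]
    unassigned: list[tuple[str, str]]  # (read_id, reason)
    samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            rows.append(
                {
                    "read_id": c.read_id,
                    "mature": c.mature_name,
                    "shift5": c.shifts.shift5,
                    "shift3": c.shifts.shift3,
                    "substitutions": ";".join(
                        f"{s.position}:{s.ref}>{s.alt}" for s in c.substitutions
                    ),
                    "added5_templated": c.added5_templated,
                    "added3_templated": c.added3_templated,
                    "iso_class": c.iso_class,
                    **{s: c.counts.get(s, 0) for s in self.samples},
                }
            )
        cols = [
            "read_id", "mature", "shift5", "shift3", "substitutions",
            "added5_templated", "added3_templated", "iso_class", *self.samples,
        ]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _mature_context(index: ReferenceIndex, k: int):
    out = []
    for name in sorted(index.matures):
        m = index.matures[name]
        up, down = index.context(name, k)
        out.append((name, m.sequence, up, down))
    return out


def _evaluate(read, mseq, up, down, s5, s3, max_sub):
    """Score one (mature, shift5, shift3) placement; None if over budget."""
    L = len(mseq)
    # canonical body positions covered by the read
    lo = max(0, -s5)
    hi = L - max(0, -s3)
    subs = []
    for p in range(lo, hi):
        rb = read[p + s5]
        if rb != mseq[p]:
            subs.append(Substitution(p + 1, mseq[p], rb))
            if len(subs) > max_sub:
                return None
    t5 = t3 = None
    if s5 > 0:
        added = read[:s5]
        t5 = len(up) >= s5 and added == up[-s5:]
    if s3 > 0:
        added = read[len(read) - s3 :]
        t3 = len(down) >= s3 and added == down[:s3]
    return subs, t5, t3


def classify_read(
    sequence: str,
    index: ReferenceIndex,
    max_shift: int = 3,
    max_sub: int = 1,
) -> IsomiRCall | str:
    """Classify one read sequence; returns an :class:`IsomiRCall` or an
    unassigned-reason string.

    Candidates are every (mature, shift5, shift3) placement whose implied
    length matches the read; the best valid one minimises
    ``|shift5| + |shift3| + #substitutions``, ties broken by fewer
    substitutions, then smaller ``|shift5|``, then mature name, then
    ``(shift5, shift3)`` lexicographically.
    """
    read = normalize_rna(sequence)
    if len(read) < MIN_READ_LEN:
        return f"read shorter than {MIN_READ_LEN} nt"
    best = None
    best_key = None
    for name, mseq, up, down in _mature_context(index, max_shift):
        total = len(read) - len(mseq)
        if total < -2 * max_shift or total > 2 * max_shift:
            continue
        for s5 in range(-max_shift, max_shift + 1):
            s3 = total - s5
            if not -max_shift <= s3 <= max_shift:
                continue
            res = _evaluate(read, mseq, up, down, s5, s3, max_sub)
            if res is None:
                continue
            subs, t5, t3 = res
            key = (abs(s5) + abs(s3) + len(subs), len(subs), abs(s5), name, s5, s3)
            if best_key is None or key < best_key:
                best_key = key
                best = IsomiRCall(
                    mature_name=name,
                    shifts=EndShift(s5, s3),
                    substitutions=subs,
                    added5_templated=t5,
                    added3_templated=t3,
                )
    if best is not None:
        return best
    # diagnose: would the read match under a wider end window?
    wide = max_shift + 3
    for name, mseq, up, down in _mature_context(index, max_shift):
        total = len(read) - len(mseq)
        for s5 in range(-wide, wide + 1):
            s3 = total - s5
            if not -wide <= s3 <= wide:
                continue
            if -max_shift <= s5 <= max_shift and -max_shift <= s3 <= max_shift:
                continue
            lo, hi = max(0, -s5), len(mseq) - max(0, -s3)
            if hi - lo < MIN_READ_LEN - 2 * wide:
                continue
            n_mm = sum(
                1 for p in range(lo, hi) if read[p + s5] != mseq[p]
            )
            if n_mm <= max_sub:
                return f"shift exceeds ±{max_shift}"
    return "no candidate within tolerance"


def call_isomirs(
    reads: list[ReadRecord],
    index: ReferenceIndex,
    max_shift: int = 3,
    max_sub: int = 1,
) -> IsomiRTable:
    """Batch classification; duplicate sequences are merged with summed counts."""
    merged: dict[str, ReadRecord] = {}
    for r in reads:
        if r.sequence in merged:
            warnings.warn(f"duplicate read sequence {r.read_id}; counts merged")
            keep = merged[r.sequence]
            for s, c in r.count_per_sample.items():
                keep.count_per_sample[s] = keep.count_per_sample.get(s, 0) + c
        else:
            merged[r.sequence] = ReadRecord(
                r.read_id, r.sequence, dict(r.count_per_sample)
            )
    samples = sorted({s for r in merged.values() for s in r.count_per_sample})
    calls: list[IsomiRCall] = []
    unassigned: list[tuple[str, str]] = []
    for r in merged.values():
        result = classify_read(r.sequence, index, max_shift, max_sub)
        if isinstance(result, str):
            unassigned.append((r.read_id, result))
        else:
            result.read_id = r.read_id
            result.counts = dict(r.count_per_sample)
            calls.append(result)
    return IsomiRTable(calls=calls, unassigned=unassigned, samples=samples)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _counts_frame(table: IsomiRTable) -> pd.DataFrame:
    data = {
        c.read_id: [c.counts.get(s, 0) for s in table.samples] for c in table.calls
    }
    return pd.DataFrame.from_dict(
        data, orient="index", columns=table.samples
    ).astype(int)


def isoform_class_counts(
    table: IsomiRTable,
    design: pd.DataFrame | None = None,
    min_reads: float = 5,
):
    """Distinct-sequence counts and summed expression per isomiR class.

    With a ``design`` (sample -> population), sequences are first filtered to
    those with a replicate-mean of at least ``min_reads`` in some population,
    matching the expression filter applied before the class breakdown.
    Returns ``(seq_counts, expression)``: a Series over the four classes and
    a classes x samples DataFrame.
    """
    keep = {c.read_id for c in table.calls}
    if design is not None and table.calls:
        from .quant import filter_expressed

        cf = _counts_frame(table)
        kept = filter_expressed(cf, design, min_reads=min_reads, rule="mean_only")
        keep = set(kept.index)
    seq_counts = pd.Series(0, index=list(ISO_CLASSES), dtype=int)
    expr = pd.DataFrame(0, index=list(ISO_CLASSES), columns=table.samples, dtype=int)
    for c in table.calls:
        if c.read_id not in keep:
            continue
        seq_counts[c.iso_class] += 1
        for s in table.samples:
            expr.loc[c.iso_class, s] += c.counts.get(s, 0)
    return seq_counts, expr


def end_position_summary(
    table: IsomiRTable, design: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Expression-weighted histogram of end-shift positions.

    Returns ``{"5p": ..., "3p": ...}``; each DataFrame is indexed by shift
    (-3..3 excluding 0) with one column per sample, or per population when a
    design is given. Zero shift at an end does not contribute to that end.
    """
    shifts = [s for s in range(-3, 4) if s != 0]
    cols = list(table.samples)
    out = {
        end: pd.DataFrame(0, index=shifts, columns=cols, dtype=int)
        for end in ("5p", "3p")
    }
    for c in table.calls:
        for end, s in (("5p", c.shifts.shift5), ("3p", c.shifts.shift3)):
            if s == 0:
                continue
            for smp in cols:
                out[end].loc[s, smp] += c.counts.get(smp, 0)
    if design is not None:
        pop = design["population"]
        out = {
            end: df.T.groupby(pop).sum().T for end, df in out.items()
        }
    return out


_DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}
SPECTRUM_CATEGORIES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def substitution_spectrum(
    table: IsomiRTable, weight: str = "expression"
) -> tuple[pd.Series, pd.Series]:
    """Substitution counts over the 12 ref>alt categories (DNA alphabet) and
    per canonical-mature position.

    ``weight="expression"`` sums read counts; ``weight="sequences"`` counts
    distinct sequences once.
    """
    if weight not in ("expression", "sequences"):
        raise ValueError(f"unknown weight {weight!r}")
    spectrum = pd.Series(0, index=list(SPECTRUM_CATEGORIES), dtype=int)
    per_pos: dict[int, int] = {}
    for c in table.calls:
        w = sum(c.counts.values()) if weight == "expression" else 1
        for sub in c.substitutions:
            spectrum[f"{_DNA[sub.ref]}>{_DNA[sub.alt]}"] += w
            per_pos[sub.position] = per_pos.get(sub.position, 0) + w
    return spectrum, pd.Series(per_pos, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# ADAR
# ---------------------------------------------------------------------------

def detect_adar(
    table: IsomiRTable, index: ReferenceIndex
) -> tuple[list[AdarSite], pd.DataFrame]:
    """A>G substitution calling at reference-A positions of the mature.

    Inosine pairs like guanosine, so A-to-I editing appears as A>G on the
    sense read. Returns the per-site list and a per-sample summary with the
    number of distinct edited matures, edited expression in CPM of the
    called library, and edited expression as a percentage of the affected
    matures' total expression.
    """
    mature_totals: dict[str, dict[str, int]] = {}
    for c in table.calls:
        tot = mature_totals.setdefault(c.mature_name, {})
        for s, n in c.counts.items():
            tot[s] = tot.get(s, 0) + n
    edited: dict[tuple[str, int], dict[str, int]] = {}
    for c in table.calls:
        for sub in c.substitutions:
            if sub.ref != "A" or sub.alt != "G":
                continue
            # positions are canonical-mature coordinates, so ref A is
            # guaranteed by construction; assert the reference agrees
            mseq = index.matures[c.mature_name].sequence
            if mseq[sub.position - 1] != "A":
                continue
            site = edited.setdefault((c.mature_name, sub.position), {})
            for s, n in c.counts.items():
                site[s] = site.get(s, 0) + n
    sites = [
        AdarSite(
            mature_name=m,
            position=p,
            edited_counts=cnts,
            total_counts=dict(mature_totals.get(m, {})),
        )
        for (m, p), cnts in sorted(edited.items())
    ]
    lib = {
        s: sum(c.counts.get(s, 0) for c in table.calls) for s in table.samples
    }
    rows = []
    for s in table.samples:
        matures = {a.mature_name for a in sites if a.edited_counts.get(s, 0) > 0}
        ed = sum(a.edited_counts.get(s, 0) for a in sites)
        tot = sum(
            mature_totals.get(m, {}).get(s, 0) for m in matures
        )
        rows.append(
            {
                "sample": s,
                "n_adar_matures": len(matures),
                "adar_cpm": ed / lib[s] * 1e6 if lib[s] else 0.0,
                "adar_pct_of_mature": ed / tot * 100 if tot else 0.0,
            }
        )
    return sites, pd.DataFrame(rows).set_index("sample")


def compare_adar_between_groups(
    summary: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    column: str = "n_adar_matures",
) -> tuple[float, float]:
    """Unpaired two-sided t-test on per-replicate ADAR summaries.

    Compares ``column`` (default: number of edited matures) between the
    replicates of two populations. Returns ``(statistic, p_value)``.
    """
    pops = design["population"]
    a = summary.loc[pops[pops == group_a].index, column].to_numpy(float)
    b = summary.loc[pops[pops == group_b].index, column].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 replicates")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if b.mean() > a.mean() else -np.inf, 0.0
    stat, p = stats.ttest_ind(a, b)
    return float(stat), float(p)
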