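"""miRBase-style reference model.

Parses hairpin/mature FASTA plus a miRBase-dialect GFF3 into a
:class:`ReferenceIndex` that locates every mature miRNA inside its hairpin,
and derives the two groupings the downstream analyses aggregate over:

* **genomic clusters** — matures on the same chromosome chained while the
  gap between consecutive (coordinate-sorted) matures is at most
  ``max_gap`` bases (miRBase convention: 10,000), named ``Chr{N}.{k}``;
* **seed families** — matures sharing the identical seed (nucleotides 2-8
  of the mature sequence).

Coordinates are 0-based half-open internally; GFF3 I/O converts from/to the
1-based inclusive convention of the format.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "HairpinRecord",
    "MatureRecord",
    "ReferenceIndex",
    "GenomicCluster",
    "SeedFamily",
    "load_reference",
    "write_reference",
    "seed_of",
    "detect_genomic_clusters",
    "group_families",
]

_RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def revcomp_rna(seq: str) -> str:
    return str(Seq(seq.replace("U", "T")).reverse_complement()).replace("T", "U")


def _check_rna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    bad = set(seq) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"{what}: non-RNA characters {sorted(bad)}")


@dataclass
class HairpinRecord:
    """A pri/pre-miRNA hairpin (~70 nt) with optional genomic placement.

    ``sequence`` is stored in sense (5'->3' RNA) orientation; ``start``/``end``
    are 0-based half-open genomic coordinates.
    """

    id: str
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        _check_rna(self.sequence, f"hairpin {self.id}")
        if self.chrom is not None:
            if self.end - self.start != len(self.sequence):
                raise ValueError(
                    f"hairpin {self.id}: genomic span {self.end - self.start} "
                    f"!= sequence length {len(self.sequence)}"
                )
            if self.strand not in ("+", "-"):
                raise ValueError(f"hairpin {self.id}: strand must be + or -")


@dataclass
class MatureRecord:
    """A mature miRNA located inside its hairpin.

    ``offset_in_hairpin`` indexes into the sense-oriented hairpin sequence.
    Genomic coordinates (0-based half-open) are derived from the hairpin's.
    """

    name: str
    hairpin_id: str
    offset_in_hairpin: int
    sequence: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence)
        _check_rna(self.sequence, f"mature {self.name}")
        if not 16 <= len(self.sequence) <= 28:
            raise ValueError(
                f"mature {self.name}: length {len(self.sequence)} outside [16, 28]"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)


@dataclass
class GenomicCluster:
    """>=2 matures on one chromosome chained by gaps <= max_gap."""

    name: str
    chrom: str
    members: list[str]
    start: int
    end: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"cluster {self.name}: needs >=2 members")


@dataclass
class SeedFamily:
    """Matures grouped by identical seed (or by a curated annotation label)."""

    family_id: str
    seed: str | None
    members: list[str]
    fallback: bool = False  # annotated mode: members grouped by seed because
    #                         they were absent from the annotation table


@dataclass
class ReferenceIndex:
    """Hairpins + matures with a per-chromosome coordinate-sorted view."""

    hairpins: dict[str, HairpinRecord]
    matures: dict[str, MatureRecord]
    by_chrom: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        for m in self.matures.values():
            if m.hairpin_id not in self.hairpins:
                raise ValueError(f"mature {m.name}: unknown hairpin {m.hairpin_id}")
            hp = self.hairpins[m.hairpin_id]
            sub = hp.sequence[m.offset_in_hairpin : m.offset_in_hairpin + m.length]
            if sub != m.sequence:
                raise ValueError(f"mature {m.name}: not a substring of its hairpin")
        self.by_chrom = {}
        for name, m in self.matures.items():
            if m.chrom is not None:
                self.by_chrom.setdefault(m.chrom, []).append(name)
        for names in self.by_chrom.values():
            names.sort(key=lambda n: (self.matures[n].start, n))

    def context(self, mature_name: str, k: int = 3) -> tuple[str, str]:
        """Up to ``k`` hairpin bases flanking the mature on each side.

        Returns ``(upstream, downstream)`` in sense orientation; strings are
        shorter than ``k`` where the mature sits near a hairpin end.
        """
        m = self.matures[mature_name]
        hp = self.hairpins[m.hairpin_id].sequence
        lo = m.offset_in_hairpin
        hi = lo + m.length
        return hp[max(0, lo - k) : lo], hp[hi : hi + k]


def seed_of(sequence: str) -> str:
    """Seed region: nucleotides 2-8 (1-based inclusive) of a mature sequence."""
    sequence = normalize_rna(sequence)
    if len(sequence) < 8:
        raise ValueError(f"sequence of length {len(sequence)} has no full seed")
    return sequence[1:8]


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O (miRBase dialect)
# ---------------------------------------------------------------------------

def _read_gff3(path: str | Path) -> list[dict]:
    from gffutils.iterators import DataIterator

    rows = []
    for feat in DataIterator(str(path)):
        rows.append(
            {
                "chrom": feat.seqid,
                "type": feat.featuretype,
                "start": feat.start,  # 1-based inclusive
                "end": feat.end,
                "strand": feat.strand,
                "attrs": {k: v[0] for k, v in feat.attributes.items() if v},
            }
        )
    return rows


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id}")
        seqs[rec.id] = normalize_rna(str(rec.seq))
    return seqs


def load_reference(
    hairpin_fasta: str | Path, mature_fasta: str | Path, gff3: str | Path
) -> ReferenceIndex:
    """Load a miRBase-style reference into a :class:`ReferenceIndex`.

    The GFF3 must carry ``miRNA_primary_transcript`` rows (hairpins) and
    ``miRNA`` rows with a ``Derives_from`` attribute naming the hairpin's
    ``ID``. FASTA sequences may use T or U. Each mature must occur verbatim
    inside its hairpin; for minus-strand hairpins whose FASTA was extracted
    from the plus strand of the genome, the hairpin is reverse-complemented
    to sense orientation before matching.

    Raises ``ValueError`` for a mature that cannot be located in its hairpin
    or for a duplicate mature name; matures lacking ``Derives_from`` are
    skipped with a warning.
    """
    hp_seqs = _read_fasta(hairpin_fasta)
    mat_seqs = _read_fasta(mature_fasta)
    rows = _read_gff3(gff3)

    hairpins: dict[str, HairpinRecord] = {}
    gffid_to_name: dict[str, str] = {}
    for row in rows:
        if row["type"] != "miRNA_primary_transcript":
            continue
        attrs = row["attrs"]
        name = attrs.get("Name", attrs.get("ID"))
        gffid_to_name[attrs.get("ID", name)] = name
        if name not in hp_seqs:
            warnings.warn(f"hairpin {name} in GFF3 but not in FASTA; skipped")
            continue
        seq = hp_seqs[name]
        hairpins[name] = HairpinRecord(
            id=name,
            sequence=seq,
            chrom=row["chrom"],
            start=row["start"] - 1,
            end=row["end"],
            strand=row["strand"],
        )
    # hairpins with sequence but no GFF row: keep, without coordinates
    for name, seq in hp_seqs.items():
        if name not in hairpins:
            hairpins[name] = HairpinRecord(id=name, sequence=seq)

    matures: dict[str, MatureRecord] = {}
    for row in rows:
        if row["type"] != "miRNA":
            continue
        attrs = row["attrs"]
        name = attrs.get("Name", attrs.get("ID"))
        if name in matures:
            raise ValueError(f"duplicate mature name {name}")
        derives = attrs.get("Derives_from")
        if derives is None:
            warnings.warn(f"mature {name}: no Derives_from attribute; skipped")
            continue
        hp_name = gffid_to_name.get(derives, derives)
        if hp_name not in hairpins:
            raise ValueError(f"mature {name}: Derives_from {derives} not found")
        if name not in mat_seqs:
            warnings.warn(f"mature {name} in GFF3 but not in FASTA; skipped")
            continue
        seq = mat_seqs[name]
        hp = hairpins[hp_name]
        off = hp.sequence.find(seq)
        if off < 0 and hp.strand == "-":
            # plus-strand extracted hairpin: flip to sense and retry
            flipped = revcomp_rna(hp.sequence)
            off = flipped.find(seq)
            if off >= 0:
                hp.sequence = flipped
        if off < 0:
            raise ValueError(
                f"mature {name}: sequence not found in hairpin {hp_name}"
            )
        chrom = start = end = strand = None
        if hp.chrom is not None:
            chrom, strand = hp.chrom, hp.strand
            if strand == "+":
                start = hp.start + off
                end = start + len(seq)
            else:
                end = hp.end - off
                start = end - len(seq)
        matures[name] = MatureRecord(
            name=name,
            hairpin_id=hp_name,
            offset_in_hairpin=off,
            sequence=seq,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
        )
    return ReferenceIndex(hairpins=hairpins, matures=matures)


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_reference(
    index: ReferenceIndex,
    hairpin_fasta: str | Path,
    mature_fasta: str | Path,
    gff3: str | Path,
) -> None:
    """Write the index back to hairpin/mature FASTA and miRBase-dialect GFF3."""
    with open(hairpin_fasta, "w") as fh:
        for hp in index.hairpins.values():
            fh.write(f">{hp.id}\n{_wrap(hp.sequence)}\n")
    with open(mature_fasta, "w") as fh:
        for m in index.matures.values():
            fh.write(f">{m.name}\n{_wrap(m.sequence)}\n")
    with open(gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for hp in index.hairpins.values():
            if hp.chrom is None:
                continue
            fh.write(
                f"{hp.chrom}\t.\tmiRNA_primary_transcript\t{hp.start + 1}\t{hp.end}"
                f"\t.\t{hp.strand}\t.\tID={hp.id};Name={hp.id}\n"
            )
        for m in index.matures.values():
            if m.chrom is None:
                continue
            fh.write(
                f"{m.chrom}\t.\tmiRNA\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.name};Name={m.name};Derives_from={m.hairpin_id}\n"
            )


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def _chrom_label(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def detect_genomic_clusters(
    index: ReferenceIndex,
    max_gap: int = 10_000,
    return_singletons: bool = False,
):
    """Single-linkage chaining of matures within ``max_gap`` bases.

    Matures on one chromosome, coordinate-sorted, are linked while the number
    of intervening bases between consecutive matures is at most ``max_gap``
    (strand-agnostic, per the miRBase coordinate-only convention). Chains of
    one are not clusters; with ``return_singletons=True`` they are returned
    as a second list. Cluster ``k`` is the 1-based ordinal, by start, of the
    cluster on its chromosome.
    """
    clusters: list[GenomicCluster] = []
    singletons: list[str] = []
    for chrom in sorted(index.by_chrom):
        names = index.by_chrom[chrom]
        chains: list[list[str]] = []
        for name in names:
            m = index.matures[name]
            if chains:
                prev_end = max(index.matures[n].end for n in chains[-1])
                # 0-based half-open: start - end == intervening bases
                if m.start - prev_end <= max_gap:
                    chains[-1].append(name)
                    continue
            chains.append([name])
        k = 0
        for chain in chains:
            if len(chain) < 2:
                singletons.extend(chain)
                continue
            k += 1
            starts = [index.matures[n].start for n in chain]
            ends = [index.matures[n].end for n in chain]
            clusters.append(
                GenomicCluster(
                    name=f"Chr{_chrom_label(chrom)}.{k}",
                    chrom=chrom,
                    members=list(chain),
                    start=min(starts),
                    end=max(ends),
                )
            )
    if return_singletons:
        return clusters, singletons
    return clusters


def group_families(
    index: ReferenceIndex,
    mode: str = "seed",
    annotation: Mapping[str, str] | Iterable[tuple[str, str]] | None = None,
) -> list[SeedFamily]:
    """Partition matures into families.

    ``seed`` mode groups by exact seed identity (family_id ``seed:<7-mer>``).
    ``annotated`` mode groups by a curated mature->family table; matures
    absent from the table fall back to seed grouping and are flagged.
    """
    if mode not in ("seed", "annotated"):
        raise ValueError(f"unknown family mode {mode!r}")

    def seed_partition(names: Iterable[str], fallback: bool) -> list[SeedFamily]:
        by_seed: dict[str, list[str]] = {}
        for n in sorted(names):
            by_seed.setdefault(index.matures[n].seed, []).append(n)
        return [
            SeedFamily(family_id=f"seed:{s}", seed=s, members=mem, fallback=fallback)
            for s, mem in sorted(by_seed.items())
        ]

    if mode == "seed":
        return seed_partition(index.matures, fallback=False)

    if annotation is None:
        raise ValueError("annotated mode requires an annotation table")
    table: dict[str, str] = {}
    pairs = annotation.items() if isinstance(annotation, Mapping) else annotation
    for mature, fam in pairs:
        if mature in table and table[mature] != fam:
            raise ValueError(
                f"mature {mature} annotated to both {table[mature]} and {fam}"
            )
        table[mature] = fam
    by_fam: dict[str, list[str]] = {}
    missing: list[str] = []
    for n in sorted(index.matures):
        if n in table:
            by_fam.setdefault(table[n], []).append(n)
        else:
            missing.append(n)
    families = [
        SeedFamily(family_id=f, seed=None, members=mem)
        for f, mem in sorted(by_fam.items())
    ]
    families.extend(seed_partition(missing, fallback=True))
    return families
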