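"""Synthetic references, reads, count matrices and score tables with planted
ground truth.

The generator emulates the structure of a small-RNA-seq study of staged
differentiation: a miRBase-like reference with planted genomic clusters and
shared-seed families; collapsed reads derived from the matures by end-shifts
(mode -3 at the 5' end, -1 at the 3' end), templated and non-templated 3'/5'
additions, at most one internal substitution with a spectrum favouring
C>G / G>A / T>C, and A>G editing at designated reference-A sites; and
negative-binomial count matrices for three populations x three replicates
with planted fold changes and the five canonical trajectory shapes
(monotone up, late up, late down, early down, transient up).

Every operation is deterministic given ``config.seed``: the same seed yields
byte-identical output files.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .isomir import ReadRecord
from .quant import make_design
from .refmodel import (
    HairpinRecord,
    MatureRecord,
    ReferenceIndex,
    write_reference,
)

__all__ = [
    "SimulationConfig",
    "TRAJECTORY_SHAPES",
    "simulate_reference",
    "simulate_reads",
    "simulate_counts",
    "simulate_score_table",
    "write_collapsed_fasta",
    "write_counts",
    "write_design",
    "write_score_table",
]

# the five dynamic patterns across three ordered stages, as standardized
# (mean 0 / sd 1) profiles
TRAJECTORY_SHAPES: dict[str, np.ndarray] = {
    "monotone_up": np.array([-1.0, 0.0, 1.0]),
    "late_up": np.array([-0.5773503, -0.5773503, 1.1547005]),
    "late_down": np.array([0.5773503, 0.5773503, -1.1547005]),
    "early_down": np.array([1.1547005, -0.5773503, -0.5773503]),
    "transient_up": np.array([-0.5773503, 1.1547005, -0.5773503]),
}

_BASES = "ACGU"


@dataclass
class SimulationConfig:
    """Study-shaped defaults for all generators.

    Rates and distributions mirror the study conditions: 3 populations x 3
    replicates; 5' shift mode at -3 and 3' shift mode at -1; substitution
    spectrum enriched for C>G, G>A and U>C (A>G is reserved for ADAR
    editing); most read sequences are end-variants rather than exact.
    """

    seed: int = 0
    # --- reference ---
    cluster_plan: tuple[tuple[str, int], ...] = (("4", 4), ("13", 3), ("19", 3))
    n_singleton_hairpins: int = 20
    intra_cluster_gap: int = 2_000
    inter_cluster_gap: int = 50_000
    hairpin_flank: int = 4
    mature_length: int = 22
    loop_length: int = 18
    n_shared_seed_families: int = 4
    family_size: int = 3
    minus_strand_fraction: float = 0.2
    # --- reads ---
    n_read_sequences: int = 1_500
    class_probs: tuple[float, float, float, float] = (0.25, 0.15, 0.35, 0.25)
    #             exact, iso5, iso3, iso5_iso3
    shift5_probs: dict[int, float] = field(
        default_factory=lambda: {-3: 0.40, -2: 0.15, -1: 0.15, 1: 0.10, 2: 0.10, 3: 0.10}
    )
    shift3_probs: dict[int, float] = field(
        default_factory=lambda: {-1: 0.40, -2: 0.15, -3: 0.10, 1: 0.15, 2: 0.10, 3: 0.10}
    )
    substitution_rate: float = 0.15
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: {"C>G": 6.0, "G>A": 6.0, "U>C": 6.0}
    )  # unlisted categories weight 1; A>G fixed at 0 (reserved for ADAR)
    templated_prob: float = 0.7
    adar_site_fraction: float = 0.1
    adar_editing_rate: float = 0.2
    read_mean_range: tuple[float, float] = (5.0, 500.0)
    read_dispersion: float = 0.1
    # --- counts ---
    populations: tuple[str, ...] = ("PSC", "MPC", "CM")
    replicates: int = 3
    n_features: int = 600
    count_mean_log10_range: tuple[float, float] = (0.7, 3.5)
    count_dispersion_range: tuple[float, float] = (0.01, 0.15)
    n_de_features: int = 20
    de_log2fc: float = 6.0
    de_target_pop: str | None = None  # default: last population
    n_exclusive_features: int = 0
    traj_per_shape: int = 30
    traj_noise_sd: float = 0.2
    traj_amplitude: float = 2.0


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[ReferenceIndex, dict]:
    """Generate a miRBase-like reference with planted clusters and families.

    Hairpins listed in ``cluster_plan`` carry a 5p and a 3p mature and are
    placed ``intra_cluster_gap`` bases apart, so each plan entry becomes one
    genomic cluster; singleton hairpins carry a single mature placed
    ``inter_cluster_gap`` bases from anything else (never clustered).
    ``n_shared_seed_families`` seeds are each stamped into ``family_size``
    matures from different hairpins.

    Returns ``(index, truth)``; with ``out_dir`` the three reference files
    (hairpin.fa, mature.fa, reference.gff3) are also written.
    """
    rng = _rng(config, 1)
    L = config.mature_length
    plan: list[tuple[str, int, int]] = []  # (chrom, n_matures, hairpin_count)
    total_cluster_hp = sum(n for _, n in config.cluster_plan)
    n_hp = total_cluster_hp + config.n_singleton_hairpins
    if any(n < 1 for _, n in config.cluster_plan):
        raise ValueError("cluster plan entries need >=1 hairpin")

    # distinct seeds: planted shared ones + one per remaining mature
    n_matures = 2 * total_cluster_hp + config.n_singleton_hairpins
    seeds: list[str] = []
    seen = set()
    while len(seeds) < n_matures + config.n_shared_seed_families:
        s = _random_rna(rng, 7)
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    shared_seeds = seeds[: config.n_shared_seed_families]

    hairpins: dict[str, HairpinRecord] = {}
    matures: dict[str, MatureRecord] = {}
    placements: list[dict] = []  # mature name -> construction info

    def make_mature(seq_seed: str) -> str:
        return rng.choice(list(_BASES)) + seq_seed + _random_rna(rng, L - 8)

    hp_idx = 0
    chrom_cursor: dict[str, int] = {}
    truth_clusters: dict[str, list[str]] = {}
    for ci, (chrom, n) in enumerate(config.cluster_plan):
        members: list[str] = []
        pos = chrom_cursor.get(chrom, 10_000) + config.inter_cluster_gap
        for j in range(n):
            hp_idx += 1
            hid = f"sim-mir-{hp_idx}"
            m5 = make_mature(_random_rna(rng, 7))
            m3 = make_mature(_random_rna(rng, 7))
            hp_seq = (
                _random_rna(rng, config.hairpin_flank)
                + m5
                + _random_rna(rng, config.loop_length)
                + m3
                + _random_rna(rng, config.hairpin_flank)
            )
            strand = "-" if rng.random() < config.minus_strand_fraction else "+"
            hairpins[hid] = HairpinRecord(
                id=hid, sequence=hp_seq, chrom=chrom, start=pos,
                end=pos + len(hp_seq), strand=strand,
            )
            for arm, mseq, off in (
                ("5p", m5, config.hairpin_flank),
                ("3p", m3, config.hairpin_flank + L + config.loop_length),
            ):
                name = f"sim-miR-{hp_idx}-{arm}"
                placements.append({"name": name, "hairpin": hid, "offset": off,
                                   "sequence": mseq})
                members.append(name)
            pos += len(hp_seq) + config.intra_cluster_gap
        chrom_cursor[chrom] = pos
        truth_clusters[f"plan{ci + 1}:{chrom}"] = members
    singleton_chroms = [str(c) for c in range(1, 23)]
    for j in range(config.n_singleton_hairpins):
        hp_idx += 1
        hid = f"sim-mir-{hp_idx}"
        chrom = singleton_chroms[j % len(singleton_chroms)]
        pos = chrom_cursor.get(chrom, 10_000) + config.inter_cluster_gap
        m5 = make_mature(_random_rna(rng, 7))
        hp_seq = (
            _random_rna(rng, config.hairpin_flank)
            + m5
            + _random_rna(rng, config.loop_length + L + config.hairpin_flank)
        )
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        hairpins[hid] = HairpinRecord(
            id=hid, sequence=hp_seq, chrom=chrom, start=pos,
            end=pos + len(hp_seq), strand=strand,
        )
        placements.append({"name": f"sim-miR-{hp_idx}-5p", "hairpin": hid,
                           "offset": config.hairpin_flank, "sequence": m5})
        chrom_cursor[chrom] = pos + len(hp_seq)

    # stamp shared seeds into family_size matures each, round-robin over
    # distinct hairpins, then give everyone else a unique seed
    truth_families: dict[str, list[str]] = {}
    flat = list(placements)
    take = 0
    for fi, fseed in enumerate(shared_seeds):
        fam: list[str] = []
        used_hp: set[str] = set()
        for p in flat:
            if len(fam) >= config.family_size:
                break
            if p["hairpin"] in used_hp or p.get("family"):
                continue
            p["family"] = fseed
            p["sequence"] = p["sequence"][0] + fseed + p["sequence"][8:]
            used_hp.add(p["hairpin"])
            fam.append(p["name"])
            take += 1
        truth_families[f"seed:{fseed}"] = fam
    unique_iter = iter(seeds[config.n_shared_seed_families :])
    for p in flat:
        if not p.get("family"):
            p["sequence"] = p["sequence"][0] + next(unique_iter) + p["sequence"][8:]

    # rebuild hairpins with the (possibly re-seeded) mature sequences stitched in
    for p in flat:
        hp = hairpins[p["hairpin"]]
        s = hp.sequence
        off = p["offset"]
        hp.sequence = s[:off] + p["sequence"] + s[off + L :]
    for p in flat:
        hp = hairpins[p["hairpin"]]
        if hp.strand == "+":
            start = hp.start + p["offset"]
            end = start + L
        else:
            end = hp.end - p["offset"]
            start = end - L
        matures[p["name"]] = MatureRecord(
            name=p["name"], hairpin_id=p["hairpin"],
            offset_in_hairpin=p["offset"], sequence=p["sequence"],
            chrom=hp.chrom, start=start, end=end, strand=hp.strand,
        )
    index = ReferenceIndex(hairpins=hairpins, matures=matures)
    truth = {"clusters": truth_clusters, "families": truth_families}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reference(index, out / "hairpin.fa", out / "mature.fa",
                        out / "reference.gff3")
        (out / "reference_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True)
        )
    return index, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _sample_weighted(rng, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    w = np.array([probs[k] for k in keys], float)
    return int(rng.choice(keys, p=w / w.sum()))


def _bruteforce_best(read: str, index: ReferenceIndex, max_shift=3, max_sub=1):
    """All minimal-cost (mature, shift5, shift3, n_subs) explanations of a
    read, by naive enumeration; used only to flag ambiguous sequences."""
    hits = []
    for name in sorted(index.matures):
        m = index.matures[name]
        mseq = m.sequence
        up, down = index.context(name, max_shift)
        for s5 in range(-max_shift, max_shift + 1):
            s3 = len(read) - len(mseq) - s5
            if not -max_shift <= s3 <= max_shift:
                continue
            n_mm = sum(
                1
                for p in range(max(0, -s5), len(mseq) - max(0, -s3))
                if read[p + s5] != mseq[p]
            )
            if n_mm <= max_sub:
                hits.append((abs(s5) + abs(s3) + n_mm, name, s5, s3, n_mm))
    if not hits:
        return []
    best = min(h[0] for h in hits)
    return [h for h in hits if h[0] == best]


def simulate_reads(
    config: SimulationConfig,
    index: ReferenceIndex,
    out_dir: str | Path | None = None,
):
    """Collapsed read sequences derived from the reference, with truth.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    :class:`ReadRecord` with per-sample NB counts and ``truth`` maps read id
    to its generating tuple (mature, shifts, substitution, templated flags,
    ADAR flag) plus an ``ambiguity_free`` flag (the generating explanation is
    the unique minimal-cost one under brute force). With ``out_dir``, one
    collapsed FASTA per sample plus ``reads_truth.json`` are written.
    """
    rng = _rng(config, 2)
    mature_names = sorted(index.matures)
    samples = [
        f"{pop}{r + 1}"
        for pop in config.populations
        for r in range(config.replicates)
    ]
    # designate ADAR sites: internal A positions of a fraction of matures
    adar_sites: dict[str, int] = {}
    n_adar = max(1, int(round(config.adar_site_fraction * len(mature_names)))) \
        if config.adar_site_fraction > 0 else 0
    for name in rng.permutation(mature_names)[:n_adar]:
        seq = index.matures[name].sequence
        a_pos = [i + 1 for i, b in enumerate(seq[4:-4], start=4) if b == "A"]
        if a_pos:
            adar_sites[str(name)] = int(rng.choice(a_pos))

    class_names = ("exact", "iso5", "iso3", "iso5_iso3")
    probs = np.array(config.class_probs, float)
    probs = probs / probs.sum()
    spectrum = {}
    for r in "ACGU":
        for a in "ACGU":
            if r == a or (r, a) == ("A", "G"):
                continue
            key = f"{r}>{a}"
            spectrum[(r, a)] = config.spectrum_weights.get(key, 1.0)

    reads: list[ReadRecord] = []
    truth: dict[str, dict] = {}
    seen_seq: set[str] = set()
    i = 0
    attempts = 0
    while i < config.n_read_sequences and attempts < 20 * config.n_read_sequences:
        attempts += 1
        name = str(rng.choice(mature_names))
        m = index.matures[name]
        mseq = m.sequence
        up, down = index.context(name, 3)
        cls = class_names[int(rng.choice(4, p=probs))]
        s5 = (
            _sample_weighted(rng, config.shift5_probs)
            if cls in ("iso5", "iso5_iso3")
            else 0
        )
        s3 = (
            _sample_weighted(rng, config.shift3_probs)
            if cls in ("iso3", "iso5_iso3")
            else 0
        )
        # body after trimming
        body = mseq[max(0, -s5) : len(mseq) - max(0, -s3)]
        body_offset = max(0, -s5)  # canonical position of body[0] (0-based)
        sub = None
        is_adar = False
        site = adar_sites.get(name)
        if site is not None and body_offset < site <= body_offset + len(body) \
                and rng.random() < config.adar_editing_rate:
            p0 = site - 1 - body_offset
            body = body[:p0] + "G" + body[p0 + 1 :]
            sub = (site, "A", "G")
            is_adar = True
        elif rng.random() < config.substitution_rate and len(body) > 2:
            p0 = int(rng.integers(0, len(body)))
            ref = body[p0]
            alts = [a for (r, a) in spectrum if r == ref]
            w = np.array([spectrum[(ref, a)] for a in alts])
            alt = str(rng.choice(alts, p=w / w.sum()))
            body = body[:p0] + alt + body[p0 + 1 :]
            sub = (body_offset + p0 + 1, ref, alt)
        t5 = t3 = None
        pre = post = ""
        if s5 > 0:
            t5 = bool(rng.random() < config.templated_prob) and len(up) >= s5
            pre = up[-s5:] if t5 else _random_rna(rng, s5)
            if not t5 and len(up) >= s5 and pre == up[-s5:]:
                # force a non-templated mismatch
                b = pre[0]
                pre = ("A" if b != "A" else "C") + pre[1:]
        if s3 > 0:
            t3 = bool(rng.random() < config.templated_prob) and len(down) >= s3
            post = down[:s3] if t3 else _random_rna(rng, s3)
            if not t3 and len(down) >= s3 and post == down[:s3]:
                b = post[0]
                post = ("A" if b != "A" else "C") + post[1:]
        seq = pre + body + post
        if len(seq) < 16 or seq in seen_seq:
            continue
        seen_seq.add(seq)
        i += 1
        rid = f"read{i:05d}"
        mean = float(np.exp(rng.uniform(*np.log(config.read_mean_range))))
        nbn = 1.0 / config.read_dispersion
        counts = {
            s: int(rng.negative_binomial(nbn, nbn / (nbn + mean)))
            for s in samples
        }
        if not any(counts.values()):
            counts[samples[0]] = 1
        reads.append(ReadRecord(read_id=rid, sequence=seq, count_per_sample=counts))
        best = _bruteforce_best(seq, index)
        ambiguity_free = (
            len(best) == 1
            and best[0][1] == name
            and best[0][2] == s5
            and best[0][3] == s3
        )
        truth[rid] = {
            "mature": name,
            "shift5": s5,
            "shift3": s3,
            "iso_class": cls,
            "substitution": list(sub) if sub else None,
            "added5_templated": t5,
            "added3_templated": t3,
            "adar": is_adar,
            "ambiguity_free": bool(ambiguity_free),
            "sequence": seq,
        }
    if i < config.n_read_sequences:
        raise RuntimeError("could not generate the requested number of reads")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in samples:
            write_collapsed_fasta(reads, s, out / f"{s}.fa")
        (out / "reads_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True)
        )
    return reads, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean, dispersion) draws; dispersion below 1e-8 falls back to Poisson."""
    mean = np.asarray(mean, float)
    alpha = np.broadcast_to(np.asarray(alpha, float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poiss = alpha < 1e-8
    if poiss.any():
        out[poiss] = rng.poisson(mean[poiss])
    if (~poiss).any():
        n = 1.0 / alpha[~poiss]
        out[~poiss] = rng.negative_binomial(n, n / (n + mean[~poiss]))
    return out


def simulate_counts(config: SimulationConfig, out_dir: str | Path | None = None):
    """NB count matrix with planted DE, exclusive and trajectory features.

    Features are NB(mean, dispersion) with per-feature base mean and
    dispersion drawn from the configured ranges, identical across
    populations except for the planted structure: ``n_de_features`` have
    their mean multiplied by ``2**de_log2fc`` in the target population,
    ``n_exclusive_features`` have mean 0 outside the target, and
    ``traj_per_shape`` features per shape follow the five standardized
    trajectory shapes (amplitude ``traj_amplitude`` in log2 units, Gaussian
    noise ``traj_noise_sd`` on the standardized scale).

    Returns ``(counts, design, truth)``.
    """
    rng = _rng(config, 3)
    pops = list(config.populations)
    target = config.de_target_pop or pops[-1]
    if target not in pops:
        raise ValueError(f"de_target_pop {target!r} not in populations")
    samples = [f"{p}{r + 1}" for p in pops for r in range(config.replicates)]
    design = make_design(samples, [p for p in pops for _ in range(config.replicates)])

    n = config.n_features
    shapes = list(TRAJECTORY_SHAPES)
    n_traj = config.traj_per_shape * len(shapes)
    if config.n_de_features + config.n_exclusive_features + n_traj > n:
        raise ValueError("planted features exceed n_features")
    names = [f"feat{i + 1:04d}" for i in range(n)]
    lo, hi = config.count_mean_log10_range
    base = 10 ** rng.uniform(lo, hi, size=n)
    alpha = rng.uniform(*config.count_dispersion_range, size=n)

    mean = np.tile(base[:, None], (1, len(pops)))  # features x populations
    de_names = names[: config.n_de_features]
    excl_names = names[config.n_de_features : config.n_de_features + config.n_exclusive_features]
    ti = pops.index(target)
    mean[: config.n_de_features, ti] *= 2.0**config.de_log2fc
    sl = slice(config.n_de_features, config.n_de_features + config.n_exclusive_features)
    mean[sl, :] = 0.0
    mean[sl, ti] = base[sl] * 4.0  # exclusive: well-expressed in target only
    traj_truth: dict[str, str] = {}
    row = config.n_de_features + config.n_exclusive_features
    for shape in shapes:
        z = TRAJECTORY_SHAPES[shape]
        for _ in range(config.traj_per_shape):
            noisy = z + rng.normal(0.0, config.traj_noise_sd, size=len(pops))
            mean[row, :] = base[row] * 2.0 ** (config.traj_amplitude * noisy)
            traj_truth[names[row]] = shape
            row += 1

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        pj = pops.index(design.loc[s, "population"])
        counts[:, j] = _nb_draw(rng, mean[:, pj], alpha)
    counts = pd.DataFrame(counts, index=names, columns=samples)
    truth = {
        "de_features": list(de_names),
        "de_log2fc": config.de_log2fc,
        "de_target_pop": target,
        "exclusive_features": list(excl_names),
        "trajectory_shapes": traj_truth,
        "population_means": {
            p: {names[i]: float(mean[i, k]) for i in range(n)}
            for k, p in enumerate(pops)
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(counts, out / "counts.tsv")
        write_design(design, out / "design.tsv")
        slim = {k: truth[k] for k in
                ("de_features", "de_log2fc", "de_target_pop",
                 "exclusive_features", "trajectory_shapes")}
        (out / "counts_truth.json").write_text(
            json.dumps(slim, indent=1, sort_keys=True)
        )
    return counts, design, truth


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def simulate_score_table(
    plan: dict,
    seed: int = 0,
    out_path: str | Path | None = None,
):
    """Score table with planted per-predictor target sets and overlaps.

    ``plan`` maps region specifications to gene counts: keys are predictor
    names for exclusive targets and sorted ``"A&B"`` / ``"A&B&C"`` strings
    for shared ones, e.g. ``{"A": 70, "B": 70, "A&B": 30}`` plants
    ``|A| = |B| = 100`` with ``|A∩B| = 30``. Target genes score
    Uniform(0.8, 1), and an equal number of decoy genes per predictor score
    Uniform(0, 0.8). Returns ``(table, truth)`` with the planted sets.
    """
    rng = np.random.default_rng([seed, 4])
    predictors = sorted({p for key in plan for p in key.split("&")})
    for key, cnt in plan.items():
        if cnt < 0:
            raise ValueError(f"negative region count for {key!r}")
    sets: dict[str, set[str]] = {p: set() for p in predictors}
    gid = 0
    for key in sorted(plan):
        for _ in range(plan[key]):
            gid += 1
            g = f"gene{gid:05d}"
            for p in key.split("&"):
                sets[p].add(g)
    rows = []
    for p in predictors:
        for g in sorted(sets[p]):
            rows.append((g, p, float(rng.uniform(0.8, 1.0))))
        n_decoy = len(sets[p])
        for d in range(n_decoy):
            gid += 1
            rows.append((f"gene{gid:05d}", p, float(rng.uniform(0.0, 0.8))))
    table = pd.DataFrame(rows, columns=["gene", "predictor", "score"])
    truth = {"target_sets": {p: sorted(s) for p, s in sets.items()}}
    if out_path is not None:
        write_score_table(table, out_path)
    return table, truth


# ---------------------------------------------------------------------------
# Writers (plain-text, deterministic)
# ---------------------------------------------------------------------------

def write_collapsed_fasta(reads: list[ReadRecord], sample: str, path: str | Path):
    """One collapsed FASTA per sample, headers ``>{id}_x{count}``."""
    with open(path, "w") as fh:
        for r in reads:
            c = r.count_per_sample.get(sample, 0)
            if c > 0:
                fh.write(f">{r.read_id}_x{c}\n{r.sequence}\n")


def write_counts(counts: pd.DataFrame, path: str | Path):
    counts.to_csv(path, sep="\t", index_label="feature")


def write_design(design: pd.DataFrame, path: str | Path):
    design.to_csv(path, sep="\t", index_label="sample")


def write_score_table(table: pd.DataFrame, path: str | Path):
    table.to_csv(path, sep="\t", index=False)
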