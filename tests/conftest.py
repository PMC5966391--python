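"""Shared fixtures: a tiny hand-built reference and simulated fixtures."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirnaome.refmodel import HairpinRecord, MatureRecord, ReferenceIndex
from mirnaome.simdata import SimulationConfig, simulate_reference

# let-7a-like: hairpin = AAGC | mature (22 nt) | CCGA
LET7_HAIRPIN = "AAGCUGAGGUAGUAGGUUGUAUAGUUCCGA"
LET7_MATURE = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture
def tiny_index() -> ReferenceIndex:
    """One hairpin, one mature, with known 5' (AGC) and 3' (CCG) context."""
    hp = HairpinRecord(
        id="hp1", sequence=LET7_HAIRPIN, chrom="9", start=1000,
        end=1000 + len(LET7_HAIRPIN), strand="+",
    )
    m = MatureRecord(
        name="let7-like-5p", hairpin_id="hp1", offset_in_hairpin=4,
        sequence=LET7_MATURE, chrom="9", start=1004, end=1026, strand="+",
    )
    return ReferenceIndex(hairpins={"hp1": hp}, matures={m.name: m})


def single_mature_index(starts: dict[str, list[int]], length: int = 22):
    """Index of isolated single-mature hairpins at the given starts per
    chromosome (helper for cluster-detection tests)."""
    rng = np.random.default_rng(0)
    hairpins, matures = {}, {}
    i = 0
    for chrom, ss in starts.items():
        for s in ss:
            i += 1
            mseq = "".join(rng.choice(list("ACGU"), size=length))
            hid, name = f"hp{i}", f"m{i}"
            hairpins[hid] = HairpinRecord(
                id=hid, sequence=mseq, chrom=chrom, start=s, end=s + length,
                strand="+",
            )
            matures[name] = MatureRecord(
                name=name, hairpin_id=hid, offset_in_hairpin=0, sequence=mseq,
                chrom=chrom, start=s, end=s + length, strand="+",
            )
    return ReferenceIndex(hairpins=hairpins, matures=matures)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=42, n_read_sequences=400)


@pytest.fixture(scope="session")
def sim_index(sim_config):
    index, truth = simulate_reference(sim_config)
    return index, truth


@pytest.fixture
def design9() -> pd.DataFrame:
    samples = [f"{p}{r}" for p in ("PSC", "MPC", "CM") for r in (1, 2, 3)]
    pops = [p for p in ("PSC", "MPC", "CM") for _ in range(3)]
    return pd.DataFrame(
        {"population": pops}, index=pd.Index(samples, name="sample")
    )
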