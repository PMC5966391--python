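"""isomiR classification, summaries and ADAR calling."""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from mirnaome.isomir import (
    IsomiRTable,
    ReadRecord,
    call_isomirs,
    classify_read,
    compare_adar_between_groups,
    detect_adar,
    end_position_summary,
    isoform_class_counts,
    substitution_spectrum,
)
from mirnaome.simdata import SimulationConfig, simulate_reads, simulate_reference

from conftest import LET7_MATURE


class TestClassifyRead:
    """Spec-level behavior on the single-mature reference with known
    flanking context (5' AGC, 3' CCG)."""

    def test_canonical_sequence_is_exact(self, tiny_index):
        call = classify_read(LET7_MATURE, tiny_index)
        assert call.iso_class == "exact"
        assert (call.shifts.shift5, call.shifts.shift3) == (0, 0)
        assert call.substitutions == []

    def test_three_prime_trim(self, tiny_index):
        call = classify_read(LET7_MATURE[:-2], tiny_index)
        assert call.iso_class == "iso3"
        assert call.shifts.shift3 == -2

    def test_templated_three_prime_addition(self, tiny_index):
        call = classify_read(LET7_MATURE + "CC", tiny_index)
        assert call.shifts.shift3 == 2
        assert call.added3_templated is True
        assert call.substitutions == []

    def test_non_templated_three_prime_addition(self, tiny_index):
        call = classify_read(LET7_MATURE + "AA", tiny_index)
        assert call.shifts.shift3 == 2
        assert call.added3_templated is False
        # tailing mismatches do not consume the substitution budget
        assert call.substitutions == []

    def test_internal_substitution_reported_in_mature_coordinates(self, tiny_index):
        read = LET7_MATURE[:9] + "G" + LET7_MATURE[10:]  # position 10: A->G
        call = classify_read(read, tiny_index)
        assert (call.shifts.shift5, call.shifts.shift3) == (0, 0)
        (sub,) = call.substitutions
        assert (sub.position, sub.ref, sub.alt) == (10, "A", "G")

    def test_shift_beyond_tolerance_unassigned(self, tiny_index):
        result = classify_read(LET7_MATURE + "CCGA", tiny_index)
        assert result == "shift exceeds ±3"

    def test_two_substitutions_unassigned(self, tiny_index):
        read = "CC" + LET7_MATURE[2:9] + "G" + LET7_MATURE[10:]
        result = classify_read(read, tiny_index)
        assert isinstance(result, str)

    def test_short_read_unassigned(self, tiny_index):
        assert isinstance(classify_read(LET7_MATURE[:15], tiny_index), str)

    def test_every_canonical_mature_classifies_exact(self, sim_index):
        index, _ = sim_index
        for name, m in index.matures.items():
            call = classify_read(m.sequence, index)
            assert call.iso_class == "exact"
            assert call.mature_name == name


def _oracle_best(read, index, max_shift=3, max_sub=1):
    """Independent minimal-cost explanation of a read: enumerate every
    (mature, shift5, shift3) placement, count body mismatches by direct
    string comparison, and apply the declared tie-break."""
    candidates = []
    for name in index.matures:
        m = index.matures[name]
        for s5, s3 in itertools.product(range(-max_shift, max_shift + 1), repeat=2):
            if len(m.sequence) + s5 + s3 != len(read):
                continue
            body = m.sequence[max(0, -s5): len(m.sequence) - max(0, -s3)]
            window = read[max(0, s5): len(read) - max(0, s3)]
            assert len(body) == len(window)
            n_mm = sum(a != b for a, b in zip(body, window))
            if n_mm <= max_sub:
                candidates.append(
                    ((abs(s5) + abs(s3) + n_mm, n_mm, abs(s5), name, s5, s3),
                     (name, s5, s3, n_mm))
                )
    if not candidates:
        return None
    return min(candidates)[1]


class TestOracleEquivalence:
    def test_agrees_with_bruteforce_enumerator(self):
        """classify_read equals the brute-force minimal-cost candidate for
        every read the enumerator itself can generate from a small index
        (all shifts, templated extensions, and one cyclic substitution)."""
        cfg = SimulationConfig(seed=11, cluster_plan=(("4", 2),),
                               n_singleton_hairpins=1,
                               n_shared_seed_families=1, family_size=2)
        index, _ = simulate_reference(cfg)
        assert len(index.matures) <= 5
        rot = {"A": "C", "C": "G", "G": "U", "U": "A"}
        n_checked = 0
        for name in index.matures:
            m = index.matures[name]
            up, down = index.context(name, 3)
            for s5 in range(-3, 4):
                for s3 in range(-3, 4):
                    if s5 > len(up) or s3 > len(down):
                        continue
                    core = m.sequence[max(0, -s5): len(m.sequence) - max(0, -s3)]
                    pre = up[len(up) - s5:] if s5 > 0 else ""
                    post = down[:s3] if s3 > 0 else ""
                    variants = [core] + [
                        core[:i] + rot[core[i]] + core[i + 1:]
                        for i in range(len(core))
                    ]
                    for var in variants:
                        read = pre + var + post
                        if len(read) < 16:
                            continue
                        expected = _oracle_best(read, index)
                        got = classify_read(read, index)
                        assert not isinstance(got, str), (read, expected)
                        assert (
                            got.mature_name,
                            got.shifts.shift5,
                            got.shifts.shift3,
                            len(got.substitutions),
                        ) == expected
                        n_checked += 1
        assert n_checked > 1000


class TestBatchCalling:
    def test_calls_and_unassigned_partition_reads(self, tiny_index):
        reads = [
            ReadRecord("r1", LET7_MATURE, {"s1": 5}),
            ReadRecord("r2", LET7_MATURE[:-1], {"s1": 3}),
            ReadRecord("r3", "ACGU" * 5, {"s1": 2}),
        ]
        table = call_isomirs(reads, tiny_index)
        assert len(table.calls) == 2
        assert len(table.unassigned) == 1
        assert table.unassigned[0][0] == "r3"

    def test_empty_input(self, tiny_index):
        table = call_isomirs([], tiny_index)
        assert table.calls == [] and table.unassigned == []

    def test_duplicate_sequences_merged_with_summed_counts(self, tiny_index):
        reads = [
            ReadRecord("r1", LET7_MATURE, {"s1": 2}),
            ReadRecord("r2", LET7_MATURE, {"s1": 3}),
        ]
        with pytest.warns(UserWarning, match="merged"):
            table = call_isomirs(reads, tiny_index)
        (call,) = table.calls
        assert call.counts == {"s1": 5}

    def test_count_conservation(self, sim_config, sim_index):
        index, _ = sim_index
        reads, _ = simulate_reads(sim_config, index)
        table = call_isomirs(reads, index)
        una = {u[0] for u in table.unassigned}
        for s in table.samples:
            total_in = sum(r.count_per_sample.get(s, 0) for r in reads)
            total_out = sum(c.counts.get(s, 0) for c in table.calls)
            total_out += sum(
                r.count_per_sample.get(s, 0) for r in reads if r.read_id in una
            )
            assert total_in == total_out


class TestSummaries:
    def _mini_table(self, tiny_index):
        reads = [
            ReadRecord("r1", LET7_MATURE, {"s1": 10, "s2": 4}),
            ReadRecord("r2", LET7_MATURE[:-1], {"s1": 7, "s2": 0}),
            ReadRecord("r3", LET7_MATURE[:-2], {"s1": 1, "s2": 2}),
        ]
        return call_isomirs(reads, tiny_index)

    def test_class_counts(self, tiny_index):
        seq_counts, expr = isoform_class_counts(self._mini_table(tiny_index))
        assert seq_counts.to_dict() == {
            "exact": 1, "iso5": 0, "iso3": 2, "iso5_iso3": 0
        }
        assert expr.loc["iso3", "s1"] == 8
        assert expr.sum().sum() == 24  # conservation over classes

    def test_end_histogram_additivity(self, tiny_index):
        hists = end_position_summary(self._mini_table(tiny_index))
        assert hists["3p"].loc[-1, "s1"] == 7
        assert hists["3p"].loc[-2, "s2"] == 2
        assert (hists["5p"].to_numpy() == 0).all()

    def test_substitution_spectrum(self, tiny_index):
        read = LET7_MATURE[:9] + "G" + LET7_MATURE[10:]
        table = call_isomirs(
            [ReadRecord("r1", read, {"s1": 1}),
             ReadRecord("r2", LET7_MATURE, {"s1": 1})],
            tiny_index,
        )
        spectrum, per_pos = substitution_spectrum(table)
        assert spectrum["A>G"] == 1
        assert spectrum.drop("A>G").sum() == 0
        assert per_pos.to_dict() == {10: 1}

    def test_empty_spectrum(self, tiny_index):
        table = call_isomirs(
            [ReadRecord("r1", LET7_MATURE, {"s1": 1})], tiny_index
        )
        spectrum, per_pos = substitution_spectrum(table)
        assert spectrum.sum() == 0 and per_pos.empty


class TestAdar:
    def test_a_to_g_fraction(self, tiny_index):
        edited = LET7_MATURE[:9] + "G" + LET7_MATURE[10:]  # pos 10 is A
        table = call_isomirs(
            [ReadRecord("r1", LET7_MATURE, {"s1": 90}),
             ReadRecord("r2", edited, {"s1": 10})],
            tiny_index,
        )
        sites, summary = detect_adar(table, tiny_index)
        (site,) = sites
        assert site.position == 10
        assert site.fraction("s1") == pytest.approx(0.10)
        assert summary.loc["s1", "n_adar_matures"] == 1

    def test_non_a_substitution_is_not_adar(self, tiny_index):
        # position 13 is U in the mature; U->C is not an ADAR event
        assert LET7_MATURE[12] == "U"
        read = LET7_MATURE[:12] + "C" + LET7_MATURE[13:]
        table = call_isomirs([ReadRecord("r1", read, {"s1": 5})], tiny_index)
        sites, _ = detect_adar(table, tiny_index)
        assert sites == []

    def test_adar_calls_only_on_reference_A(self, sim_config, sim_index):
        index, _ = sim_index
        reads, _ = simulate_reads(sim_config, index)
        table = call_isomirs(reads, index)
        sites, _ = detect_adar(table, index)
        for site in sites:
            assert index.matures[site.mature_name].sequence[site.position - 1] == "A"


class TestAdarGroupComparison:
    def _summary(self, values):
        return pd.DataFrame(
            {"n_adar_matures": values},
            index=[f"{p}{r}" for p in ("A", "B") for r in (1, 2, 3)],
        )

    def _design(self):
        return pd.DataFrame(
            {"population": ["A"] * 3 + ["B"] * 3},
            index=[f"{p}{r}" for p in ("A", "B") for r in (1, 2, 3)],
        )

    def test_identical_groups_give_p_one(self):
        stat, p = compare_adar_between_groups(
            self._summary([5, 5, 5, 5, 5, 5]), self._design(), "A", "B"
        )
        assert stat == 0.0 and p == 1.0

    def test_separated_groups_significant(self):
        stat, p = compare_adar_between_groups(
            self._summary([10, 10, 10, 2, 2, 2]), self._design(), "A", "B"
        )
        assert p < 0.01

    def test_single_replicate_rejected(self):
        summary = self._summary([5, 5, 5, 5, 5, 5]).iloc[[0, 3, 4]]
        design = self._design().iloc[[0, 3, 4]]
        with pytest.raises(ValueError):
            compare_adar_between_groups(summary, design, "A", "B")
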