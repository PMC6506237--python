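"""Amplicon quantification: alignment, position table, editing statistics."""

import numpy as np
import pytest

from editscope import (
    EditingProfile,
    QualityModel,
    Scoring,
    SimConfig,
    align_reads_to_amplicon,
    count_edited_adenosines,
    error_corrected_frequency,
    indel_frequency,
    mean_a_to_i_frequency,
    nucleotide_percentage_table,
    protospacer_editing,
    simulate_amplicon_reads,
)
from editscope.amplicon import EmptyInputError, UndefinedStatisticError
from editscope.models import ERROR_FREE, IndelSpec, ReadBlock, ReadSet, seq_to_codes

import oracles


def make_readset(seq_strings, qual=30):
    by_len = {}
    for s in seq_strings:
        by_len.setdefault(len(s), []).append(seq_to_codes(s))
    blocks = [ReadBlock(np.array(rows),
                        np.full((len(rows), L), qual, dtype=np.uint8))
              for L, rows in by_len.items()]
    return ReadSet(blocks=blocks, name="t")


class TestAlignment:
    def test_reference_read_aligns_full_length(self, spec):
        result = align_reads_to_amplicon(make_readset([spec.sequence]), spec)
        reads = list(result.iter_aligned())
        assert len(reads) == 1
        assert reads[0].ops == [("M", len(spec))]
        assert reads[0].start == 0

    def test_three_nt_deletion_recovered(self, spec):
        read = spec.sequence[:100] + spec.sequence[103:]
        result = align_reads_to_amplicon(make_readset([read]), spec)
        [aln] = result.detailed
        dels = [(op, n) for op, n in aln.ops if op == "D"]
        assert dels == [("D", 3)]

    def test_insertion_recovered(self, spec):
        read = spec.sequence[:120] + "ACGT" + spec.sequence[120:]
        result = align_reads_to_amplicon(make_readset([read]), spec)
        [aln] = result.detailed
        assert ("I", 4) in aln.ops

    def test_scores_match_dp_oracle_on_mutated_reads(self, spec):
        """50 random 10%-mutated reads score identically to an independent
        textbook affine-gap DP."""
        rng = np.random.default_rng(17)
        sc = Scoring()
        for _ in range(50):
            codes = spec.codes.copy()
            k = max(1, int(0.1 * len(codes)))
            pos = rng.choice(len(codes), size=k, replace=False)
            codes[pos] = (codes[pos] + rng.integers(1, 4, size=k)) % 4
            read = "".join("ACGT"[c] for c in codes)
            result = align_reads_to_amplicon(
                make_readset([read]), spec, sc)
            [aln] = list(result.iter_aligned())
            expected = oracles.affine_dp_score(
                spec.sequence, read, sc.match, sc.mismatch,
                sc.gap_open, sc.gap_extend)
            assert aln.score == pytest.approx(expected)

    def test_certified_gapless_path_matches_dp(self, spec):
        """Low-mismatch reads taken by the certified shortcut score exactly
        as the full DP would."""
        rng = np.random.default_rng(3)
        sc = Scoring()
        for k in range(sc.certified_mismatch_limit + 1):
            codes = spec.codes.copy()
            pos = rng.choice(len(codes), size=k, replace=False)
            codes[pos] = (codes[pos] + 1) % 4
            read = "".join("ACGT"[c] for c in codes)
            result = align_reads_to_amplicon(make_readset([read]), spec, sc)
            assert result.gapless_seqs.shape[0] == 1  # took the shortcut
            [aln] = list(result.iter_aligned())
            expected = oracles.affine_dp_score(
                spec.sequence, read, sc.match, sc.mismatch,
                sc.gap_open, sc.gap_extend)
            assert aln.score == pytest.approx(expected)

    def test_low_score_reads_discarded_and_tallied(self, spec):
        junk = "ACGT" * (len(spec) // 4)  # unrelated sequence
        rng = np.random.default_rng(0)
        junk = "".join(rng.permutation(list(junk)))
        result = align_reads_to_amplicon(
            make_readset([spec.sequence, junk]), spec)
        assert len(result) == 1
        assert result.n_discarded == 1

    def test_empty_input_rejected(self, spec):
        with pytest.raises(EmptyInputError):
            align_reads_to_amplicon(ReadSet(blocks=[], name="x"), spec)


class TestPositionTable:
    def test_identical_reference_reads(self, spec):
        result = align_reads_to_amplicon(
            make_readset([spec.sequence] * 10), spec)
        table = nucleotide_percentage_table(result, spec)
        assert (table.depth == 10).all()
        for i, base in enumerate(spec.sequence):
            assert table.frequency(base)[i] == 1.0

    def test_minor_allele_fraction(self, spec):
        site = int(spec.adenosine_positions[5])
        edited = (spec.sequence[:site - 1] + "G" + spec.sequence[site:])
        reads = [spec.sequence] * 97 + [edited] * 3
        table = nucleotide_percentage_table(
            align_reads_to_amplicon(make_readset(reads), spec), spec)
        assert table.frequency("G")[site - 1] == pytest.approx(0.03)

    def test_column_sums_equal_depth(self, spec, q30):
        reads, _ = simulate_amplicon_reads(
            spec, EditingProfile.from_pairs(
                [(int(spec.adenosine_positions[0]), 0.3)]),
            q30, SimConfig(depth=500, seed=1, indel_rate=0.05))
        result = align_reads_to_amplicon(reads, spec)
        table = nucleotide_percentage_table(result, spec)
        assert (table.counts.sum(axis=0) == table.depth).all()
        freq_sum = sum(table.frequency(b)
                       for b in ("A", "C", "G", "T", "del"))
        np.testing.assert_allclose(freq_sum[table.depth > 0], 1.0,
                                   atol=1e-9)

    def test_table_matches_naive_recount_oracle(self, spec, q30):
        """DERIVED: mixed indel/mismatch read set recounted per read."""
        reads, _ = simulate_amplicon_reads(
            spec, EditingProfile.from_pairs(
                (int(p), 0.2) for p in spec.adenosine_positions[:5]),
            QualityModel(mean_q=20, sd_q=0),
            SimConfig(depth=80, seed=2, indel_rate=0.2,
                      indel_spec=IndelSpec(0, 2, "del")))
        result = align_reads_to_amplicon(reads, spec)
        table = nucleotide_percentage_table(result, spec)
        counts, ins = oracles.tally_position_table(
            result.iter_aligned(), len(spec))
        np.testing.assert_array_equal(table.counts, counts)
        np.testing.assert_array_equal(table.ins_starts, ins)


class TestEditingStatistics:
    def _table_with_g_freqs(self, spec, site_freqs, depth=10_000):
        """Build reads realizing exact G fractions at chosen A sites."""
        reads = []
        base = list(spec.sequence)
        counts = {p: int(round(f * depth)) for p, f in site_freqs.items()}
        for i in range(depth):
            row = base.copy()
            for p, k in counts.items():
                if i < k:
                    row[p - 1] = "G"
            reads.append("".join(row))
        return nucleotide_percentage_table(
            align_reads_to_amplicon(make_readset(reads), spec), spec)

    def test_countif_strict_threshold(self, spec):
        a = spec.adenosine_positions
        freqs = {int(a[0]): 0.002, int(a[1]): 0.0005,
                 int(a[2]): 0.01, int(a[3]): 0.0}
        table = self._table_with_g_freqs(spec, freqs)
        assert count_edited_adenosines(table, spec, 0.001) == 2

    def test_exactly_at_threshold_not_counted(self, spec):
        a = spec.adenosine_positions
        table = self._table_with_g_freqs(spec, {int(p): 0.001 for p in a[:4]},
                                         depth=1000)
        assert count_edited_adenosines(table, spec, 0.001) == 0

    def test_threshold_monotonicity(self, spec):
        a = spec.adenosine_positions
        table = self._table_with_g_freqs(
            spec, {int(p): f for p, f in zip(a, (0.0005, 0.002, 0.01, 0.05))})
        counts = [count_edited_adenosines(table, spec, t)
                  for t in (0.03, 0.005, 0.001, 0.0001)]
        assert counts == sorted(counts)

    def test_mean_frequency_includes_zeros(self, spec):
        a = spec.adenosine_positions
        table = self._table_with_g_freqs(
            spec, {int(a[0]): 0.01, int(a[1]): 0.03}, depth=1000)
        expected = (0.01 + 0.03) / len(a)
        assert mean_a_to_i_frequency(table, spec) == pytest.approx(expected)

    def test_mean_frequency_read_order_and_duplication_invariance(self, spec, q30):
        reads, _ = simulate_amplicon_reads(
            spec, EditingProfile.from_pairs(
                (int(p), 0.05) for p in spec.adenosine_positions[:8]),
            q30, SimConfig(depth=200, seed=4))
        block = reads.blocks[0]
        perm = np.random.default_rng(0).permutation(block.n)
        shuffled = ReadSet([ReadBlock(block.seqs[perm], block.quals[perm])])
        doubled = ReadSet([ReadBlock(np.vstack([block.seqs] * 2),
                                     np.vstack([block.quals] * 2))])
        vals = [mean_a_to_i_frequency(
                    nucleotide_percentage_table(
                        align_reads_to_amplicon(rs, spec), spec), spec)
                for rs in (reads, shuffled, doubled)]
        assert vals[0] == pytest.approx(vals[1])
        assert vals[0] == pytest.approx(vals[2])

    def test_protospacer_window_manual_pileup(self, spec):
        """DERIVED: 20-read hand-built pileup vs direct count."""
        target = spec.protospacer_to_amplicon(5)
        edited = (spec.sequence[:target - 1] + "G" + spec.sequence[target:])
        reads = [edited] * 7 + [spec.sequence] * 13
        table = nucleotide_percentage_table(
            align_reads_to_amplicon(make_readset(reads), spec), spec)
        pe = protospacer_editing(table, spec, target_position=5)
        assert pe.efficiency == pytest.approx(7 / 20)
        assert pe.per_position[5] == pytest.approx(7 / 20)

    def test_no_edited_reads_gives_zero_window(self, spec):
        table = nucleotide_percentage_table(
            align_reads_to_amplicon(make_readset([spec.sequence] * 5), spec),
            spec)
        pe = protospacer_editing(table, spec)
        assert pe.window_has_a
        assert all(v == 0.0 for v in pe.per_position.values())


class TestIndelFrequency:
    def test_no_indels_zero(self, spec):
        result = align_reads_to_amplicon(
            make_readset([spec.sequence] * 10), spec)
        assert indel_frequency(result, spec) == 0.0

    def test_three_of_hundred(self, spec):
        nick0 = spec.nick_position  # 0-based index of base 3' of the nick
        with_del = spec.sequence[:nick0] + spec.sequence[nick0 + 2:]
        reads = [spec.sequence] * 97 + [with_del] * 3
        result = align_reads_to_amplicon(make_readset(reads), spec)
        assert indel_frequency(result, spec) == pytest.approx(0.03)

    def test_indel_outside_window_not_counted(self, spec):
        far = 5 if spec.nick_position > 40 else len(spec) - 10
        with_del = spec.sequence[:far] + spec.sequence[far + 2:]
        reads = [spec.sequence] * 9 + [with_del]
        result = align_reads_to_amplicon(make_readset(reads), spec)
        assert indel_frequency(result, spec, window_width=30) == 0.0

    def test_matches_simulated_rate(self, spec, q30):
        cfg = SimConfig(depth=5000, seed=8, indel_rate=0.04,
                        indel_spec=IndelSpec(0, 2, "del"))
        reads, truth = simulate_amplicon_reads(spec, EditingProfile(()),
                                               q30, cfg)
        result = align_reads_to_amplicon(reads, spec)
        est = indel_frequency(result, spec)
        assert est == pytest.approx(truth.n_indel_reads / 5000, abs=1e-9)


class TestErrorCorrection:
    def test_inverts_error_channel(self):
        r, e = 0.013, 1e-3
        observed = r * (1 - e) + (1 - r) * e / 3
        assert error_corrected_frequency(observed, e) == pytest.approx(r)

    def test_clips_at_zero(self):
        assert error_corrected_frequency(0.0, 1e-3) == 0.0


class TestEstimatorConsistency:
    def test_per_site_frequency_converges_to_rate_plus_error(self, spec, q30):
        """At depth 200,000 the estimated per-site frequency matches
        true_rate + error contribution within 3 binomial SDs."""
        rate = 0.013
        sites = [int(p) for p in spec.adenosine_positions]
        reads, _ = simulate_amplicon_reads(
            spec, EditingProfile.from_pairs((p, rate) for p in sites),
            q30, SimConfig(depth=200_000, seed=12))
        result = align_reads_to_amplicon(reads, spec)
        table = nucleotide_percentage_table(result, spec)
        e = 1e-3
        expected = rate * (1 - e) + (1 - rate) * e / 3
        sd = np.sqrt(expected * (1 - expected) / 200_000)
        g = table.frequency("G")[np.array(sites) - 1]
        assert (np.abs(g - expected) <= 3 * sd + 1e-12).mean() >= 0.95
        # and the mean across sites is far tighter
        mean_sd = sd / np.sqrt(len(sites))
        assert abs(g.mean() - expected) <= 4 * mean_sd
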