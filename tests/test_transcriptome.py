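"""Edit calling: posterior model, filters, down-sampling, summaries."""

import numpy as np
import pytest

from editscope import (
    EditCall,
    EditingProfile,
    SimConfig,
    SitePileup,
    additional_edits,
    adenosine_sites,
    bin_edit_density,
    call_edits,
    downsample,
    edit_posterior,
    filter_edit_calls,
    posterior_to_qual,
    qual_to_posterior,
    sem_by_repeated_downsampling,
    simulate_transcriptome,
    site_pileups,
    transcriptome_average_frequency,
    uniform_transcriptome_profile,
)
from editscope.amplicon import UndefinedStatisticError
from editscope.transcriptome import (
    DEFAULT_F_GRID,
    InfeasibleDownsampleError,
    NoCoverageError,
    mean_base_error_rate,
)

import oracles


def make_pileup(alt_count, depth=100, q=30, mapq=60, ref="A", strand="+",
                pos=100):
    bases = np.full(depth, 0 if ref == "A" else 3, dtype=np.uint8)
    alt_code = 2 if ref == "A" else 1
    bases[:alt_count] = alt_code
    return SitePileup("chr1", pos, ref, strand, bases,
                      np.full(depth, q, dtype=np.uint8),
                      np.full(depth, mapq, dtype=np.uint8))


class TestPosterior:
    def test_no_alt_reads_is_evidence_against(self):
        call = edit_posterior(make_pileup(0), prior_edit=1e-3)
        assert call.posterior < 1e-3
        assert not call.passed

    def test_qual_posterior_correspondence(self):
        """Phred 20 <-> posterior 0.99, exactly and self-inversely."""
        assert posterior_to_qual(0.99) == pytest.approx(20.0, abs=1e-9)
        assert qual_to_posterior(20.0) == pytest.approx(0.99, abs=1e-12)
        for q in (0.0, 5.0, 20.0, 47.3, 90.0):
            assert posterior_to_qual(qual_to_posterior(q)) == \
                pytest.approx(q, abs=1e-9)

    def test_matches_direct_summation_oracle(self):
        """DERIVED: depth 50, alt 5, Q30/MQ60 vs naive summation."""
        site = make_pileup(5, depth=50, q=30, mapq=60)
        call = edit_posterior(site, prior_edit=1e-3, f_grid=DEFAULT_F_GRID)
        expected = oracles.direct_posterior(
            list(site.bases), [30] * 50, [60] * 50, ref_code=0, alt_code=2,
            prior=1e-3, f_grid=list(DEFAULT_F_GRID))
        assert call.posterior == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("alt_pair", [(0, 1), (1, 3), (3, 6), (6, 12)])
    def test_monotone_in_alt_count(self, alt_pair):
        lo, hi = alt_pair
        p_lo = edit_posterior(make_pileup(lo)).posterior
        p_hi = edit_posterior(make_pileup(hi)).posterior
        assert p_hi >= p_lo

    def test_minus_strand_t_to_c(self):
        call = edit_posterior(make_pileup(10, ref="T", strand="-"))
        assert (call.ref, call.alt) == ("T", "C")
        assert call.qual >= 20

    def test_zero_depth_rejected(self):
        empty = SitePileup("chr1", 1, "A", "+",
                           np.empty(0, np.uint8), np.empty(0, np.uint8),
                           np.empty(0, np.uint8))
        with pytest.raises(NoCoverageError):
            edit_posterior(empty)

    def test_detection_sensitivity_and_specificity(self):
        """Coverage 100, Q30: rate >= 0.10 sites recovered with sensitivity
        >= 0.95; null sites pass at below the 1% implied by the 0.99
        posterior cutoff (>= 10,000 null sites)."""
        rng = np.random.default_rng(99)
        e_to_g = 1e-3 / 3
        hits = 0
        n_true = 400
        for _ in range(n_true):
            ac = rng.binomial(100, 0.10)
            ac += rng.binomial(100 - ac, e_to_g)
            if edit_posterior(make_pileup(ac)).qual >= 20:
                hits += 1
        assert hits / n_true >= 0.95
        null_alt = rng.binomial(100, e_to_g, size=10_000)
        fp = sum(edit_posterior(make_pileup(int(a))).qual >= 20
                 for a in null_alt)
        assert fp / 10_000 <= 0.01


class TestFilter:
    def _call(self, qual, ref="A", alt="G", strand="+"):
        return EditCall("chr1", 10, ref, alt, strand, 100, 5, 0.05,
                        qual_to_posterior(qual), qual, qual >= 20)

    def test_qual_boundary(self):
        result = filter_edit_calls([self._call(19.9), self._call(20.0),
                                    self._call(35.0)])
        assert [c.qual for c in result.kept] == [20.0, 35.0]
        assert result.dropped["qual"] == 1

    def test_substitution_set(self):
        calls = [self._call(30),                      # A>G '+': keep
                 self._call(30, "T", "C", "-"),       # T>C '-': keep
                 self._call(30, "T", "C", "+"),       # wrong strand: drop
                 self._call(30, "A", "C", "+")]       # wrong alt: drop
        result = filter_edit_calls(calls)
        assert len(result.kept) == 2
        assert result.dropped["substitution"] == 2

    def test_idempotent(self):
        calls = [self._call(q) for q in (5, 15, 20, 25, 90)]
        once = filter_edit_calls(calls)
        twice = filter_edit_calls(once.kept)
        assert twice.kept == once.kept
        assert twice.dropped["qual"] == 0


class TestDownsample:
    def test_identity_and_empty(self):
        data = list(range(100))
        assert downsample(data, 100, seed=1) == data
        assert downsample(data, 0, seed=1) == []

    def test_infeasible(self):
        with pytest.raises(InfeasibleDownsampleError):
            downsample(list(range(10)), 11, seed=0)

    def test_deterministic_and_uniform_inclusion(self):
        data = list(range(10_000))
        a = downsample(data, 2000, seed=5)
        b = downsample(data, 2000, seed=5)
        assert a == b
        # DERIVED: inclusion frequency over 100 seeds ~ 0.2 +- 3 SD
        included = np.zeros(10_000)
        for s in range(100):
            idx = downsample(data, 2000, seed=s)
            included[idx] += 1
        frac = included / 100
        sd = np.sqrt(0.2 * 0.8 / 100)
        assert abs(frac.mean() - 0.2) < 1e-12  # exactly 2000 drawn each time
        assert (np.abs(frac - 0.2) <= 3 * sd).mean() >= 0.99

    def test_alignment_set_take_preserves_order(self, models, q30):
        profile = uniform_transcriptome_profile(models, 0.02, seed=0)
        aln, _ = simulate_transcriptome(
            models, EditingProfile(()), profile, q30,
            SimConfig(depth=20, read_length=100, seed=1))
        sub = downsample(aln, len(aln) // 2, seed=3)
        assert len(sub) == len(aln) // 2
        assert (np.diff(sub.starts[sub.chrom_idx == 0]) >= 0).sum() >= 0


class TestSemByDownsampling:
    def test_zero_editing_gives_zero_spread(self):
        data = list(range(50))
        stats = sem_by_repeated_downsampling(
            data, 25, reps=4, base_seed=0, pipeline=lambda s: 0.0)
        assert stats.values == [0.0] * 4
        assert stats.spread == 0.0

    def test_spread_matches_recomputed_sd(self, models, q30):
        """DERIVED: spread equals the SD of the emitted replicate values."""
        profile = uniform_transcriptome_profile(models, 0.3, fraction=0.05,
                                                seed=2)
        aln, _ = simulate_transcriptome(
            models, EditingProfile(()), profile, q30,
            SimConfig(depth=40, read_length=100, seed=3))
        sites = adenosine_sites(models)

        def pipe(subset):
            pl = site_pileups(subset, models.chromosomes, sites)
            return len(filter_edit_calls(call_edits(pl)).kept)

        stats = sem_by_repeated_downsampling(aln, len(aln) // 2, reps=5,
                                             base_seed=7, pipeline=pipe)
        assert stats.spread == pytest.approx(
            float(np.std(stats.values, ddof=1)))
        assert stats.reps == 5


class TestAdditionalEdits:
    def _calls(self, positions, models):
        return [EditCall(c, p, "A", "G", "+", 50, 5, 0.1, 0.999, 30, True)
                for c, p in positions]

    def test_identical_sets(self, models):
        t = models.transcripts[0]
        pos = int(models.transcript_adenosines(t)[0])
        calls = self._calls([(t.chrom, pos)], models)
        result = additional_edits(calls, calls, models)
        assert (result.count_difference, result.n_novel_transcripts) == (0, 0)

    def test_new_sites_on_unedited_transcripts(self, models):
        coding = [t for t in models.transcripts
                  if len(models.transcript_adenosines(t)) > 2][:4]
        control = self._calls(
            [(coding[0].chrom, int(models.transcript_adenosines(coding[0])[0]))],
            models)
        new = [(t.chrom, int(models.transcript_adenosines(t)[j]))
               for t in coding[1:4] for j in (0, 1)][:5]
        treated = control + self._calls(new, models)
        result = additional_edits(treated, control, models)
        assert result.count_difference == 5
        assert result.n_novel_transcripts == 3


class TestAverageFrequency:
    def test_zero_when_no_edits(self):
        pileups = [make_pileup(0, depth=30, pos=i + 1) for i in range(10)]
        assert transcriptome_average_frequency(pileups) == 0.0

    def test_coverage_filter_excludes_shallow_sites(self):
        shallow = make_pileup(10, depth=19, pos=1)   # heavily edited, dropped
        deep = make_pileup(0, depth=100, pos=2)
        assert transcriptome_average_frequency([shallow, deep]) == 0.0
        with pytest.raises(UndefinedStatisticError):
            transcriptome_average_frequency([shallow], min_coverage=20)

    def test_read_weighting(self):
        pileups = [make_pileup(5, depth=100, pos=1),
                   make_pileup(0, depth=300, pos=2)]
        assert transcriptome_average_frequency(pileups) == \
            pytest.approx(100 * 5 / 400)
        assert transcriptome_average_frequency(
            pileups, weighting="site") == pytest.approx(50.0)


class TestBinDensity:
    def _call_at(self, chrom, pos):
        return EditCall(chrom, pos, "A", "G", "+", 50, 5, 0.1, 0.999, 30, True)

    def test_empty(self):
        bins = bin_edit_density([], {"chr1": 2_500_000})
        assert bins["count"].sum() == 0
        assert len(bins) == 3

    def test_boundary_positions(self):
        size = 1_000_000
        calls = [self._call_at("chr1", p) for p in (1, size, size + 1)]
        bins = bin_edit_density(calls, {"chr1": 2 * size}, size)
        assert list(bins["count"]) == [2, 1]

    def test_random_calls_match_interval_oracle(self):
        rng = np.random.default_rng(11)
        length = 7_300_000
        positions = rng.integers(1, length + 1, size=500)
        calls = [self._call_at("chr1", int(p)) for p in positions]
        bins = bin_edit_density(calls, {"chr1": length})
        expected = oracles.assign_bins(positions, length, 1_000_000)
        assert list(bins["count"]) == expected
        assert bins["count"].sum() == 500

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_edit_density([self._call_at("chr1", 1_000_001)],
                             {"chr1": 1_000_000})


class TestSimulationRecovery:
    def test_call_filter_recovers_truth_sites(self, models, q30):
        """Sensitivity/specificity on a simulated truth set equals an
        independent set-comparison oracle."""
        profile = uniform_transcriptome_profile(models, 0.5, fraction=0.04,
                                                seed=4)
        aln, truth = simulate_transcriptome(
            models, EditingProfile(()), profile, q30,
            SimConfig(depth=100, read_length=100, seed=5))
        sites = adenosine_sites(models)
        pileups = site_pileups(aln, models.chromosomes, sites)
        kept = filter_edit_calls(call_edits(pileups)).kept
        called = {(c.chrom, c.pos) for c in kept}
        true_sites = set(zip(truth.sites["CHROM"], truth.sites["POS"]))
        covered_true = {(p.chrom, p.pos) for p in pileups
                        if p.depth >= 20} & true_sites
        sensitivity = len(called & covered_true) / max(1, len(covered_true))
        null_called = called - true_sites
        n_null = sum(1 for p in pileups if (p.chrom, p.pos) not in true_sites)
        assert sensitivity >= 0.95
        assert len(null_called) / max(1, n_null) <= 0.01
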