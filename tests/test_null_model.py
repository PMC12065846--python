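import numpy as np
import pytest
from scipy import stats

from rtdsbr.annotations import GenomicInterval, IntronRecord, build_intron_index
from rtdsbr.deletion_io import DeletionCall, DeletionCohort
from rtdsbr.null_model import (
    LengthDistribution,
    NullModelError,
    SimulationConfig,
    SpaceWeights,
    count_wids,
    empirical_pvalue,
    fit_length_distribution,
    fit_space_weights,
    run_null_ensemble,
    simulate_cohort,
    simulate_deletion,
)
from rtdsbr.wid_caller import MarginPolicy


def _cohort(lengths, start=0):
    calls = []
    for i, ln in enumerate(lengths):
        s = start + i * 1000
        calls.append(DeletionCall(f"S{i}", "chr1", GenomicInterval("chr1", s, s + ln)))
    return DeletionCohort(calls)


class TestLengthDistribution:
    def test_degenerate(self):
        d = fit_length_distribution(_cohort([5, 5, 5]))
        assert d.support == (5,) and d.probs == (1.0,)

    def test_counting(self):
        d = fit_length_distribution(_cohort([3, 3, 7, 10]))
        assert dict(zip(d.support, d.probs)) == {3: 0.5, 7: 0.25, 10: 0.25}

    def test_empty_cohort_rejected(self):
        with pytest.raises(NullModelError):
            fit_length_distribution(DeletionCohort([]))


class TestSpaceWeights:
    UNITS = (GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 5000, 6000))

    def test_start_counting(self):
        calls = [DeletionCall("S", "chr1", GenomicInterval("chr1", s, s + 10))
                 for s in list(range(0, 300, 10)) + list(range(5000, 5100, 10))]
        w = fit_space_weights(DeletionCohort(calls), self.UNITS)
        assert w.weights == (0.75, 0.25)

    def test_single_unit_weight_one_and_outside_excluded(self):
        calls = [DeletionCall("S", "chr1", GenomicInterval("chr1", 10, 20)),
                 DeletionCall("S", "chr1", GenomicInterval("chr1", 90_000, 90_010))]
        w = fit_space_weights(DeletionCohort(calls), self.UNITS[:1])
        assert w.weights == (1.0,)

    def test_no_inside_starts_is_error(self):
        calls = [DeletionCall("S", "chr1", GenomicInterval("chr1", 90_000, 90_010))]
        with pytest.raises(NullModelError):
            fit_space_weights(DeletionCohort(calls), self.UNITS)

    def test_weights_sum_to_one_on_random_inputs(self):
        rng = np.random.default_rng(3)
        units = tuple(GenomicInterval("chr1", s, s + 500) for s in range(0, 50_000, 1000))
        calls = [DeletionCall("S", "chr1", GenomicInterval("chr1", int(s), int(s) + 5))
                 for s in rng.integers(0, 50_000, size=400)]
        w = fit_space_weights(DeletionCohort(calls), units)
        assert abs(sum(w.weights) - 1.0) < 1e-12


ONE_UNIT = SpaceWeights(units=(GenomicInterval("chr1", 0, 100),), weights=(1.0,))
LEN10 = LengthDistribution(support=(10,), probs=(1.0,))


class TestSimulateDeletion:
    def test_always_valid_in_roomy_unit(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = simulate_deletion(ONE_UNIT, LEN10, rng)
            assert 0 <= d.interval.start <= 90 and d.length == 10

    def test_impossible_placement_raises(self):
        w = SpaceWeights(units=(GenomicInterval("chr1", 0, 20),), weights=(1.0,))
        big = LengthDistribution(support=(50,), probs=(1.0,))
        with pytest.raises(NullModelError, match="max_attempts"):
            simulate_deletion(w, big, np.random.default_rng(0), max_attempts=20)

    def test_spillover_into_next_interval_allowed_only_in_permissive_mode(self):
        units = (GenomicInterval("chr1", 0, 20), GenomicInterval("chr1", 25, 100))
        w = SpaceWeights(units=units, weights=(1.0, 0.0))
        ln = LengthDistribution(support=(30,), probs=(1.0,))
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = simulate_deletion(w, ln, rng)
            # start in the first unit; end must land inside the next interval
            assert 0 <= d.interval.start < 20
            assert 25 <= d.interval.end <= 100
        with pytest.raises(NullModelError):
            # strict mode: end must equal next start (25) exactly; length 30
            # from starts 0..19 gives ends 30..49, never 25
            simulate_deletion(w, ln, np.random.default_rng(2),
                              strict_boundary=True, max_attempts=50)

    def test_start_uniform_within_valid_range(self):
        cfg = SimulationConfig(mode="panel", cohort_size=100_000, n_cohorts=1, base_seed=4)
        cohort = simulate_cohort(cfg, ONE_UNIT, LEN10, cohort_index=0)
        starts = np.array([c.interval.start for c in cohort])
        observed = np.bincount(starts, minlength=91)
        assert observed.sum() == 100_000 and starts.max() <= 90
        p = stats.chisquare(observed).pvalue
        assert p > 0.001

    def test_length_marginal_matches_fitted_pmf(self):
        # an adjacent spill-over interval makes every draw valid, so the
        # simulated marginal is the fitted PMF itself (rejection-free regime)
        units = (GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200))
        w = SpaceWeights(units=units, weights=(1.0, 0.0))
        lengths = LengthDistribution(support=(3, 7, 10), probs=(0.5, 0.25, 0.25))
        cfg = SimulationConfig(mode="panel", cohort_size=100_000, n_cohorts=1, base_seed=6)
        cohort = simulate_cohort(cfg, w, lengths, cohort_index=0)
        observed = np.array([sum(1 for c in cohort if c.length == s) for s in lengths.support])
        expected = np.array(lengths.probs) * len(cohort)
        assert stats.chisquare(observed, expected).pvalue > 0.001


class TestSimulateCohort:
    def test_exact_size_and_constraint(self):
        cfg = SimulationConfig(mode="panel", cohort_size=100, n_cohorts=1, base_seed=0)
        cohort = simulate_cohort(cfg, ONE_UNIT, LEN10, cohort_index=0)
        assert len(cohort) == 100
        assert all(c.interval.end <= 100 for c in cohort)

    def test_deterministic_per_seed_and_index(self):
        cfg = SimulationConfig(mode="panel", cohort_size=50, n_cohorts=1, base_seed=9)
        a = simulate_cohort(cfg, ONE_UNIT, LEN10, cohort_index=3)
        b = simulate_cohort(cfg, ONE_UNIT, LEN10, cohort_index=3)
        assert [(c.interval.start, c.interval.end) for c in a] == [
            (c.interval.start, c.interval.end) for c in b
        ]
        c_ = simulate_cohort(cfg, ONE_UNIT, LEN10, cohort_index=4)
        assert [(c.interval.start, c.interval.end) for c in a] != [
            (x.interval.start, x.interval.end) for x in c_
        ]
        cfg2 = SimulationConfig(mode="panel", cohort_size=50, n_cohorts=1, base_seed=10)
        d = simulate_cohort(cfg2, ONE_UNIT, LEN10, cohort_index=3)
        assert [(c.interval.start, c.interval.end) for c in a] != [
            (x.interval.start, x.interval.end) for x in d
        ]

    def test_gene_mode_keeps_deletion_inside_unit(self):
        units = (GenomicInterval("chr1", 0, 40), GenomicInterval("chr1", 45, 300))
        w = SpaceWeights(units=units, weights=(0.5, 0.5))
        ln = LengthDistribution(support=(30,), probs=(1.0,))
        cfg = SimulationConfig(mode="gene", cohort_size=200, n_cohorts=1, base_seed=2)
        cohort = simulate_cohort(cfg, w, ln, cohort_index=0)
        for c in cohort:
            assert any(u.start <= c.interval.start and c.interval.end <= u.end for u in units)


class TestEmpiricalPValue:
    def test_observed_zero_gives_one(self):
        assert empirical_pvalue([0, 1, 2], 0) == 1.0

    def test_all_equal_gives_one(self):
        assert empirical_pvalue([4, 4, 4], 4) == 1.0

    def test_tail_count_arithmetic(self):
        assert empirical_pvalue([0, 0, 1, 2, 5], 2) == pytest.approx(2 / 5)

    def test_add_one_estimator_never_zero(self):
        counts = [0] * 9998 + [4, 4]
        assert empirical_pvalue(counts, 5, "plain") == 0.0
        # (k+1)/(N+1) with k=0 tail hits over N=10,000 cohorts
        assert empirical_pvalue(counts, 5, "add_one") == pytest.approx(1 / 10_001)

    def test_monotone_in_observed(self):
        counts = [0, 1, 1, 3, 7]
        ps = [empirical_pvalue(counts, o) for o in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_empty_counts_rejected(self):
        with pytest.raises(NullModelError):
            empirical_pvalue([], 1)


class TestEnsemble:
    def test_ensemble_reproducible_and_seed_sensitive(self):
        # toy space with a high per-deletion WID probability (5/91) so that
        # per-cohort counts carry enough variation to distinguish seeds
        intron = IntronRecord("G", "T", "chr1", GenomicInterval("chr1", 30, 40), 1, 1, 2)
        idx = build_intron_index([intron])
        observed = DeletionCohort(
            [DeletionCall(f"S{i}", "chr1", GenomicInterval("chr1", 10 + i, 20 + i))
             for i in range(30)]
        )
        units = (GenomicInterval("chr1", 0, 100),)
        cfg = SimulationConfig(mode="panel", cohort_size=200, n_cohorts=20, base_seed=5)
        r1 = run_null_ensemble(cfg, observed, units, idx)
        r2 = run_null_ensemble(cfg, observed, units, idx)
        assert np.array_equal(r1.wid_counts, r2.wid_counts)
        cfg3 = SimulationConfig(mode="panel", cohort_size=200, n_cohorts=20, base_seed=6)
        r3 = run_null_ensemble(cfg3, observed, units, idx)
        assert not np.array_equal(r1.wid_counts, r3.wid_counts)

    def test_gene_mode_prefilters_observed_cohort(self, gene_space):
        # all observed deletions <= 10 bp vanish under the >10 bp pre-filter
        idx = gene_space.intron_index()
        units = [m.span() for m in gene_space.transcripts]
        short = DeletionCohort(
            [DeletionCall("S", u.contig, GenomicInterval(u.contig, u.start, u.start + 5))
             for u in units]
        )
        cfg = SimulationConfig(mode="gene", cohort_size=10, n_cohorts=2, base_seed=0)
        with pytest.raises(NullModelError):  # empty after filtering -> unfittable
            run_null_ensemble(cfg, short, units, idx)
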