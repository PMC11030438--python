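"""Outcome statistics: SFS, LD profile, fixed fractions, fixation-time histograms."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from wfscale import (
    compute_ld_profile,
    compute_r2,
    compute_sfs,
    fixation_time_histogram,
    fraction_fixed,
    reference_bin_width,
    run_replicate,
    summarize_replicate,
)
from wfscale.engine import SampleHaplotypes
from wfscale.summaries import N_LD_BINS, N_TIME_BINS, LD_SUBSAMPLE_CAP


def _sample(matrix, positions=None, mclass=None, L=10_000):
    matrix = np.asarray(matrix, dtype=np.uint8)
    m = matrix.shape[1]
    if positions is None:
        positions = np.linspace(0, L - 1, m).astype(np.int64)
    if mclass is None:
        mclass = np.zeros(m, dtype=np.int8)
    return SampleHaplotypes(
        n_individuals=matrix.shape[0] // 2, L=L,
        positions=np.asarray(positions, dtype=np.int64),
        mclass=np.asarray(mclass, dtype=np.int8),
        s=np.zeros(m), matrix=matrix)


class TestSFS:
    def test_singleton_in_four_haplotypes(self):
        sample = _sample([[1], [0], [0], [0]])
        assert list(compute_sfs(sample, "neutral").counts) == [1, 0, 0]

    def test_monomorphic_sample_all_zero(self):
        sample = _sample([[1, 0], [1, 0], [1, 0], [1, 0]])
        assert compute_sfs(sample, "neutral").counts.sum() == 0

    def test_length_199_for_100_individuals(self):
        sample = _sample(np.zeros((200, 3)))
        assert len(compute_sfs(sample, "neutral").counts) == 199

    def test_classes_kept_separate(self):
        sample = _sample([[1, 1], [0, 1], [0, 0], [0, 0]], mclass=[0, 2])
        assert list(compute_sfs(sample, "neutral").counts) == [1, 0, 0]
        assert list(compute_sfs(sample, "deleterious").counts) == [0, 1, 0]

    def test_entries_sum_to_segregating_count(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        two_n = res.sample.matrix.shape[0]
        dac = res.sample.matrix.sum(axis=0)
        for code, name in enumerate(("neutral", "beneficial", "deleterious")):
            seg = ((res.sample.mclass == code) & (dac > 0) & (dac < two_n)).sum()
            assert compute_sfs(res.sample, name).counts.sum() == seg

    def test_neutral_sfs_follows_one_over_k(self, neutral_model):
        """Aggregated neutral SFS ~ 1/k over 100 replicates (n=10 sampled
        individuals): chi-square goodness of fit not rejected at alpha=0.01.

        Linked sites make the per-cell counts overdispersed relative to the
        multinomial null (var/mean ~ 2-3 here), so the statistic is divided
        by the quasi-likelihood inflation factor c-hat estimated from the
        across-replicate variance before comparison.
        """
        n_rep = 100
        per_rep = []
        for seed in range(300, 300 + n_rep):
            res = run_replicate(neutral_model, seed=seed, sample_n=10)
            per_rep.append(compute_sfs(res.sample, "neutral").counts)
        per_rep = np.asarray(per_rep)
        agg = per_rep.sum(axis=0)
        k = np.arange(1, len(agg) + 1)
        expected = (1.0 / k) / (1.0 / k).sum() * agg.sum()
        assert expected.min() >= 5
        chi2 = (((agg - expected) ** 2) / expected).sum()
        c_hat = max(1.0, float(np.mean(per_rep.var(axis=0) / per_rep.mean(axis=0))))
        p = stats.chi2.sf(chi2 / c_hat, df=len(agg) - 1)
        assert p > 0.01


class TestR2:
    def test_perfect_coupling(self):
        assert compute_r2([1, 1, 0, 0], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_equal_gamete_frequencies_give_zero(self):
        assert compute_r2([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_monomorphic_column_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            compute_r2([1, 1, 1, 1], [1, 0, 1, 0])

    def test_matches_gamete_count_table(self, rng):
        """r^2 from the 2x2 gamete count table (brute force) on random
        8-haplotype two-site configurations."""
        for _ in range(50):
            a = rng.integers(0, 2, size=8)
            b = rng.integers(0, 2, size=8)
            if a.min() == a.max() or b.min() == b.max():
                continue
            n = len(a)
            n_ab = {(i, j): int(((a == i) & (b == j)).sum())
                    for i in (0, 1) for j in (0, 1)}
            p_a = (n_ab[(1, 0)] + n_ab[(1, 1)]) / n
            p_b = (n_ab[(0, 1)] + n_ab[(1, 1)]) / n
            d = n_ab[(1, 1)] / n - p_a * p_b
            want = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
            assert compute_r2(a, b) == pytest.approx(want)


class TestLDProfile:
    def test_single_pair_lands_in_distance_bin(self):
        L = 10_000
        # distance 0.3*L -> bin 15; both sites in perfect coupling
        sample = _sample([[1, 1], [1, 1], [0, 0], [0, 0]],
                         positions=[1000, 1000 + int(0.3 * L)], L=L)
        prof = compute_ld_profile(sample)
        assert prof.pair_counts[15] == 1
        assert prof.bin_means[15] == pytest.approx(1.0)
        assert prof.pair_counts.sum() == 1
        assert np.isnan(np.delete(prof.bin_means, 15)).all()

    def test_exactly_50_bins_and_subsample_cap(self, rng):
        m = 6000
        matrix = rng.integers(0, 2, size=(8, m))
        # ensure all columns polymorphic
        matrix[0] = 1
        matrix[1] = 0
        sample = _sample(matrix, positions=rng.choice(100_000, m, replace=False), L=100_000)
        prof = compute_ld_profile(sample, rng=rng)
        assert len(prof.bin_means) == N_LD_BINS
        assert prof.pair_counts.sum() == math.comb(LD_SUBSAMPLE_CAP, 2)

    def test_matches_brute_force_on_ten_mutations(self, rng):
        L = 50_000
        matrix = rng.integers(0, 2, size=(10, 10))
        matrix[0], matrix[1] = 1, 0  # keep all columns polymorphic
        positions = np.sort(rng.choice(L, 10, replace=False))
        sample = _sample(matrix, positions=positions, L=L)
        prof = compute_ld_profile(sample)
        sums = np.zeros(N_LD_BINS)
        counts = np.zeros(N_LD_BINS)
        for i, j in itertools.combinations(range(10), 2):
            r2 = compute_r2(matrix[:, i], matrix[:, j])
            b = min(int(abs(positions[i] - positions[j]) // (L / N_LD_BINS)), N_LD_BINS - 1)
            sums[b] += r2
            counts[b] += 1
        np.testing.assert_array_equal(prof.pair_counts, counts)
        good = counts > 0
        np.testing.assert_allclose(prof.bin_means[good], sums[good] / counts[good])
        assert prof.pair_counts.sum() == math.comb(10, 2)


class TestFractionFixed:
    def test_arithmetic(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.arisen[0], res.fixed[0] = 10_000, 5
        res.Q = 10.0
        assert fraction_fixed(res)["neutral"].corrected_fraction == pytest.approx(5e-5)

    def test_zero_arisen_flagged_undefined(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.arisen[1], res.fixed[1] = 0, 0
        est = fraction_fixed(res)["beneficial"]
        assert not est.defined
        assert math.isnan(est.corrected_fraction)


class TestFixationTimeHistogram:
    def test_reference_bin_width_is_max_over_20(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.fixation_classes = np.array([0, 0], dtype=np.int8)
        res.fixation_times = np.array([4_000.0, 10_000.0])
        assert reference_bin_width(res, "neutral") == pytest.approx(500.0)
        res.fixation_times = np.array([10.0, 20.0])
        assert reference_bin_width(res, "neutral") == pytest.approx(1.0)

    def test_no_fixations_in_reference_is_an_error(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.fixation_classes = np.empty(0, dtype=np.int8)
        res.fixation_times = np.empty(0)
        with pytest.raises(ValueError, match="another reference"):
            reference_bin_width(res, "neutral")

    def test_half_open_bins(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.fixation_classes = np.zeros(3, dtype=np.int8)
        res.fixation_times = np.array([100.0, 499.0, 500.0])
        counts = fixation_time_histogram(res, "neutral", 500.0).counts
        assert counts[0] == 2 and counts[1] == 1
        assert counts.sum() == 3

    def test_empty_class_gives_all_zero(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.fixation_classes = np.empty(0, dtype=np.int8)
        res.fixation_times = np.empty(0)
        counts = fixation_time_histogram(res, "neutral", 500.0).counts
        assert counts.sum() == 0 and len(counts) == N_TIME_BINS + 1

    def test_overflow_bin_collects_beyond_reference_max(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        res.fixation_classes = np.zeros(2, dtype=np.int8)
        res.fixation_times = np.array([9_999.0, 60_000.0])
        counts = fixation_time_histogram(res, "neutral", 500.0).counts
        assert counts[N_TIME_BINS] == 1  # overflow

    def test_q_corrected_time_binning(self, tiny_selected_model):
        # raw scaled time 30 at Q=20 -> corrected 600 -> bin 1 at width 500
        res = run_replicate(tiny_selected_model, seed=8)
        res.Q = 20.0
        res.fixation_classes = np.zeros(1, dtype=np.int8)
        res.fixation_times = np.array([30.0 * 20])
        counts = fixation_time_histogram(res, "neutral", 500.0).counts
        assert counts[1] == 1


class TestSummarizeReplicate:
    def test_histogram_total_matches_fixation_count(self, tiny_selected_model):
        res = run_replicate(tiny_selected_model, seed=8)
        widths = {c: 50.0 for c in ("neutral", "beneficial", "deleterious")}
        s = summarize_replicate(res, widths)
        for code, name in enumerate(("neutral", "beneficial", "deleterious")):
            assert s.fixation_hist[name].sum() == res.fixed[code]

    def test_json_round_trip(self, tiny_selected_model, tmp_path):
        from wfscale.summaries import ReplicateSummary
        res = run_replicate(tiny_selected_model, seed=8)
        s = summarize_replicate(res, {"neutral": 50.0})
        path = tmp_path / "s.json"
        s.save_json(path)
        back = ReplicateSummary.load_json(path)
        assert back.classes == s.classes
        np.testing.assert_allclose(back.ld_bin_means, s.ld_bin_means)
        for c in s.classes:
            np.testing.assert_array_equal(back.sfs[c], s.sfs[c])
        np.testing.assert_equal(back.mean_fixation_time, s.mean_fixation_time)
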