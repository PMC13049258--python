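"""Sampling-scheme construction: coverage, TR histories, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sero import (
    SchemeConfig,
    compute_tr_matrix,
    generate_direct_scheme,
    generate_sero_scheme,
    generate_slice_shift_scheme,
    scheme_statistics,
)
from sero.schemes import (
    FRESH_SUBVOXEL_TR_OFFSET,
    AcquisitionScheme,
    InfeasibleSchemeError,
    SchemeError,
)


def brute_force_tr(start, times, k, n):
    """O(m^2 n) last-excitation scan, independent of the production code."""
    m = len(start)
    TR = np.full((m, n), np.nan)
    first = np.zeros((m, n), dtype=bool)
    for j in range(m):
        for i in range(start[j], min(start[j] + k, n)):
            prev = [times[l] for l in range(j) if start[l] <= i < start[l] + k]
            if prev:
                TR[j, i] = times[j] - max(prev)
            else:
                TR[j, i] = np.inf
                first[j, i] = True
    return TR, first


class TestTRMatrix:
    def test_consecutive_overlap_gives_shot_spacing(self):
        # two shots 150 ms apart sharing position 7
        TR, first = compute_tr_matrix([4, 7], [0.0, 0.15], k=4, n=12)
        assert TR[1, 7] == pytest.approx(0.15)
        assert not first[1, 7]

    def test_single_coverage_is_first_coverage(self):
        TR, first = compute_tr_matrix([2], [0.0], k=2, n=6)
        assert first[0, 2] and first[0, 3]
        assert np.isinf(TR[0, 2])

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n, k, m = 8, 2, 10
        start = rng.integers(0, n - k + 1, size=m)
        times = np.cumsum(rng.uniform(0.05, 0.3, size=m))
        TR, first = compute_tr_matrix(start, times, k, n)
        TR_ref, first_ref = brute_force_tr(start, times, k, n)
        np.testing.assert_allclose(TR, TR_ref)
        np.testing.assert_array_equal(first, first_ref)

    def test_rejects_non_increasing_times(self):
        with pytest.raises(SchemeError):
            compute_tr_matrix([0, 0], [0.1, 0.1], k=1, n=4)


class TestSeroScheme:
    def test_start_support_and_row_sums(self, sero_scheme):
        cfg = sero_scheme.config
        assert sero_scheme.start_index.min() >= 0
        assert sero_scheme.start_index.max() <= cfg.n - cfg.k
        np.testing.assert_array_equal(sero_scheme.W.sum(axis=1), cfg.k)

    def test_coverage_conservation(self, sero_scheme):
        cfg = sero_scheme.config
        counts = sero_scheme.coverage_counts()
        assert counts.sum() == cfg.m * cfg.k
        stats = scheme_statistics(sero_scheme)
        assert stats.mean_coverage == pytest.approx(cfg.m * cfg.k / cfg.n)

    def test_reproducible_for_fixed_seed(self, study_config, sero_scheme):
        again = generate_sero_scheme(study_config)
        np.testing.assert_array_equal(again.start_index, sero_scheme.start_index)
        np.testing.assert_array_equal(again.b, sero_scheme.b)
        different = generate_sero_scheme(study_config.with_(seed=1))
        assert not np.array_equal(different.start_index, sero_scheme.start_index)

    def test_rejection_soundness(self, sero_scheme):
        """Replaying the accepted slice order never yields a slice-averaged
        TR below the rejection threshold."""
        cfg = sero_scheme.config
        last = np.full(cfg.n, np.nan)
        for j in range(sero_scheme.m):
            t = sero_scheme.shot_time[j]
            s = sero_scheme.start_index[j]
            prev = last[s : s + cfg.k]
            elapsed = np.where(
                np.isnan(prev), t + FRESH_SUBVOXEL_TR_OFFSET, t - prev
            )
            assert elapsed.mean() >= cfg.min_mean_tr - 1e-12
            last[s : s + cfg.k] = t

    def test_tr_at_least_shot_spacing(self, sero_scheme):
        pool = sero_scheme.pooled_tr()
        assert pool.min() >= sero_scheme.config.shot_spacing - 1e-12

    def test_b_values_drawn_from_levels(self, sero_scheme):
        assert set(np.unique(sero_scheme.b)) == set(sero_scheme.config.b_levels)

    def test_infeasible_threshold_raises(self):
        cfg = SchemeConfig(n=5, k=4, m=60, min_mean_tr=1e6, seed=0)
        with pytest.raises(InfeasibleSchemeError):
            generate_sero_scheme(cfg)


class TestDirectScheme:
    def test_uniform_coverage_and_fixed_tr(self, direct_scheme):
        stats = scheme_statistics(direct_scheme)
        np.testing.assert_array_equal(stats.coverage, 20)
        assert stats.tr_min == pytest.approx(7.5)
        assert stats.tr_median == pytest.approx(7.5)
        assert stats.tr_max == pytest.approx(7.5)

    def test_one_hot_rows(self, direct_scheme):
        np.testing.assert_array_equal(direct_scheme.W.sum(axis=1), 1)
        assert set(np.unique(direct_scheme.W)) == {0.0, 1.0}

    def test_single_cycle_is_all_first_coverage(self):
        cfg = SchemeConfig(n=20, k=1, m=20)
        sch = generate_direct_scheme(cfg)
        covered = sch.W > 0
        assert np.array_equal(sch.first_coverage & covered, covered)

    def test_b_cycles_volume_by_volume(self, direct_scheme):
        b = direct_scheme.b.reshape(-1, direct_scheme.n)
        assert all(np.unique(vol).size == 1 for vol in b)

    def test_requires_k_equal_one(self, study_config):
        with pytest.raises(SchemeError):
            generate_direct_scheme(study_config)  # k = 4


class TestSliceShiftScheme:
    def test_shift_offsets_in_mm(self, shift_scheme):
        cfg = shift_scheme.config
        block = cfg.m // cfg.n_shifts
        for q in range(cfg.n_shifts):
            starts = shift_scheme.start_index[q * block : (q + 1) * block]
            offsets = np.unique((starts - q) % cfg.k)
            assert offsets.tolist() == [0]
            assert starts.min() == q  # physical shift q * 1.5 mm
        # realized shifts 0, 1.5, 3.0, 4.5 mm
        shifts_mm = np.arange(cfg.n_shifts) * cfg.voxel_size
        np.testing.assert_allclose(shifts_mm, [0.0, 1.5, 3.0, 4.5])

    def test_discarded_shot_count(self, shift_scheme):
        assert shift_scheme.analysis_mask.sum() == 1000 - 4 * 2

    def test_within_block_revisit_interval(self, shift_scheme):
        """Steady-state TR equals slices-per-volume x shot spacing."""
        cfg = shift_scheme.config
        expected = (cfg.n // cfg.k) * cfg.shot_spacing
        pool = shift_scheme.pooled_tr()
        assert np.median(pool) == pytest.approx(expected)

    def test_small_instance_matches_history_replay(self):
        cfg = SchemeConfig(n=8, k=2, m=24, n_shifts=2, discard_per_fov=1)
        sch = generate_slice_shift_scheme(cfg)
        TR_ref, first_ref = brute_force_tr(
            sch.start_index, sch.shot_time, cfg.k, cfg.n
        )
        np.testing.assert_allclose(sch.TR, TR_ref)
        np.testing.assert_array_equal(sch.first_coverage, first_ref)

    def test_indivisible_shot_count_rejected(self, study_config):
        with pytest.raises(SchemeError):
            generate_slice_shift_scheme(study_config.with_(m=1001))


class TestSchemeStatistics:
    def test_counting_oracle(self, sero_scheme):
        stats = scheme_statistics(sero_scheme)
        direct_counts = np.array(
            [
                sum(
                    1
                    for j in range(sero_scheme.m)
                    if sero_scheme.start_index[j]
                    <= i
                    < sero_scheme.start_index[j] + sero_scheme.config.k
                )
                for i in range(sero_scheme.n)
            ]
        )
        np.testing.assert_array_equal(stats.coverage, direct_counts)
        assert stats.mean_coverage == pytest.approx(direct_counts.mean())

    def test_degenerate_scheme_raises(self):
        cfg = SchemeConfig(n=20, k=1, m=20)
        sch = generate_direct_scheme(cfg)  # single cycle: all first coverage
        with pytest.raises(SchemeError):
            scheme_statistics(sch)

    def test_quantiles_are_order_statistics(self, sero_scheme):
        stats = scheme_statistics(sero_scheme)
        pool = np.sort(sero_scheme.pooled_tr())
        assert stats.tr_min == pool[0]
        assert stats.tr_max == pool[-1]
        assert stats.tr_median == pytest.approx(np.median(pool))


def test_config_invariants_enforced():
    with pytest.raises(SchemeError):
        SchemeConfig(n=2, k=4)
    with pytest.raises(SchemeError):
        SchemeConfig(b_levels=(0.5, 0.1))
    with pytest.raises(SchemeError):
        SchemeConfig(shot_spacing=0.0)


def test_from_shots_validates_lengths(study_config):
    with pytest.raises(SchemeError):
        AcquisitionScheme.from_shots(
            study_config, "sero", [0, 1], [0.1], [0.0, 0.15]
        )
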