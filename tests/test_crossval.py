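"""Pairing, contiguous-blocks partitioning, CV leakage, equivalence test."""

import numpy as np
import pytest

from nirmetab.crossval import (PairingError, confounder_equivalence_test,
                               cross_validate, pair_measurements,
                               partition_contiguous_blocks)
from nirmetab.forward import ReferenceSeries, SpectraSeries


def _spectra(times, n_channels=24, seed=0):
    rng = np.random.default_rng(seed)
    wl = np.linspace(1680, 2400, n_channels)
    return SpectraSeries(np.asarray(times, float),
                         rng.normal(size=(len(times), n_channels)), wl)


def _reference(times, values, analyte="glucose"):
    return ReferenceSeries(np.asarray(times, float), np.asarray(values, float),
                           analyte, "ekf_glucose")


class TestPairing:
    def test_identical_grids_pair_all(self):
        t = np.arange(0.0, 50.0, 5.0)
        paired = pair_measurements(_spectra(np.arange(50.0)), _reference(t, t))
        assert len(paired) == len(t)
        np.testing.assert_array_equal(paired.time_min, t)

    def test_nearest_neighbor_matching(self):
        spectra = _spectra(np.arange(0.0, 20.0))
        paired = pair_measurements(spectra, _reference([7.2], [100.0]),
                                   tolerance_s=60)
        assert paired.spectrum_idx[0] == 7

    def test_zero_tolerance_misaligned_raises(self):
        spectra = _spectra(np.arange(0.0, 20.0))
        with pytest.raises(PairingError, match="tolerance"):
            pair_measurements(spectra, _reference([7.2], [100.0]), tolerance_s=0)

    def test_exposure_flag_from_windows(self):
        t = np.arange(0.0, 100.0, 5.0)
        paired = pair_measurements(_spectra(np.arange(100.0)), _reference(t, t),
                                   exposure_windows=[(20.0, 40.0)])
        np.testing.assert_array_equal(paired.exposed,
                                      (t >= 20.0) & (t <= 40.0))


class TestPartition:
    def test_study_sized_visits_give_blocks_of_12_to_15(self):
        """For every pair count a visit can produce, 8 consecutive blocks
        of 12-15 pairs, disjoint and covering."""
        for n in range(96, 121):
            part = partition_contiguous_blocks(n)
            assert part.n_blocks == 8
            assert sum(part.sizes) == n
            assert all(12 <= s <= 15 for s in part.sizes)

    def test_even_split(self):
        assert partition_contiguous_blocks(104).sizes == (13,) * 8

    def test_larger_blocks_first(self):
        assert partition_contiguous_blocks(100).sizes == \
            (13, 13, 13, 13, 12, 12, 12, 12)

    def test_degenerate_minimum(self):
        assert partition_contiguous_blocks(8).sizes == (1,) * 8

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            partition_contiguous_blocks(7)


class TestCrossValidate:
    def _paired_linear(self, n=104, noise=0.0, seed=0, rank=None):
        rng = np.random.default_rng(seed)
        times = np.arange(float(n))
        if rank is None:
            X = rng.normal(size=(n, 24))
        else:
            X = rng.normal(size=(n, rank)) @ rng.normal(size=(rank, 24))
        y = X @ rng.normal(size=24) + noise * rng.normal(size=n)
        spectra = SpectraSeries(times, X, np.linspace(1680, 2400, 24))
        paired = pair_measurements(spectra, _reference(times, y))
        return paired, X

    def test_exact_model_class_recovers(self):
        """Noiseless rank-4 spectra with k=4: out-of-block predictions are
        exact to numerical precision."""
        paired, X = self._paired_linear(rank=4)
        result = cross_validate(paired, X, k=4)
        scale = np.abs(paired.reference).max()
        assert result.pooled_rmsecv < 1e-6 * scale

    def test_pooled_rmsecv_hand_value(self):
        """Residuals 3 and 4 pool to sqrt((9+16)/2) = 3.5355..."""
        resid = np.array([3.0, 4.0])
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(3.5355339059327378)

    def test_pooled_equals_brute_force_over_blocks(self):
        paired, X = self._paired_linear(noise=0.5)
        result = cross_validate(paired, X, k=5)
        resid = result.predicted - result.reference
        np.testing.assert_allclose(result.pooled_rmsecv,
                                   np.sqrt(np.mean(resid**2)), rtol=1e-12)
        # per-block values recompute from the stored per-pair residuals
        for b, (s, e) in enumerate(result.partition.ranges):
            np.testing.assert_allclose(result.per_block_rmsecv[b],
                                       np.sqrt(np.mean(resid[s:e] ** 2)),
                                       rtol=1e-12)

    def test_no_leakage_from_held_out_block(self):
        """Out-of-block predictions are invariant to corrupting the held-out
        block's reference values in training."""
        paired, X = self._paired_linear(noise=0.5, seed=3)
        result = cross_validate(paired, X, k=5)
        s, e = result.partition.ranges[2]
        corrupted = paired
        corrupted.reference[s:e] += 1e4  # corrupt block 2 references
        result2 = cross_validate(corrupted, X, k=5)
        np.testing.assert_allclose(result2.predicted[s:e],
                                   result.predicted[s:e], rtol=1e-9)

    def test_training_fold_too_small_for_k(self):
        paired, X = self._paired_linear(n=16)
        with pytest.raises(ValueError, match="too small"):
            cross_validate(paired, X, k=15)

    def test_every_pair_predicted_once(self):
        paired, X = self._paired_linear(noise=0.5)
        result = cross_validate(paired, X, k=3)
        assert len(result.predicted) == len(paired)
        covered = np.concatenate([np.arange(s, e)
                                  for s, e in result.partition.ranges])
        np.testing.assert_array_equal(np.sort(covered), np.arange(len(paired)))


class TestEquivalence:
    def test_identical_sets_equivalent(self, rng):
        errs = np.abs(rng.normal(3.0, 1.0, size=50))
        res = confounder_equivalence_test(errs, errs.copy())
        assert res.mean_difference == 0.0
        assert res.verdict == "equivalent"

    def test_large_shift_not_shown(self, rng):
        """A +20 mg/dl shift with sd 3 and n=50 puts the CI outside the
        +-10.5 band, matching the closed-form CI."""
        base = rng.normal(5.0, 3.0, size=50)
        res = confounder_equivalence_test(base + 20.0, base + rng.normal(0, 3, 50))
        assert res.verdict == "not shown"
        assert res.ci_low > 10.5

    def test_ci_matches_closed_form(self):
        from scipy import stats
        e1 = np.array([1.0, 2.0, 3.0, 4.0])
        e0 = np.array([1.5, 2.5, 2.0, 3.0, 4.0])
        res = confounder_equivalence_test(e1, e0)
        v1, v0 = e1.var(ddof=1), e0.var(ddof=1)
        se = np.sqrt(v1 / 4 + v0 / 5)
        df = (v1 / 4 + v0 / 5) ** 2 / ((v1 / 4) ** 2 / 3 + (v0 / 5) ** 2 / 4)
        d = e1.mean() - e0.mean()
        t = stats.t.ppf(0.975, df)
        assert res.ci_low == pytest.approx(d - t * se)
        assert res.ci_high == pytest.approx(d + t * se)

    def test_verdict_iff_ci_within_band(self, rng):
        errs = rng.normal(5.0, 2.0, size=40)
        res = confounder_equivalence_test(errs + 9.0, errs, threshold=10.5)
        inside = -10.5 < res.ci_low and res.ci_high < 10.5
        assert (res.verdict == "equivalent") == inside

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            confounder_equivalence_test(np.ones(5), np.ones(5))

    def test_tiny_sets_rejected(self):
        with pytest.raises(ValueError):
            confounder_equivalence_test(np.array([1.0]), np.array([1.0, 2.0]))
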