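"""Surrogates, Rayleigh null, p-values, corrections and the inflation demo."""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from tacb import (
    EpochedRecording,
    FrequencyPair,
    SegmentationConfig,
    correct_multiple,
    epoch_shift_surrogate,
    estimate_sigma,
    fourier_coefficients,
    fp_inflation_experiment,
    normal_based_p,
    scaled_q,
    surrogate_ensemble,
    tacb_from_spectra,
)
from tacb.bispectrum import TACBTensor
from tacb.nullstats import (
    RayleighNull,
    SurrogateEnsemble,
    _any_rejection_sorted,
    rayleigh_population_moments,
)
from tacb.errors import DegenerateNullError, ValidationError

FP = FrequencyPair(10.0, 20.0)


def _ensemble(values):
    values = np.atleast_2d(np.asarray(values, dtype=complex)).T
    return SurrogateEnsemble(
        values=values,
        offsets_used=np.arange(1, values.shape[0] + 1),
        triples=np.array([[0, 1, 2]]),
    )


class TestEpochShiftSurrogate:
    def test_shift_composition_is_additive(self, null_spec):
        o1, o2 = 7, 11
        once = epoch_shift_surrogate(epoch_shift_surrogate(null_spec, FP, o1), FP, o2)
        combined = epoch_shift_surrogate(null_spec, FP, (o1 + o2) % null_spec.n_epochs)
        np.testing.assert_allclose(once.coeffs, combined.coeffs)

    def test_two_epochs_swap(self):
        rng = np.random.default_rng(0)
        rec = EpochedRecording(rng.standard_normal((2, 2, 256)), fs=256.0)
        spec = fourier_coefficients(rec, SegmentationConfig(256))
        shifted = epoch_shift_surrogate(spec, FP, 1)
        b3 = 30
        np.testing.assert_allclose(
            shifted.coeffs[:, 0, :, b3], spec.coeffs[:, 1, :, b3]
        )
        np.testing.assert_allclose(
            shifted.coeffs[:, 1, :, b3], spec.coeffs[:, 0, :, b3]
        )

    def test_only_third_frequency_bin_touched(self, null_spec):
        shifted = epoch_shift_surrogate(null_spec, FP, 5)
        untouched = np.delete(np.arange(null_spec.n_bins), 30)
        np.testing.assert_array_equal(
            shifted.coeffs[:, :, :, untouched], null_spec.coeffs[:, :, :, untouched]
        )
        assert not np.allclose(
            shifted.coeffs[:, :, :, 30], null_spec.coeffs[:, :, :, 30]
        )

    @pytest.mark.parametrize("offset", [0, 60, -1])
    def test_invalid_offsets_rejected(self, null_spec, offset):
        with pytest.raises(ValidationError):
            epoch_shift_surrogate(null_spec, FP, offset)

    def test_surrogate_magnitudes_rayleigh(self, coupled_spec):
        """Exhaustive epoch-shift ensemble of |T| fits the Rayleigh it implies."""
        channels = [0, 2, 5]
        n_e = coupled_spec.n_epochs
        vals = np.array(
            [
                tacb_from_spectra(
                    epoch_shift_surrogate(coupled_spec, FP, o), FP, channels=channels
                ).values[0]
                for o in range(1, n_e)
            ]
        )
        ens = SurrogateEnsemble(
            values=vals[:, None],
            offsets_used=np.arange(1, n_e),
            triples=np.array([[0, 1, 2]]),
        )
        sigma = estimate_sigma(ens).sigma[0]
        _, pval = sps.kstest(np.abs(vals), sps.rayleigh(scale=sigma).cdf)
        assert pval > 0.01


class TestEstimateSigma:
    def test_constant_magnitude(self):
        null = estimate_sigma(_ensemble([2.0, 2.0j, -2.0, 2.0]))
        assert null.sigma_sq[0] == pytest.approx(2.0)  # c^2 / 2 with c = 2

    def test_two_value_arithmetic(self):
        null = estimate_sigma(_ensemble([1.0, 2.0]))
        assert null.sigma_sq[0] == pytest.approx(5.0 / 4.0)

    def test_monte_carlo_consistency(self, rng):
        draws = (rng.standard_normal(10_000) + 1j * rng.standard_normal(10_000))
        null = estimate_sigma(_ensemble(draws))
        assert null.sigma_sq[0] == pytest.approx(1.0, abs=0.05)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateNullError):
            estimate_sigma(_ensemble([0.0, 0.0]))

    def test_single_surrogate_rejected(self):
        with pytest.raises(ValidationError):
            estimate_sigma(_ensemble([1.0]))


class TestScaledQ:
    def _t(self, value):
        return TACBTensor(
            n_channels=3,
            triples=np.array([[0, 1, 2]]),
            values=np.array([value], dtype=complex),
            pair=FP,
        )

    def test_zero_coupling(self):
        stats = scaled_q(self._t(0.0), RayleighNull(sigma_sq=np.array([1.0])))
        assert stats.q[0] == 0.0
        assert stats.p[0] == 1.0

    def test_median_point(self):
        # |t| = sigma * sqrt(2 ln 2) inverts to p = 0.5
        sigma = 1.7
        stats = scaled_q(
            self._t(sigma * np.sqrt(2 * np.log(2))),
            RayleighNull(sigma_sq=np.array([sigma**2])),
        )
        assert stats.p[0] == pytest.approx(0.5)

    def test_p_is_exp_minus_q_and_monotone(self, rng):
        mags = np.sort(rng.uniform(0, 5, 50))
        t = TACBTensor(
            n_channels=50,
            triples=np.zeros((50, 3), dtype=int),
            values=mags.astype(complex),
            pair=FP,
        )
        stats = scaled_q(t, RayleighNull(sigma_sq=np.full(50, 0.8)))
        np.testing.assert_allclose(stats.p, np.exp(-stats.q))
        assert (np.diff(stats.p) <= 0).all()

    def test_null_pvalues_uniform(self):
        """One-triple null datasets: p = exp(-Q) is uniform on (0, 1]."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(200):
            rec = EpochedRecording(rng.standard_normal((3, 40, 128)), fs=64.0)
            spec = fourier_coefficients(rec, SegmentationConfig(64, 0.5))
            fp = FrequencyPair(8.0, 14.0)
            t = tacb_from_spectra(spec, fp)
            ens = surrogate_ensemble(spec, fp, n_surrogates=100, seed=rng)
            stats = scaled_q(t, estimate_sigma(ens))
            pvals.append(stats.p[0])
        _, ks_p = sps.kstest(pvals, "uniform")
        assert ks_p > 0.01


class TestCorrectMultiple:
    def test_single_test_reduces_to_alpha(self):
        for method in ("bonferroni", "benjamini_hochberg"):
            reject, thr = correct_multiple(np.array([0.04]), method, alpha=0.05)
            assert reject[0]
            reject, _ = correct_multiple(np.array([0.06]), method, alpha=0.05)
            assert not reject[0]

    def test_bh_step_up_hand_case(self):
        # thresholds i*alpha/n = .0125, .025, .0375, .05:
        # 0.04 > 0.0375 so only the two smallest survive the step-up
        reject, thr = correct_multiple(
            np.array([0.01, 0.02, 0.04, 0.9]), "benjamini_hochberg", 0.05
        )
        np.testing.assert_array_equal(reject, [True, True, False, False])
        assert thr == pytest.approx(0.02)
        # whereas 0.03 <= 0.0375 pulls all three smallest in
        reject, thr = correct_multiple(
            np.array([0.01, 0.02, 0.03, 0.9]), "benjamini_hochberg", 0.05
        )
        np.testing.assert_array_equal(reject, [True, True, True, False])
        assert thr == pytest.approx(0.03)

    def test_all_ones_nothing_rejected(self):
        reject, thr = correct_multiple(np.ones(10), "bonferroni", 0.05)
        assert not reject.any()
        assert thr == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            correct_multiple(np.array([]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            correct_multiple(np.array([0.0, 0.5]))


class TestNormalBasedP:
    def test_at_the_mean(self):
        assert normal_based_p(1.2533, 1.2533, 0.6551) == pytest.approx(0.5)

    def test_standard_quantile(self):
        assert normal_based_p(1.959964, 0.0, 1.0) == pytest.approx(0.025, rel=1e-4)

    def test_underestimates_rayleigh_tail(self):
        # at the exact Rayleigh p = 1e-6 quantile the normal-based p is smaller
        x0 = np.sqrt(-2.0 * np.log(1e-6))
        mu, sd = rayleigh_population_moments(1.0)
        assert np.exp(-0.5 * x0**2) == pytest.approx(1e-6)
        assert normal_based_p(x0, mu, sd) < 1e-6

    def test_bad_sd_rejected(self):
        with pytest.raises(ValidationError):
            normal_based_p(1.0, 0.0, 0.0)


class TestRayleighConvergence:
    def test_mean_of_uniform_phases_is_rayleigh(self, rng):
        """Complex CLT: |mean of n unit phasors| converges to Rayleigh."""
        n, reps = 200, 400
        phases = rng.uniform(0, 2 * np.pi, size=(reps, n))
        means = np.exp(1j * phases).mean(axis=1)
        sigma = np.sqrt((np.abs(means) ** 2).sum() / (2 * reps))
        _, pval = sps.kstest(np.abs(means), sps.rayleigh(scale=sigma).cdf)
        assert pval > 0.01


@pytest.fixture(scope="module")
def small_table():
    return fp_inflation_experiment(
        family_sizes=[1, 10, 1000], n_repetitions=400, alpha=0.05, seed=3
    )


class TestFpInflation:
    def test_correct_pvalues_hold_level(self, small_table):
        sub = small_table.query("pvalue_method == 'rayleigh'")
        se3 = 3 * np.sqrt(0.05 * 0.95 / 400)
        assert (np.abs(sub["fraction_with_fp"] - 0.05) < se3 + 0.011).all()

    def test_normal_pvalues_inflate_with_family_size(self, small_table):
        sub = small_table.query(
            "pvalue_method == 'normal' and correction == 'bonferroni'"
        ).set_index("family_size")["fraction_with_fp"]
        assert sub[1000] > sub[1] - 0.01
        assert sub[1000] > 0.3  # already far above the nominal 5% at n = 1000

    def test_family_size_one_is_single_test_level(self):
        table = fp_inflation_experiment(
            family_sizes=[1], n_repetitions=2000, alpha=0.05, seed=4
        )
        sub = table.query("pvalue_method == 'rayleigh'")["fraction_with_fp"]
        se3 = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert (np.abs(sub - 0.05) < se3).all()

    def test_bonferroni_fwer_matches_closed_form(self):
        # realized FWER within 3 binomial SE of 1 - (1 - alpha/n)^n
        n, reps, alpha = 10, 3000, 0.05
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(reps):
            p = np.sort(np.exp(-0.5 * rng.rayleigh(1.0, n) ** 2))
            hits += _any_rejection_sorted(p, alpha)[0]
        expected = 1.0 - (1.0 - alpha / n) ** n
        se3 = 3 * np.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < se3

    def test_fast_path_matches_statsmodels(self, rng):
        """The sorted-threshold shortcut agrees with full correction decisions."""
        for _ in range(200):
            n = rng.integers(1, 40)
            p = np.sort(rng.uniform(1e-6, 1.0, n))
            bonf, bh = _any_rejection_sorted(p, 0.05)
            assert bonf == multipletests(p, 0.05, "bonferroni")[0].any()
            assert bh == multipletests(p, 0.05, "fdr_bh")[0].any()

    def test_bonferroni_rejection_implies_bh_rejection(self, small_table):
        wide = small_table.pivot_table(
            index=["family_size", "pvalue_method"],
            columns="correction",
            values="fraction_with_fp",
        )
        assert (wide["benjamini_hochberg"] >= wide["bonferroni"]).all()

    def test_invalid_family_size(self):
        with pytest.raises(ValidationError):
            fp_inflation_experiment(family_sizes=[0], n_repetitions=2)
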