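import math

import numpy as np
import pytest
from scipy import optimize

from msdeconv.deconv import (
    build_design_matrix,
    fit_coefficients,
    ion_current_fractions,
)
from msdeconv.errors import (
    CollinearBasisError,
    MixedDetectorError,
    ModelMismatchWarning,
    UnderdeterminedSystemError,
    UndefinedFractionError,
)
from msdeconv.spectra import BasisSpectrum, MeasuredSpectrum, PeakHeight, normalize_basis


def _spectrum(grid, y, dy, det="F"):
    return MeasuredSpectrum(
        [PeakHeight(mz, det, yi, dyi) for mz, yi, dyi in zip(grid, y, dy)]
    )


def _random_instance(rng, M, N, det="F"):
    """Random full-rank WLS instance on a small integer grid."""
    grid = list(rng.choice(np.arange(10, 60), size=M, replace=False))
    while True:
        bases = []
        for i in range(N):
            support = rng.choice(grid, size=rng.integers(2, M + 1), replace=False)
            intens = {int(m): float(rng.uniform(0.05, 1.0)) for m in support}
            bases.append(normalize_basis(f"S{i}", intens, det))
        X = np.array([[b.value(m) for b in bases] for m in grid])
        if np.linalg.matrix_rank(X) == N and np.linalg.cond(X) < 1e6:
            break
    a_true = rng.uniform(0.5, 5.0, size=N)
    y = X @ a_true * (1 + rng.normal(0, 0.02, size=M))
    dy = np.maximum(0.01 * np.abs(y), 1e-6)
    return grid, bases, y, dy, a_true


class TestDesignMatrix:
    def test_published_neon_bases(self, table5_bases):
        X = build_design_matrix(table5_bases, [17, 20, 36])
        expected = np.array(
            [[0.164, 0.0, 0.0], [1.34e-3, 1.0, 1.06e-9], [0.0, 0.0, 3.00e-3]]
        )
        np.testing.assert_allclose(X, expected, rtol=0, atol=0)

    def test_single_basis_column_is_spectrum(self, table5_bases):
        h2o = table5_bases[0]
        X = build_design_matrix([h2o], h2o.mz_values)
        np.testing.assert_allclose(
            X[:, 0], [h2o.intensities[m] for m in h2o.mz_values]
        )

    def test_identical_bases_are_collinear(self, table5_bases):
        h2o = table5_bases[0]
        with pytest.raises(CollinearBasisError, match="H2O"):
            build_design_matrix([h2o, h2o], [17, 18, 20])


class TestFitCoefficients:
    def test_neon_reference_gas_triangular_oracle(self, table5_bases, neon_ds):
        """The 3x3 dry-air system is exactly determined; the WLS solution
        must agree with the hand triangular solve to 1e-9 relative."""
        spectrum = neon_ds.gases["Gas-III"]
        y = {p.mz: p.y for p in spectrum.entries}
        # independent back-substitution: m/z 17 only H2O, 36 only Ar, 20 mix
        a_h2o = y[17] / 0.164
        a_ar = y[36] / 3.00e-3
        a_ne = y[20] - a_h2o * 1.34e-3 - a_ar * 1.06e-9
        fit = fit_coefficients(spectrum, table5_bases)
        np.testing.assert_allclose(fit.a, [a_h2o, a_ne, a_ar], rtol=1e-9)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-15)
        assert fit.dof == 0
        assert math.isnan(fit.chi2_sigma)
        assert fit.rescale_factor == 1.0

    def test_single_basis_exact_representation(self, table5_bases):
        h2o = table5_bases[0]
        a = 7.0e-12
        grid = h2o.mz_values
        y = [a * h2o.intensities[m] for m in grid]
        dy = [0.01 * v for v in y]
        fit = fit_coefficients(_spectrum(grid, y, dy, "M"), [h2o])
        assert fit.a[0] == pytest.approx(a, rel=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-18)

    def test_methane_rich_gas_dominates_its_fragment_peak(self, methane_ds):
        """A high-CH4 gas should owe essentially all of its m/z=15 current
        to CH4 (published: (100 +/- 2)%)."""
        fit = fit_coefficients(methane_ds.gases["Gas-I"], methane_ds.block.basis)
        ft = ion_current_fractions(fit, methane_ds.block.basis, 15)
        f, _ = ft.fraction("CH4")
        assert round(100 * f) == 100

    def test_underdetermined_rejected(self, table5_bases):
        spec = _spectrum([20], [1e-9], [1e-11], "M")
        with pytest.raises(UnderdeterminedSystemError):
            fit_coefficients(spec, table5_bases)

    def test_detector_mismatch_rejected(self, table5_bases):
        spec = _spectrum([17, 20, 36], [1e-9] * 3, [1e-11] * 3, det="F")
        with pytest.raises(MixedDetectorError):
            fit_coefficients(spec, table5_bases)

    def test_wls_agrees_with_simplex_oracle(self):
        """Weighted least squares must agree with an independent numerical
        minimization of the chi-square objective to 1e-8 relative."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            M = int(rng.integers(3, 7))
            N = int(rng.integers(1, min(M, 3) + 1))
            grid, bases, y, dy, _ = _random_instance(rng, M, N)
            fit = fit_coefficients(_spectrum(grid, y, dy), bases)
            X = np.array([[b.value(m) for b in bases] for m in grid])

            def chi2(a):
                return float(np.sum(((X @ a - y) / dy) ** 2))

            x0 = np.linalg.lstsq(X, y, rcond=None)[0]  # unweighted start
            res = optimize.minimize(
                chi2, x0, method="Nelder-Mead",
                options={"xatol": 1e-13, "fatol": 1e-16, "maxfev": 50000},
            )
            np.testing.assert_allclose(fit.a, res.x, rtol=1e-8, atol=1e-10)
            assert fit.chi2 <= res.fun * (1 + 1e-10) + 1e-12

    def test_wls_agrees_with_statsmodels(self):
        """Cross-check the estimator and covariance against statsmodels WLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        grid, bases, y, dy, _ = _random_instance(rng, 6, 3)
        fit = fit_coefficients(_spectrum(grid, y, dy), bases)
        X = np.array([[b.value(m) for b in bases] for m in grid])
        res = sm.WLS(y, X, weights=1.0 / dy**2).fit()
        np.testing.assert_allclose(fit.a, res.params, rtol=1e-10)
        # statsmodels scales the covariance by chi2/dof; undo that to
        # compare the pure error-propagation covariance
        unscaled = res.cov_params() / res.scale
        np.testing.assert_allclose(fit.covariance, unscaled, rtol=1e-8)

    def test_exact_mixture_recovered_to_machine_precision(self, table3_bases):
        rng = np.random.default_rng(3)
        a_true = rng.uniform(0.1, 10.0, size=3) * 1e-12
        grid = [14, 15, 16, 28, 32]
        X = np.array([[b.value(m) for b in table3_bases] for m in grid])
        y = X @ a_true
        dy = 0.01 * np.abs(y)
        fit = fit_coefficients(_spectrum(grid, y, dy), table3_bases)
        np.testing.assert_allclose(fit.a, a_true, rtol=1e-12)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-16)

    def test_scale_equivariance(self, methane_ds):
        """Multiplying y and dy by a constant scales a and da and leaves
        chi2 and all fractions unchanged (detector sensitivity cancels)."""
        spec = methane_ds.gases["Gas-II"]
        bases = methane_ds.block.basis
        fit1 = fit_coefficients(spec, bases)
        c = 137.0
        scaled = MeasuredSpectrum(
            [PeakHeight(p.mz, p.detector, c * p.y, c * p.dy) for p in spec.entries]
        )
        fit2 = fit_coefficients(scaled, bases)
        np.testing.assert_allclose(fit2.a, c * fit1.a, rtol=1e-10)
        np.testing.assert_allclose(fit2.da, c * fit1.da, rtol=1e-10)
        assert fit2.chi2 == pytest.approx(fit1.chi2, rel=1e-10)
        f1 = ion_current_fractions(fit1, bases, 15).fractions
        f2 = ion_current_fractions(fit2, bases, 15).fractions
        for sp in f1:
            assert f2[sp][0] == pytest.approx(f1[sp][0], rel=1e-10)

    def test_inflating_a_residual_never_shrinks_errors(self, table3_bases):
        grid = [14, 15, 16, 28, 32]
        X = np.array([[b.value(m) for b in table3_bases] for m in grid])
        y = X @ np.array([5.0, 3.0, 1.0])
        dy = 0.01 * np.abs(y)
        da_prev = fit_coefficients(_spectrum(grid, y, dy), table3_bases).da
        for bump in (1.05, 1.2, 2.0):
            y2 = y.copy()
            y2[3] *= bump  # perturb one peak, errors held fixed
            da = fit_coefficients(_spectrum(grid, y2, dy), table3_bases).da
            assert np.all(da >= da_prev - 1e-15)
            da_prev = da

    # y = [a_A + 0.5 a_B, a_B] with (a_A, a_B) = (-1, 4): the exact solve
    # forces a significantly negative amplitude for species A
    _NEG_SPEC = ([10, 11], [1.0, 4.0], [0.01, 0.04])
    _NEG_BASES = (
        BasisSpectrum("A", {10: 1.0}),
        BasisSpectrum("B", {10: 0.5, 11: 1.0}),
    )

    def test_significantly_negative_coefficient_warns(self):
        with pytest.warns(ModelMismatchWarning, match="'A'"):
            fit = fit_coefficients(_spectrum(*self._NEG_SPEC), self._NEG_BASES)
        assert fit.a[0] == pytest.approx(-1.0)

    def test_nonneg_mode_clips_at_zero(self):
        fit = fit_coefficients(
            _spectrum(*self._NEG_SPEC), self._NEG_BASES, nonneg=True
        )
        assert np.all(fit.a >= 0.0)


class TestFractions:
    def test_fractions_sum_to_one_everywhere(self, methane_ds):
        for gas, spec in methane_ds.gases.items():
            fit = fit_coefficients(spec, methane_ds.block.basis)
            for mz in (14, 15, 16, 28, 32):
                ft = ion_current_fractions(fit, methane_ds.block.basis, mz)
                total = sum(f for f, _ in ft.fractions.values())
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_unsupported_species_has_exactly_zero_fraction(self, methane_ds):
        fit = fit_coefficients(methane_ds.gases["Gas-I"], methane_ds.block.basis)
        ft = ion_current_fractions(fit, methane_ds.block.basis, 32)
        assert ft.fraction("CH4") == (0.0, 0.0)  # CH4 has no m/z=32 peak
        assert ft.fraction("AIR")[0] == pytest.approx(1.0)

    def test_single_basis_fraction_is_unity(self, table5_bases):
        h2o = table5_bases[0]
        grid = h2o.mz_values
        y = [2e-9 * h2o.intensities[m] for m in grid]
        fit = fit_coefficients(
            _spectrum(grid, y, [0.01 * v for v in y], "M"), [h2o]
        )
        ft = ion_current_fractions(fit, [h2o], 18)
        assert ft.fraction("H2O")[0] == 1.0

    def test_undefined_fraction_off_support(self, table5_bases, neon_ds):
        fit = fit_coefficients(neon_ds.gases["Gas-III"], table5_bases)
        with pytest.raises(UndefinedFractionError):
            ion_current_fractions(fit, table5_bases, 99)
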