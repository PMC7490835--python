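# Methods

## Problem

Portable quadrupole gas mass spectrometers quantify gas species by
peak-height comparison: the ion current at a species' characteristic m/z
ratio is ratioed against the same current measured with a reference gas of
known composition, so detector sensitivity cancels. This breaks down when
several species contribute current at the same m/z (overlap, or isobaric,
interference): N2 fragments and O2 interfere with the CH3+ fragment used
for CH4 at m/z 15; doubly charged 40Ar and the 20(H2O)+ isotopologue
interfere with 20Ne at m/z 20. msdeconv disentangles such interferences so
that only the target species' share of the current enters the calibration.

## Model

Peak heights y(mu_j) +/- dy(mu_j) measured at m/z ratios mu_1..mu_M with one
detector are modelled as a linear combination of N basis spectra x_i —
dimensionless per-species ion-current patterns, max-normalized to 1,
measured once on the same instrument with the same ion-source settings:

    y~(mu_j) = sum_{i=1..N} a_i x_i(mu_j),        j = 1..M

Any m/z absent from a basis spectrum contributes exactly zero. The basis
spectra must be linearly independent on the measurement grid and M >= N.
The amplitudes a_i (amperes) are the weighted least-squares minimizer of

    chi2(a) = sum_j ( (y~(mu_j) - y(mu_j)) / dy(mu_j) )^2 .

The solve uses an orthogonal decomposition of the weighted design matrix
(numpy `lstsq`), with a collinearity guard at condition number 1e10.
Coefficient covariance is C = (X^T W X)^{-1}, W = diag(1/dy^2).

### Measurement errors and the 1% floor

The y(mu_j) are means (or medians) of repeated PEAK readings minus the
corresponding aggregate of ZERO baseline readings; dy is the quadrature sum
of the two standard errors of the mean. Because the error of the mean only
captures short-term noise — not drift or detector non-linearity — dy is
floored at 1% of |y|, the typical relative peak-height accuracy of this
instrument class. A single reading has sem 0, so the floor always provides
a nonzero dy; the degenerate case y = 0 with zero scatter falls back to a
sub-femtoampere token error (1e-18 A) to keep weights finite.

### Goodness of fit and error rescaling

chi2 at the minimum measures whether the quoted dy explain the residual
misfit. With dof = M - N > 0, chi2 is compared against chi2_sigma, the
68.2689% (1-sigma) quantile of the chi-square distribution with dof degrees
of freedom — a dof-aware reading of the "chi2 ≈ M − N means the fit is
fully explained" rule. If chi2 > chi2_sigma, the dy were evidently too
optimistic (or the basis set incomplete) and every coefficient error is
inflated by sqrt(chi2 / chi2_sigma). When M = N the system is exactly
determined, chi2 = 0 by construction, chi2_sigma is undefined (stored as
NaN) and no rescaling is applied; errors come from covariance propagation
alone. This case matters in practice: the neon validation campaign is a
3-peak / 3-species fit.

### Ion-current fractions

The share of species i in the current at any m/z is

    f_i = a_i x_i(mz) / sum_k a_k x_k(mz),

evaluated against the *modelled* total — for an acceptable fit it agrees
with the observed current within dy, and it keeps the fractions summing to
exactly 1. Fraction errors use the delta method with the full coefficient
covariance (off-diagonal terms included), times the rescale factor.
Neglecting the covariances would only lose information; note however that
the published validation tables appear to use a different (unstated) error
recipe at peaks dominated by a single species, so quoted fraction *errors*
should be compared only in order of magnitude, while central values are
reproduced tightly. Basis spectra are treated as exact: no uncertainty
model for the x_i is available, so their measurement error is absorbed by
the chi-square rescaling like any other unmodelled effect.

Coefficients are not sign-constrained by default (plain weighted least
squares); a coefficient more than 3 sigma below zero raises a model-mismatch
warning, and an optional NNLS mode (`nonneg=True`) is available for users
who prefer a constrained estimate. At compensation time, fractions outside
[0, 1] are clipped with a warning, and f = 0 marks the peak below detection.

## Compensation and calibration

Only the target species' share enters the peak-height comparison:
y_comp = f * y with relative errors of f and y combined in quadrature.
Calibration is single-reference:

    c_sample = (y_comp,sample / y_comp,reference) * c_reference,

relative errors again in quadrature; the reference amount is exact unless
an uncertainty is supplied. Compensation is applied to the reference gas as
well (it reduces to x1.00 for a pure reference). Because compensation
multiplies in the fraction uncertainties, a compensated concentration
always carries a somewhat larger relative error than the raw one — that
increase is the honest price of removing the interference bias. A blank
step, when supplied, is subtracted peak-wise before deconvolution, errors
in quadrature, with the 1% floor re-applied.

### The worked-arithmetic variant

The bundled validation campaigns publish their target fractions rounded to
two decimals (1.00/0.70 for the methane pair; 0.74/0.42/0.14 for the neon
trio) and carry those printed values through the concentration arithmetic.
The exact WLS fractions (0.9997, 0.7045; 0.7378, 0.4251, 0.1456) are not
mechanical roundings of those printed values in every case, so
`validation.run_example` computes two calibrations: `compensated` (full
precision, the package's genuine output) and `worked` (the published
two-decimal fractions, reproducing the published arithmetic digit for
digit). The worked variant first asserts that the freshly deconvolved
fraction agrees with the published value within its printed 1-sigma error,
so it can never silently diverge from the computation.

## Data formats

* **Readings file** — one reading per line,
  `<ISO timestamp or seconds> <PEAK|ZERO|PEAK_DECONV|ZERO_DECONV> mz=<int>
  detector=<F|M> I=<value><A|mA|uA|nA|pA|fA>`. `PEAK_DECONV`/`ZERO_DECONV`
  are *helper* readings at extra m/z ratios: they constrain the fit but are
  excluded from calibration. This dialect is deliberately minimal and
  human-diffable; readers for other raw formats can be added behind
  `parse_readings`.
* **DECONVOLUTION block** — a single-line record
  `DECONVOLUTION: target_mz=15 ; target_species=CH4 ; detector=F ;
  MS_EE=70 eV ; basis=(('CH4', 14,0.103, 15,0.806, 16,1.0), ...)`,
  parse-tolerant of multi-line layout and typographic quotes. `MS_EE`
  documents the ion-source electron energy and never enters the numerics.
  Basis tuples whose maximum deviates from 1 are re-normalized with a
  warning. m/z values are integers everywhere; fractional values are
  rejected rather than rounded, to surface configuration mistakes.
* **Basis table** — a `species  m/z  intensity` delimited text table,
  max-normalized on load.

## Synthetic data generator

`synth.MixtureScenario` emulates repeated noisy readings of a known
mixture: PEAK currents are the forward model times (1 + eps) with
eps ~ N(0, noise_rel_sd), ZERO readings are additive baseline noise
(default 1e-16 A). Defaults mirror the instrument's operating point: 1%
relative noise, 10 repeats per peak. One species may relax exponentially
toward its equilibrium amplitude (time constant tau) to emulate the slow
stabilization of water vapour after switching gas inlets; the relaxation is
qualitative, so tau is a free scenario parameter.

The generator reproduces exactly the assumptions of the estimator
(stationary amplitudes apart from the optional drift, uncorrelated
multiplicative noise, exact basis spectra). Passing recovery and coverage
tests therefore validates the estimator's internal consistency — bias,
error calibration, exact recovery in the noise-free limit — not its
robustness to basis-spectrum error, detector non-linearity or EM gain
drift, which real data can exhibit and which the 1% floor and chi-square
rescaling only partially absorb.

Monte-Carlo problem sizes: coverage is assessed with 200 scenario
replicates of a 5-peak / 3-species mixture at 1% noise and 10 repeats
(2-sigma coverage required in [0.90, 1.0]); bias is tracked at 3, 10 and
30 repeats with 60 replicates each. These sizes give stable checks while
keeping the full suite fast.

## Known limitations

* No peak-shape or peak-tail modelling and no fractional-m/z
  interpolation: every interference must be represented by a measured
  basis spectrum on the integer grid.
* Single-detector fits only; mixing Faraday-cup and electron-multiplier
  peaks is rejected because their sensitivity ratio drifts between
  analysis steps.
* Single-reference, linear calibration only; no multi-point calibration
  curves and no conversion of partial pressures to dissolved
  concentrations.
* Drift is handled by measurement scheduling (wait for stabilization, or
  fit time windows), never inside the fit.
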