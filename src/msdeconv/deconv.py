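"""Error-weighted least-squares deconvolution of overlap interferences.

A measured spectrum of peak heights y(mu_j) +/- dy(mu_j) (j = 1..M) is
modelled as a linear combination of N normalized basis spectra x_i:

    y~(mu_j) = sum_i a_i * x_i(mu_j)

The amplitudes a_i (amperes, since the x_i are dimensionless) are estimated
by minimizing the sum of squared error-weighted residuals

    chi2 = sum_j ((y~(mu_j) - y(mu_j)) / dy(mu_j))**2,

i.e. weighted least squares with weights 1/dy^2.  The coefficient
covariance is (X^T W X)^-1.  When chi2 exceeds its 1-sigma quantile for
M - N degrees of freedom, the quoted dy were too optimistic (or the basis
set is incomplete) and all coefficient errors are inflated by
sqrt(chi2 / chi2_sigma) so they reflect the actual misfit.

The species' shares of the ion current at any m/z follow from the fitted
model: f_i = a_i x_i(mz) / sum_k a_k x_k(mz), with errors propagated from
the full coefficient covariance by the delta method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import chi2 as _chi2_dist

from .errors import (
    CollinearBasisError,
    MixedDetectorError,
    ModelMismatchWarning,
    MsDeconvError,
    UnderdeterminedSystemError,
    UndefinedFractionError,
)
from .spectra import BasisSpectrum, MeasuredSpectrum, PeakHeight

__all__ = [
    "DeconvolutionFit",
    "FractionTable",
    "build_design_matrix",
    "fit_coefficients",
    "ion_current_fractions",
    "ONE_SIGMA",
]

#: Probability mass within +/- 1 sigma of a standard normal; the chi-square
#: quantile at this level defines the goodness-of-fit reference chi2_sigma.
ONE_SIGMA = 0.6826894921370859

#: Condition number above which the basis set is treated as collinear.
_COND_LIMIT = 1e10


def build_design_matrix(
    basis_set: Sequence[BasisSpectrum], mz_grid: Sequence[int]
) -> np.ndarray:
    """Evaluate the basis spectra on an m/z grid.

    Returns the M x N matrix with element (j, i) = x_i(mu_j).  The basis
    spectra must be linearly independent on the grid.

    Raises
    ------
    CollinearBasisError
        If the matrix has numerical rank < N; the message lists the
        candidate dependent species.
    """
    if not basis_set:
        raise MsDeconvError("empty basis set")
    grid = [int(m) for m in mz_grid]
    if not grid:
        raise MsDeconvError("empty m/z grid")
    if len(set(grid)) != len(grid):
        raise MsDeconvError(f"duplicate m/z in grid: {grid}")
    X = np.array(
        [[b.value(mz) for b in basis_set] for mz in grid], dtype=float
    )
    rank = np.linalg.matrix_rank(X)
    if rank < len(basis_set):
        full_rank = rank
        dependent = [
            b.species
            for i, b in enumerate(basis_set)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == full_rank
        ]
        raise CollinearBasisError(
            f"basis spectra are linearly dependent on grid {grid} "
            f"(rank {rank} < {len(basis_set)}); dependent species: {dependent}"
        )
    return X


@dataclass(frozen=True)
class DeconvolutionFit:
    """Result of a weighted least-squares spectral deconvolution.

    ``a``/``da`` are the basis amplitudes and their rescaled 1-sigma errors
    in amperes; ``covariance`` is the *unscaled* covariance (X^T W X)^-1, so
    ``da[i] = sqrt(covariance[i, i]) * rescale_factor``.  ``chi2_sigma`` is
    the 1-sigma chi-square quantile for ``dof`` degrees of freedom (NaN when
    dof = 0, in which case no rescaling is applied).
    """

    species: tuple[str, ...]
    a: np.ndarray
    da: np.ndarray
    covariance: np.ndarray
    chi2: float
    dof: int
    chi2_sigma: float
    rescale_factor: float
    mz_grid: tuple[int, ...]
    detector: str

    def coefficient(self, species: str) -> tuple[float, float]:
        i = self.species.index(species)
        return float(self.a[i]), float(self.da[i])

    def report(self) -> str:
        """Flat key-value text report of the fit."""
        lines = [
            f"detector = {self.detector}",
            f"mz_grid = {list(self.mz_grid)}",
            f"chi2 = {self.chi2!r}",
            f"dof = {self.dof}",
            f"rescale_factor = {self.rescale_factor!r}",
        ]
        for i, sp in enumerate(self.species):
            lines.append(f"a[{sp}] = {self.a[i]!r} +- {self.da[i]!r}")
        return "\n".join(lines)


def fit_coefficients(
    spectrum: MeasuredSpectrum,
    basis_set: Sequence[BasisSpectrum],
    nonneg: bool = False,
) -> DeconvolutionFit:
    """Estimate basis amplitudes from a measured spectrum.

    Solves the weighted least-squares problem on the spectrum's m/z grid.
    Requires at least as many peaks as basis spectra (M >= N) and a single
    detector shared by the spectrum and every basis spectrum.

    With ``nonneg=True`` the amplitudes are constrained to be >= 0
    (active-set NNLS on the weighted system); the covariance and chi-square
    bookkeeping are unchanged.  The default is the unconstrained estimator;
    a coefficient more negative than -3 of its error triggers a
    :class:`ModelMismatchWarning`, as it usually indicates a wrong or
    incomplete basis set.
    """
    N = len(basis_set)
    M = len(spectrum.entries)
    if M < N:
        raise UnderdeterminedSystemError(
            f"{M} peaks cannot constrain {N} basis spectra (need M >= N)"
        )
    for b in basis_set:
        if b.detector != spectrum.detector:
            raise MixedDetectorError(
                f"basis {b.species!r} is a {b.detector} spectrum but the "
                f"measurement used detector {spectrum.detector}"
            )

    grid = spectrum.mz_grid
    X = build_design_matrix(basis_set, grid)
    y = np.array([p.y for p in spectrum.entries], dtype=float)
    dy = np.array([p.dy for p in spectrum.entries], dtype=float)

    Xw = X / dy[:, None]
    yw = y / dy
    cond = np.linalg.cond(Xw)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise CollinearBasisError(
            f"weighted design matrix is numerically singular "
            f"(condition number {cond:.3g} > {_COND_LIMIT:.0e})"
        )

    if nonneg:
        a, _ = optimize.nnls(Xw, yw)
    else:
        a, *_ = np.linalg.lstsq(Xw, yw, rcond=None)

    covariance = np.linalg.inv(Xw.T @ Xw)
    chi2 = float(np.sum((Xw @ a - yw) ** 2))
    dof = M - N
    if dof > 0:
        chi2_sigma = float(_chi2_dist.ppf(ONE_SIGMA, dof))
        rescale = math.sqrt(chi2 / chi2_sigma) if chi2 > chi2_sigma else 1.0
    else:
        chi2_sigma = float("nan")
        rescale = 1.0
    da = np.sqrt(np.diag(covariance)) * rescale

    for i, b in enumerate(basis_set):
        if da[i] > 0 and a[i] < -3.0 * da[i]:
            warnings.warn(
                f"coefficient of {b.species!r} is {a[i]:.4g} "
                f"({a[i] / da[i]:.1f} sigma below zero): the basis set is "
                "probably wrong or incomplete",
                ModelMismatchWarning,
                stacklevel=2,
            )

    return DeconvolutionFit(
        species=tuple(b.species for b in basis_set),
        a=a,
        da=da,
        covariance=covariance,
        chi2=chi2,
        dof=dof,
        chi2_sigma=chi2_sigma,
        rescale_factor=rescale,
        mz_grid=tuple(grid),
        detector=spectrum.detector,
    )


@dataclass(frozen=True)
class FractionTable:
    """Per-species shares of the modeled ion current at one m/z.

    ``fractions`` maps species to (f, df).  Fractions are reported against
    the modeled total current and sum to 1 exactly; a species with no basis
    intensity at ``mz`` has fraction exactly 0.  Unconstrained fits can
    produce fractions outside [0, 1]; clipping is deferred to the
    compensation step so the raw model output stays inspectable.
    """

    mz: int
    total_y: float
    fractions: Mapping[str, tuple[float, float]]

    def fraction(self, species: str) -> tuple[float, float]:
        try:
            return self.fractions[species]
        except KeyError:
            raise MsDeconvError(f"species {species!r} not in fraction table") from None


def ion_current_fractions(
    fit: DeconvolutionFit,
    basis_set: Sequence[BasisSpectrum],
    mz: int,
    observed: PeakHeight | None = None,
) -> FractionTable:
    """Split the modeled ion current at ``mz`` among the basis species.

    The contribution of species i is c_i = a_i x_i(mz) and its fraction is
    f_i = c_i / sum_k c_k.  Errors come from first-order propagation of the
    coefficient covariance through the ratio (including off-diagonal terms),
    scaled by the fit's error-rescale factor:

        d f_i / d a_k = x_k(mz) (delta_ik - f_i) / total

    ``observed`` is accepted for interface symmetry and diagnostics; the
    denominator is always the modeled total, which for an acceptable fit
    agrees with the observed current within its error.
    """
    if tuple(b.species for b in basis_set) != fit.species:
        raise MsDeconvError("basis_set does not match the fitted species")
    x = np.array([b.value(mz) for b in basis_set], dtype=float)
    c = fit.a * x
    total = float(c.sum())
    if np.all(x == 0.0) or total == 0.0:
        raise UndefinedFractionError(
            f"no basis spectrum contributes ion current at m/z={mz}"
        )
    f = c / total
    fractions: dict[str, tuple[float, float]] = {}
    for i, sp in enumerate(fit.species):
        if x[i] == 0.0:
            fractions[sp] = (0.0, 0.0)
            continue
        grad = x * (-f[i]) / total
        grad[i] += x[i] / total
        var = float(grad @ fit.covariance @ grad)
        df = math.sqrt(max(var, 0.0)) * fit.rescale_factor
        fractions[sp] = (float(f[i]), df)
    return FractionTable(mz=int(mz), total_y=total, fractions=fractions)
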