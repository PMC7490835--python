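"""Interference compensation and peak-height-comparison calibration.

Once a deconvolution has attributed a fraction f of the ion current at the
target m/z to the target species, only that fraction is carried into the
calibration: the compensated peak height is f * y.  Concentrations (or
partial pressures) follow by peak-height comparison against a reference gas
of known composition measured at the same m/z with the same detector:

    c_sample = (y_comp,sample / y_comp,reference) * c_reference

All errors are 1-sigma and combined in quadrature on relative scales; the
detector sensitivity cancels in the ratio, so no absolute calibration is
needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .deconv import FractionTable
from .errors import CalibrationError, ConfigError
from .spectra import PeakHeight

__all__ = [
    "CompensatedPeak",
    "CalibratedAmount",
    "compensate",
    "calibrate",
    "subtract_blank",
]


@dataclass(frozen=True)
class CompensatedPeak:
    """A peak height reduced to the target species' share of the current."""

    mz: int
    species: str
    detector: str
    y_comp: float
    dy_comp: float
    fraction: float
    dfraction: float
    below_detection: bool = False


@dataclass(frozen=True)
class CalibratedAmount:
    """A calibrated concentration or partial pressure with 1-sigma error."""

    species: str
    value: float
    dvalue: float
    units: str = "ppm"
    reference: str = ""


def compensate(
    peak: PeakHeight,
    fractions: FractionTable,
    target_species: str,
    clip: bool = True,
) -> CompensatedPeak:
    """Keep only the target species' share of a measured peak height.

    ``y_comp = f * y`` with ``dy_comp = sqrt((df*y)^2 + (f*dy)^2)`` (the
    relative-quadrature rule, written so it stays finite at f = 0).  Model
    fractions outside [0, 1] — possible with the unconstrained estimator —
    are clipped with a warning: a negative physical contribution is
    meaningless, and f = 0 flags the peak as below detection.
    """
    if fractions.mz != peak.mz:
        raise ConfigError(
            f"fraction table is for m/z={fractions.mz}, peak is m/z={peak.mz}"
        )
    f, df = fractions.fraction(target_species)
    if clip and not 0.0 <= f <= 1.0:
        clipped = min(max(f, 0.0), 1.0)
        warnings.warn(
            f"model fraction of {target_species!r} at m/z={peak.mz} is "
            f"{f:.4g}; clipping to {clipped}",
            UserWarning,
            stacklevel=2,
        )
        f = clipped
    y_comp = f * peak.y
    dy_comp = math.hypot(df * peak.y, f * peak.dy)
    return CompensatedPeak(
        mz=peak.mz,
        species=target_species,
        detector=peak.detector,
        y_comp=y_comp,
        dy_comp=dy_comp,
        fraction=f,
        dfraction=df,
        below_detection=(f == 0.0),
    )


def calibrate(
    sample: CompensatedPeak,
    reference: CompensatedPeak,
    reference_amount: float,
    reference_error: float = 0.0,
    units: str = "ppm",
    reference_label: str = "",
) -> CalibratedAmount:
    """Peak-height comparison of a sample against a reference gas.

    ``value = (sample.y_comp / reference.y_comp) * reference_amount``; the
    relative error is the quadrature sum of both compensated peaks' relative
    errors and, if supplied, the reference amount's.  The reference amount
    must be expressed in the output units (e.g. a 23.1% (vol) reference is
    231000 ppm when calibrating in ppm).
    """
    if sample.species != reference.species:
        raise CalibrationError(
            f"species mismatch: sample {sample.species!r} vs "
            f"reference {reference.species!r}"
        )
    if sample.mz != reference.mz or sample.detector != reference.detector:
        raise CalibrationError(
            f"sample (m/z={sample.mz}, {sample.detector}) and reference "
            f"(m/z={reference.mz}, {reference.detector}) must share m/z and detector"
        )
    if not reference.y_comp > 0:
        raise CalibrationError(
            f"reference compensated peak height must be > 0, got {reference.y_comp}"
        )
    value = sample.y_comp / reference.y_comp * reference_amount
    rel_terms = [reference.dy_comp / reference.y_comp]
    if sample.y_comp != 0:
        rel_terms.append(sample.dy_comp / sample.y_comp)
        if reference_amount != 0:
            rel_terms.append(reference_error / reference_amount)
        dvalue = abs(value) * math.sqrt(sum(t * t for t in rel_terms))
    else:
        # below-detection sample: error driven by the absolute peak error
        dvalue = sample.dy_comp / reference.y_comp * reference_amount
    return CalibratedAmount(
        species=sample.species,
        value=value,
        dvalue=dvalue,
        units=units,
        reference=reference_label,
    )


def subtract_blank(
    peaks: list[PeakHeight], blank: list[PeakHeight], error_floor: float = 0.01
) -> list[PeakHeight]:
    """Subtract a blank analysis from peak heights, errors in quadrature.

    Peaks with no matching blank (same m/z, detector, role) pass through
    unchanged.  The 1% relative error floor is re-applied after subtraction.
    """
    blank_map = {(b.mz, b.detector, b.role): b for b in blank}
    out = []
    for p in peaks:
        b = blank_map.get((p.mz, p.detector, p.role))
        if b is None:
            out.append(p)
            continue
        y = p.y - b.y
        dy = max(math.hypot(p.dy, b.dy), error_floor * abs(y))
        out.append(
            PeakHeight(p.mz, p.detector, y, dy, p.n_peak, p.n_zero, p.role)
        )
    return out
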