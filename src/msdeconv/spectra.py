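"""Basis spectra and measured spectra on an integer m/z grid.

A *basis spectrum* is the normalized ion-current pattern of a single gas
species (or a fixed mixture such as clean air) across m/z, measured once on
the same instrument and ion-source settings as the analyses it will be used
to deconvolve.  Basis spectra are dimensionless and normalized so that their
largest intensity equals 1; any m/z not stored evaluates to exactly zero.

A *measured spectrum* is an ordered set of peak heights (ion currents with
1-sigma errors) recorded with a single detector.  Quadrupole instruments of
the class targeted here carry two detectors — a Faraday cup (``"F"``) and an
electron multiplier (``"M"``) — whose sensitivity ratio drifts, so a
deconvolution never mixes data from both.
"""

from __future__ import annotations

import io
import math
import numbers
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InvalidBasisError, MixedDetectorError, MsDeconvError

DETECTORS = ("F", "M")

#: Tolerance on the max-intensity == 1 normalization invariant.
_NORM_TOL = 1e-12


def _check_detector(detector: str) -> str:
    if detector not in DETECTORS:
        raise MsDeconvError(f"detector must be F or M, got {detector!r}")
    return detector


def _check_mz(mz: object) -> int:
    """Validate an m/z key: positive integer, no silent rounding."""
    if isinstance(mz, bool) or not isinstance(mz, (numbers.Integral, numbers.Real)):
        raise InvalidBasisError(f"m/z must be a positive integer, got {mz!r}")
    if not isinstance(mz, numbers.Integral):
        if not float(mz).is_integer():
            raise InvalidBasisError(
                f"fractional m/z {mz!r} rejected: the instrument resolves "
                "integer m/z only; round explicitly if this is intended"
            )
        mz = int(mz)
    if mz <= 0:
        raise InvalidBasisError(f"m/z must be positive, got {mz}")
    return int(mz)


@dataclass(frozen=True)
class BasisSpectrum:
    """Normalized ion-current pattern of one species over integer m/z.

    Parameters
    ----------
    species:
        Label of the gas species (or mixture) this spectrum represents.
    intensities:
        Mapping from m/z to dimensionless normalized intensity.  The maximum
        stored intensity must equal 1; absent m/z values are exactly 0.
    detector:
        ``"F"`` (Faraday cup) or ``"M"`` (electron multiplier).
    electron_energy:
        Ion-source electron energy in eV.  Documentation only; it never
        enters the numerics, but basis spectra are only transferable between
        analyses run at the same setting.
    """

    species: str
    intensities: Mapping[int, float]
    detector: str = "F"
    electron_energy: float | None = None

    def __post_init__(self) -> None:
        _check_detector(self.detector)
        if not self.intensities:
            raise InvalidBasisError(f"basis {self.species!r}: empty intensity map")
        clean: dict[int, float] = {}
        for mz, v in self.intensities.items():
            mz = _check_mz(mz)
            v = float(v)
            if v < 0:
                raise InvalidBasisError(
                    f"basis {self.species!r}: negative intensity {v} at m/z={mz}"
                )
            clean[mz] = v
        peak = max(clean.values())
        if abs(peak - 1.0) > _NORM_TOL:
            raise InvalidBasisError(
                f"basis {self.species!r}: max intensity is {peak}, not 1 "
                "(use normalize_basis to build a valid spectrum)"
            )
        object.__setattr__(self, "intensities", clean)

    def value(self, mz: int) -> float:
        """Intensity at ``mz``; exactly 0 when the m/z is not stored."""
        return self.intensities.get(_check_mz(mz), 0.0)

    @property
    def mz_values(self) -> tuple[int, ...]:
        return tuple(sorted(self.intensities))


def normalize_basis(
    species: str,
    raw_intensities: Mapping[int, float],
    detector: str = "F",
    electron_energy: float | None = None,
) -> BasisSpectrum:
    """Build a :class:`BasisSpectrum` from raw (unnormalized) intensities.

    Divides every intensity by the maximum so the largest becomes 1.  The
    operation is idempotent and invariant under positive rescaling of the
    input.

    Raises
    ------
    InvalidBasisError
        If the map is empty, contains a negative value, or is all-zero.
    """
    if not raw_intensities:
        raise InvalidBasisError(f"basis {species!r}: empty intensity map")
    vals = {}
    for mz, v in raw_intensities.items():
        mz = _check_mz(mz)
        v = float(v)
        if v < 0:
            raise InvalidBasisError(
                f"basis {species!r}: negative intensity {v} at m/z={mz}"
            )
        vals[mz] = v
    peak = max(vals.values())
    if peak <= 0:
        raise InvalidBasisError(f"basis {species!r}: all intensities are zero")
    return BasisSpectrum(
        species=species,
        intensities={mz: v / peak for mz, v in vals.items()},
        detector=detector,
        electron_energy=electron_energy,
    )


def basis_value(basis: BasisSpectrum, mz: int) -> float:
    """Functional form of :meth:`BasisSpectrum.value`."""
    return basis.value(mz)


@dataclass(frozen=True)
class PeakHeight:
    """One aggregated ion-current peak height.

    ``y`` and ``dy`` are in amperes; ``dy`` is a 1-sigma error.  The
    aggregation pipeline never lets ``dy`` fall below 1% of ``|y|``, because
    the error of the mean underestimates the true measurement error, which
    on this instrument class is about 1% relative at best (see
    :func:`msdeconv.readings.aggregate_peak_heights` and
    :func:`apply_error_floor`).  ``role`` is ``"main"`` for peaks used in the
    peak-height calibration and ``"helper"`` for peaks recorded only to
    constrain the deconvolution.
    """

    mz: int
    detector: str
    y: float
    dy: float
    n_peak: int = 1
    n_zero: int = 0
    role: str = "main"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", _check_mz(self.mz))
        _check_detector(self.detector)
        if self.role not in ("main", "helper"):
            raise MsDeconvError(f"role must be 'main' or 'helper', got {self.role!r}")
        if not self.dy > 0:
            raise MsDeconvError(
                f"peak m/z={self.mz}: dy must be > 0, got {self.dy}"
            )


def apply_error_floor(
    peaks: Iterable[PeakHeight], floor: float = 0.01
) -> list[PeakHeight]:
    """Return copies of ``peaks`` with ``dy`` raised to ``floor * |y|``.

    Used when peak heights come from an external source (e.g. a published
    table) whose quoted errors may sit below the instrument's relative
    error floor.
    """
    out = []
    for p in peaks:
        dy = max(p.dy, floor * abs(p.y))
        out.append(
            PeakHeight(p.mz, p.detector, p.y, dy, p.n_peak, p.n_zero, p.role)
        )
    return out


@dataclass(frozen=True)
class MeasuredSpectrum:
    """Peak heights from a single detector, ready for deconvolution."""

    entries: tuple[PeakHeight, ...]
    detector: str = field(init=False)

    def __init__(self, entries: Sequence[PeakHeight]):
        entries = tuple(entries)
        if not entries:
            raise MsDeconvError("measured spectrum has no entries")
        detectors = {p.detector for p in entries}
        if len(detectors) > 1:
            raise MixedDetectorError(
                "mixed detectors in one spectrum: "
                + ", ".join(sorted(detectors))
                + " (the EM/FC sensitivity ratio drifts; deconvolve per detector)"
            )
        mzs = [p.mz for p in entries]
        if len(set(mzs)) != len(mzs):
            dup = sorted({m for m in mzs if mzs.count(m) > 1})
            raise MsDeconvError(f"duplicate m/z values in spectrum: {dup}")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "detector", entries[0].detector)

    @property
    def mz_grid(self) -> tuple[int, ...]:
        return tuple(p.mz for p in self.entries)

    def peak(self, mz: int) -> PeakHeight:
        for p in self.entries:
            if p.mz == mz:
                return p
        raise MsDeconvError(f"no peak at m/z={mz} in spectrum")


def read_basis_table(
    source: str | os.PathLike | io.TextIOBase,
    detector: str = "F",
    electron_energy: float | None = None,
    normalize: bool = True,
) -> dict[str, BasisSpectrum]:
    """Read basis spectra from a delimited text table.

    Each non-comment line is ``species  m/z  intensity`` (whitespace or
    comma delimited).  Intensities per species are max-normalized unless
    ``normalize=False``, in which case they must already satisfy the
    normalization invariant.
    """
    if isinstance(source, (str, os.PathLike)) and not (
        isinstance(source, str) and "\n" in source
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = str(source)

    raw: dict[str, dict[int, float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 3:
            raise MsDeconvError(
                f"basis table line {lineno}: expected 'species m/z intensity', "
                f"got {line!r}"
            )
        species, mz_s, val_s = parts
        try:
            mz = _check_mz(float(mz_s) if "." in mz_s else int(mz_s))
            val = float(val_s)
        except ValueError as exc:
            raise MsDeconvError(f"basis table line {lineno}: {exc}") from exc
        raw.setdefault(species, {})[mz] = val

    out: dict[str, BasisSpectrum] = {}
    for species, intens in raw.items():
        if normalize:
            out[species] = normalize_basis(species, intens, detector, electron_energy)
        else:
            out[species] = BasisSpectrum(species, intens, detector, electron_energy)
    return out


def write_basis_table(bases: Iterable[BasisSpectrum]) -> str:
    """Serialize basis spectra to the delimited table format."""
    lines = ["# species\tm/z\tintensity"]
    for b in bases:
        for mz in b.mz_values:
            lines.append(f"{b.species}\t{mz}\t{b.intensities[mz]!r}")
    return "\n".join(lines) + "\n"
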