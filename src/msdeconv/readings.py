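"""Raw readings, peak-height aggregation, and the DECONVOLUTION block.

Raw data arrive as repeated PEAK and ZERO ion-current readings per m/z and
detector.  PEAK readings measure the ion current on the peak; ZERO readings
measure the baseline and are subtracted.  Readings marked ``PEAK_DECONV`` /
``ZERO_DECONV`` are *helper* measurements recorded at extra m/z ratios only
to constrain the deconvolution system — they never enter the peak-height
calibration itself.

The plain-text readings dialect is one reading per line::

    2020-03-01T12:00:00 PEAK mz=15 detector=F I=0.629pA

with current units A, mA, uA, nA, pA or fA.  ``DECONVOLUTION:`` records (see
:func:`parse_deconvolution_block`) may be interleaved in the same file.
"""

from __future__ import annotations

import math
import re
import statistics
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, Sequence

from .errors import (
    BlockParseError,
    ConfigError,
    MissingDataError,
    MixedDetectorError,
    MsDeconvError,
)
from .spectra import (
    BasisSpectrum,
    PeakHeight,
    _check_detector,
    _check_mz,
    normalize_basis,
)

__all__ = [
    "RawReading",
    "PeakHeight",
    "DeconvolutionBlock",
    "aggregate_peak_heights",
    "parse_deconvolution_block",
    "write_deconvolution_block",
    "parse_readings",
    "write_readings",
    "READING_KINDS",
]

READING_KINDS = ("PEAK", "ZERO", "PEAK_DECONV", "ZERO_DECONV")

_UNIT_SCALE = {
    "A": 1.0,
    "mA": 1e-3,
    "uA": 1e-6,
    "nA": 1e-9,
    "pA": 1e-12,
    "fA": 1e-15,
}


@dataclass(frozen=True)
class RawReading:
    """A single timestamped ion-current reading.

    ``timestamp`` is in seconds (epoch or experiment-relative); ``current``
    is in amperes and may be negative (baseline noise).
    """

    timestamp: float
    mz: int
    detector: str
    kind: str
    current: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz", _check_mz(self.mz))
        _check_detector(self.detector)
        if self.kind not in READING_KINDS:
            raise MsDeconvError(
                f"reading kind must be one of {READING_KINDS}, got {self.kind!r}"
            )

    @property
    def is_helper(self) -> bool:
        return self.kind.endswith("_DECONV")

    @property
    def is_peak(self) -> bool:
        return self.kind.startswith("PEAK")


def _aggregate(values: Sequence[float], method: str) -> tuple[float, float]:
    """Central value and standard error of the mean of one reading group.

    The scatter-based error is the standard error of the mean regardless of
    ``method`` (the sample median has comparable dispersion on these small
    groups, and the sem is the estimator the downstream error model is
    built on); it is 0 for a single reading, in which case the 1% floor
    takes over downstream.
    """
    if method == "mean":
        center = statistics.fmean(values)
    elif method == "median":
        center = statistics.median(values)
    else:
        raise MsDeconvError(f"aggregation method must be 'mean' or 'median', got {method!r}")
    if len(values) > 1:
        sem = statistics.stdev(values) / math.sqrt(len(values))
    else:
        sem = 0.0
    return center, sem


def aggregate_peak_heights(
    readings: Iterable[RawReading],
    method: str = "mean",
    error_floor: float = 0.01,
) -> list[PeakHeight]:
    """Aggregate repeated raw readings into peak heights with errors.

    Readings are grouped by (m/z, detector, helper-role).  Within a group,
    PEAK-type and ZERO-type readings are aggregated separately (mean or
    median); the peak height is ``agg(PEAK) - agg(ZERO)`` and its 1-sigma
    error is the quadrature sum of the two standard errors of the mean,
    floored at ``error_floor * |y|``.

    Raises
    ------
    MissingDataError
        If a group contains ZERO readings but no PEAK readings.
    """
    groups: dict[tuple[int, str, bool], list[RawReading]] = {}
    for r in readings:
        groups.setdefault((r.mz, r.detector, r.is_helper), []).append(r)
    if not groups:
        raise MissingDataError("no readings to aggregate")

    out: list[PeakHeight] = []
    for (mz, det, helper), grp in sorted(groups.items()):
        peaks = [r.current for r in grp if r.is_peak]
        zeros = [r.current for r in grp if not r.is_peak]
        if not peaks:
            raise MissingDataError(
                f"m/z={mz} detector={det}: ZERO readings without any PEAK readings"
            )
        y_p, sem_p = _aggregate(peaks, method)
        if zeros:
            y_z, sem_z = _aggregate(zeros, method)
        else:
            y_z, sem_z = 0.0, 0.0
        y = y_p - y_z
        dy = max(math.hypot(sem_p, sem_z), error_floor * abs(y))
        if dy <= 0:
            # y == 0 with zero scatter: fall back to a sub-fA token error so
            # that downstream weights stay finite.
            dy = 1e-18
        out.append(
            PeakHeight(
                mz=mz,
                detector=det,
                y=y,
                dy=dy,
                n_peak=len(peaks),
                n_zero=len(zeros),
                role="helper" if helper else "main",
            )
        )
    return out


# --------------------------------------------------------------------------
# DECONVOLUTION block
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DeconvolutionBlock:
    """Configuration of one interference deconvolution.

    ``target_mz`` is the m/z whose ion current will be compensated;
    ``target_species`` names the basis member being quantified there;
    ``ms_ee`` (eV) documents the ion-source electron energy and is not used
    numerically.
    """

    target_mz: int
    target_species: str
    detector: str
    ms_ee: float
    basis: tuple[BasisSpectrum, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_mz", _check_mz(self.target_mz))
        _check_detector(self.detector)
        object.__setattr__(self, "basis", tuple(self.basis))
        names = [b.species for b in self.basis]
        if names.count(self.target_species) != 1:
            raise ConfigError(
                f"target_species {self.target_species!r} must name exactly one "
                f"basis member (basis: {names})"
            )
        if self.target.value(self.target_mz) <= 0:
            raise ConfigError(
                f"target species {self.target_species!r} has no intensity at "
                f"target_mz={self.target_mz}"
            )

    @property
    def target(self) -> BasisSpectrum:
        for b in self.basis:
            if b.species == self.target_species:
                return b
        raise ConfigError(f"{self.target_species!r} not in basis")  # unreachable


_TUPLE_RE = re.compile(r"\(\s*['’‘]([^'’‘]*)['’‘]\s*,([^()]*)\)")


def _parse_field(text: str, name: str, pattern: str) -> str:
    m = re.search(rf"{name}\s*=\s*({pattern})", text)
    if m is None:
        raise BlockParseError(f"DECONVOLUTION block: missing or malformed field {name!r}")
    return m.group(1)


def _balanced_paren_span(text: str, start: int) -> str:
    depth = 0
    for i in range(start, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return text[start : i + 1]
    raise BlockParseError("DECONVOLUTION block: unbalanced parentheses in basis field")


def parse_deconvolution_block(
    text: str,
    electron_energy_override: float | None = None,
) -> DeconvolutionBlock:
    """Parse a ``DECONVOLUTION:`` record into a :class:`DeconvolutionBlock`.

    The record may span one physical line (as written in data files) or
    several.  Fields are ``target_mz``, ``target_species``, ``detector``,
    ``MS_EE`` and ``basis``, separated by ``;``.  Basis tuples accept both
    typographic and ASCII quotes.  Basis intensities whose maximum deviates
    from 1 beyond 1e-9 are re-normalized with a warning.
    """
    flat = " ".join(text.split())
    if "DECONVOLUTION" not in flat:
        raise BlockParseError("not a DECONVOLUTION record")
    body = flat.split("DECONVOLUTION", 1)[1].lstrip(": ")

    target_mz_s = _parse_field(body, "target_mz", r"[-+0-9.eE]+")
    try:
        target_mz = _check_mz(float(target_mz_s) if "." in target_mz_s else int(target_mz_s))
    except MsDeconvError as exc:
        raise BlockParseError(f"DECONVOLUTION block: bad target_mz: {exc}") from exc
    target_species = _parse_field(body, "target_species", r"[^;\s]+")
    detector = _parse_field(body, "detector", r"[^;\s]+")
    if detector not in ("F", "M"):
        raise BlockParseError(f"detector must be F or M, got {detector!r}")
    ms_ee = float(_parse_field(body, "MS_EE", r"[-+0-9.eE]+"))

    m = re.search(r"basis\s*=\s*\(", body)
    if m is None:
        raise BlockParseError("DECONVOLUTION block: missing or malformed field 'basis'")
    basis_text = _balanced_paren_span(body, m.end() - 1)

    bases: list[BasisSpectrum] = []
    matches = list(_TUPLE_RE.finditer(basis_text))
    if not matches:
        raise BlockParseError(
            f"DECONVOLUTION block: no basis tuples found in {basis_text!r}"
        )
    for tup in matches:
        name = tup.group(1)
        nums = [t for t in tup.group(2).replace(",", " ").split() if t]
        if len(nums) < 2 or len(nums) % 2 != 0:
            raise BlockParseError(
                f"DECONVOLUTION block: malformed basis tuple for {name!r} "
                f"at offset {tup.start()}: expected mz,value pairs, got {nums}"
            )
        intens: dict[int, float] = {}
        for mz_s, val_s in zip(nums[0::2], nums[1::2]):
            try:
                mz = _check_mz(float(mz_s) if "." in mz_s else int(mz_s))
                val = float(val_s)
            except (ValueError, MsDeconvError) as exc:
                raise BlockParseError(
                    f"DECONVOLUTION block: malformed basis tuple for {name!r} "
                    f"at offset {tup.start()}: {exc}"
                ) from exc
            intens[mz] = val
        peak = max(intens.values()) if intens else 0.0
        if abs(peak - 1.0) > 1e-9:
            warnings.warn(
                f"basis {name!r}: max intensity {peak} != 1; re-normalizing",
                UserWarning,
                stacklevel=2,
            )
        bases.append(
            normalize_basis(name, intens, detector, electron_energy_override or ms_ee)
        )

    if target_species not in [b.species for b in bases]:
        raise ConfigError(
            f"target_species {target_species!r} not among basis names "
            f"{[b.species for b in bases]}"
        )
    return DeconvolutionBlock(
        target_mz=target_mz,
        target_species=target_species,
        detector=detector,
        ms_ee=ms_ee,
        basis=tuple(bases),
    )


def _fmt_num(v: float) -> str:
    """Shortest decimal representation that round-trips."""
    if float(v).is_integer() and abs(v) < 1e15:
        return repr(float(v))
    return repr(float(v))


def write_deconvolution_block(block: DeconvolutionBlock) -> str:
    """Serialize a block to the single-line record format.

    ``parse_deconvolution_block(write_deconvolution_block(b))`` reproduces
    ``b`` exactly (numbers are written with full round-trip precision).
    """
    ee = block.ms_ee
    ee_s = str(int(ee)) if float(ee).is_integer() else repr(float(ee))
    tuples = []
    for b in block.basis:
        pairs = ", ".join(
            f"{mz},{_fmt_num(b.intensities[mz])}" for mz in b.mz_values
        )
        tuples.append(f"('{b.species}', {pairs})")
    return (
        "DECONVOLUTION: "
        f"target_mz={block.target_mz} ; "
        f"target_species={block.target_species} ; "
        f"detector={block.detector} ; "
        f"MS_EE={ee_s} eV ; "
        f"basis=({', '.join(tuples)})"
    )


# --------------------------------------------------------------------------
# Readings-file dialect
# --------------------------------------------------------------------------

_READING_RE = re.compile(
    r"^(?P<ts>\S+)\s+(?P<kind>PEAK_DECONV|ZERO_DECONV|PEAK|ZERO)\s+"
    r"mz=(?P<mz>\d+)\s+detector=(?P<det>\S+)\s+"
    r"I=(?P<val>[-+0-9.eE]+)(?P<unit>[mupnf]?A)\s*$"
)


def _parse_timestamp(token: str) -> float:
    try:
        return float(token)
    except ValueError:
        pass
    try:
        dt = datetime.fromisoformat(token)
    except ValueError as exc:
        raise BlockParseError(f"bad timestamp {token!r}") from exc
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def parse_readings(text: str) -> tuple[list[RawReading], list[DeconvolutionBlock]]:
    """Parse a readings file into raw readings and DECONVOLUTION blocks.

    Blank lines and ``#`` comments are ignored.  Each DECONVOLUTION record
    must occupy a single physical line (as written by :func:`write_readings`).
    """
    readings: list[RawReading] = []
    blocks: list[DeconvolutionBlock] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("DECONVOLUTION"):
            blocks.append(parse_deconvolution_block(line))
            continue
        m = _READING_RE.match(line)
        if m is None:
            raise BlockParseError(f"readings line {lineno}: cannot parse {line!r}")
        readings.append(
            RawReading(
                timestamp=_parse_timestamp(m.group("ts")),
                mz=int(m.group("mz")),
                detector=m.group("det"),
                kind=m.group("kind"),
                current=float(m.group("val")) * _UNIT_SCALE[m.group("unit")],
            )
        )
    return readings, blocks


def write_readings(
    readings: Iterable[RawReading],
    blocks: Iterable[DeconvolutionBlock] = (),
) -> str:
    """Serialize readings (and optional blocks) to the plain-text dialect."""
    lines = [write_deconvolution_block(b) for b in blocks]
    for r in readings:
        lines.append(
            f"{r.timestamp!r} {r.kind} mz={r.mz} detector={r.detector} "
            f"I={r.current!r}A"
        )
    return "\n".join(lines) + "\n"
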