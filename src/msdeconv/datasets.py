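"""Published validation datasets bundled for self-tests and examples.

Two small measurement campaigns on a portable quadrupole gas mass
spectrometer (Faraday cup "F" and electron multiplier "M" detectors) are
bundled as plain data.  They are the standard worked examples for this
method and exercise both detectors and both interference situations:

* **Methane example** (Faraday cup, 70 eV): CH4 quantified via its CH3+
  fragment at m/z 15, where N2 fragments (15N+) and air interfere.
  Gas-I is 23.1% (vol) CH4 in N2; Gas-II is (250 +/- 13) ppm (vol) CH4 in
  air.  Peak heights at m/z 14, 15, 16, 28, 32 in pA.

* **Neon example** (electron multiplier, 45 eV): 20Ne quantified at
  m/z 20, where doubly charged 40Ar and the H2O isotopologue 20(H2O)+
  interfere.  Gas-III is dry synthetic air spiked with 326 ppm (vol) 20Ne;
  Gas-IV is the same gas humidified; Gas-V is atmospheric air with an Ar
  spike (15.8 ppm 20Ne).  Peak heights at m/z 17, 20, 36 in nA.

Quoted peak-height errors are as published; the 1% relative error floor is
applied when the example is run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .readings import DeconvolutionBlock, parse_deconvolution_block
from .spectra import BasisSpectrum, MeasuredSpectrum, PeakHeight, apply_error_floor

__all__ = [
    "ExampleDataset",
    "methane_example",
    "neon_example",
    "METHANE_BLOCK_TEXT",
]

_PA = 1e-12
_NA = 1e-9

#: The methane deconvolution configuration as it appears in a data file.
METHANE_BLOCK_TEXT = (
    "DECONVOLUTION: target_mz=15 ; target_species=CH4 ; detector=F ; "
    "MS_EE=70 eV ; basis=("
    "('CH4', 14,0.103, 15,0.806, 16,1.0), "
    "('N2', 14,0.059, 15,0.00012, 28,1.0), "
    "('AIR', 14,0.059, 15,0.00014, 16,0.0158, 28,1.0, 32,0.208))"
)


@dataclass(frozen=True)
class ExampleDataset:
    """One bundled validation campaign.

    ``gases`` maps gas label to a :class:`MeasuredSpectrum` (error floor
    already applied); ``block`` is the deconvolution configuration;
    ``reference_gas``/``reference_amount_ppm`` define the calibration
    standard; ``nominal_ppm`` maps sample labels to (value, error) nominal
    compositions where known.
    """

    name: str
    block: DeconvolutionBlock
    gases: dict[str, MeasuredSpectrum]
    reference_gas: str
    reference_amount_ppm: float
    nominal_ppm: dict[str, tuple[float, float]]
    #: Published target-species fractions at the target m/z, per gas, as the
    #: two-decimal (fraction, 1-sigma error) values quoted with the dataset.
    published_fractions: dict[str, tuple[float, float]]


def _spectrum(
    detector: str, unit: float, rows: list[tuple[int, float, float]]
) -> MeasuredSpectrum:
    peaks = [
        PeakHeight(mz=mz, detector=detector, y=y * unit, dy=dy * unit)
        for mz, y, dy in rows
    ]
    return MeasuredSpectrum(apply_error_floor(peaks))


def methane_example() -> ExampleDataset:
    """CH4-at-m/z-15 validation campaign (Faraday cup, 70 eV)."""
    block = parse_deconvolution_block(METHANE_BLOCK_TEXT)
    gases = {
        "Gas-I": _spectrum(
            "F",
            _PA,
            [
                (14, 127.0, 2.0),
                (15, 394.0, 6.0),
                (16, 491.0, 5.0),
                (28, 1123.0, 8.0),
                (32, 2.6, 0.9),
            ],
        ),
        "Gas-II": _spectrum(
            "F",
            _PA,
            [
                (14, 77.6, 0.9),
                (15, 0.629, 0.008),
                (16, 22.7, 0.1),
                (28, 1327.0, 6.0),
                (32, 271.0, 5.0),
            ],
        ),
    }
    return ExampleDataset(
        name="methane",
        block=block,
        gases=gases,
        reference_gas="Gas-I",
        reference_amount_ppm=23.1e4,  # 23.1% (vol)
        nominal_ppm={"Gas-II": (250.0, 13.0)},
        published_fractions={"Gas-I": (1.00, 0.02), "Gas-II": (0.70, 0.03)},
    )


def neon_example() -> ExampleDataset:
    """20Ne-at-m/z-20 validation campaign (electron multiplier, 45 eV)."""
    bases = (
        BasisSpectrum("H2O", {17: 0.164, 18: 1.0, 20: 1.34e-3}, "M", 45.0),
        BasisSpectrum("Ne", {20: 1.0}, "M", 45.0),
        BasisSpectrum("Ar", {20: 1.06e-9, 36: 3.00e-3, 40: 1.0}, "M", 45.0),
    )
    block = DeconvolutionBlock(
        target_mz=20, target_species="Ne", detector="M", ms_ee=45.0, basis=bases
    )
    gases = {
        "Gas-III": _spectrum(
            "M", _NA, [(17, 24.0, 0.1), (20, 0.748, 0.008), (36, 4.59, 0.02)]
        ),
        "Gas-IV": _spectrum(
            "M", _NA, [(17, 96.4, 0.4), (20, 1.37, 0.02), (36, 4.91, 0.02)]
        ),
        "Gas-V": _spectrum(
            "M", _NA, [(17, 20.6, 0.1), (20, 0.197, 0.002), (36, 2.29, 0.01)]
        ),
    }
    return ExampleDataset(
        name="neon",
        block=block,
        gases=gases,
        reference_gas="Gas-III",
        reference_amount_ppm=326.0,
        nominal_ppm={"Gas-IV": (326.0, 0.0), "Gas-V": (15.8, 0.0)},
        published_fractions={
            "Gas-III": (0.74, 0.01),
            "Gas-IV": (0.42, 0.01),
            "Gas-V": (0.14, 0.02),
        },
    )
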