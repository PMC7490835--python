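"""Synthetic raw readings for mixtures of basis spectra.

The forward model is the same linear mixture the deconvolution inverts:
each PEAK reading at m/z mu is sum_i a_i x_i(mu) perturbed by multiplicative
Gaussian noise (relative standard deviation ``noise_rel_sd``, default 1% —
the typical relative peak-height error of the instrument class).  ZERO
readings are baseline noise around 0 with a small additive floor
(default 1e-16 A, i.e. 0.1 fA) so aggregated zeros never have exactly zero
scatter.

One species may optionally drift: its amplitude relaxes exponentially from
a start value to its equilibrium, emulating the slow stabilization of water
vapour in a metal vacuum system after switching gas inlets.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .deconv import DeconvolutionFit, fit_coefficients
from .errors import ConfigError, MsDeconvError
from .readings import RawReading, aggregate_peak_heights
from .spectra import BasisSpectrum, MeasuredSpectrum, normalize_basis

__all__ = [
    "MixtureScenario",
    "simulate_readings",
    "recovery_experiment",
    "RecoveryReport",
    "load_scenario",
]


@dataclass(frozen=True)
class MixtureScenario:
    """A synthetic gas mixture measured repeatedly on one detector.

    ``true_coefficients`` maps each basis species to its amplitude in
    amperes.  ``drift``, if given, is ``(species, tau_s, a_start)``: that
    species' amplitude relaxes as a(t) = a_inf + (a_start - a_inf) *
    exp(-t / tau_s) with a_inf its entry in ``true_coefficients``.
    ``dwell_s`` is the time per reading; readings are laid out sequentially
    (repeat-major, then m/z).
    """

    basis_set: tuple[BasisSpectrum, ...]
    true_coefficients: dict[str, float]
    mz_grid: tuple[int, ...]
    noise_rel_sd: float = 0.01
    n_repeats: int = 10
    seed: int = 0
    drift: tuple[str, float, float] | None = None
    dwell_s: float = 1.0
    zero_noise_sd: float = 1e-16

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis_set", tuple(self.basis_set))
        object.__setattr__(self, "mz_grid", tuple(int(m) for m in self.mz_grid))
        names = [b.species for b in self.basis_set]
        for sp, a in self.true_coefficients.items():
            if sp not in names:
                raise ConfigError(f"true coefficient for unknown species {sp!r}")
            if a < 0:
                raise ConfigError(f"true coefficient of {sp!r} is negative: {a}")
        if self.noise_rel_sd < 0:
            raise ConfigError("noise_rel_sd must be >= 0")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.drift is not None:
            sp, tau, _ = self.drift
            if sp not in names:
                raise ConfigError(f"drift species {sp!r} not in basis set")
            if tau <= 0:
                raise ConfigError("drift time constant must be > 0")

    @property
    def detector(self) -> str:
        return self.basis_set[0].detector


def _amplitudes_at(s: MixtureScenario, t: float) -> np.ndarray:
    a = np.array(
        [s.true_coefficients.get(b.species, 0.0) for b in s.basis_set], dtype=float
    )
    if s.drift is not None:
        sp, tau, a_start = s.drift
        i = [b.species for b in s.basis_set].index(sp)
        a_inf = a[i]
        a[i] = a_inf + (a_start - a_inf) * np.exp(-t / tau)
    return a


def simulate_readings(s: MixtureScenario) -> list[RawReading]:
    """Generate PEAK and ZERO readings for a mixture scenario.

    For repeat r and grid position k, the PEAK reading at time
    t = (r * len(grid) + k) * dwell_s is sum_i a_i(t) x_i(mu_k) * (1 + eps)
    with eps ~ N(0, noise_rel_sd); a matching ZERO reading carries pure
    baseline noise N(0, zero_noise_sd).  Identical seeds give identical
    reading lists.
    """
    rng = np.random.default_rng(s.seed)
    X = np.array(
        [[b.value(mz) for b in s.basis_set] for mz in s.mz_grid], dtype=float
    )
    readings: list[RawReading] = []
    for r in range(s.n_repeats):
        for k, mz in enumerate(s.mz_grid):
            t = (r * len(s.mz_grid) + k) * s.dwell_s
            clean = float(X[k] @ _amplitudes_at(s, t))
            eps = rng.normal(0.0, s.noise_rel_sd) if s.noise_rel_sd > 0 else 0.0
            peak = clean * (1.0 + eps)
            zero = rng.normal(0.0, s.zero_noise_sd) if s.zero_noise_sd > 0 else 0.0
            readings.append(
                RawReading(t, mz, s.detector, "PEAK", peak)
            )
            readings.append(
                RawReading(t + 0.5 * s.dwell_s, mz, s.detector, "ZERO", zero)
            )
    return readings


@dataclass(frozen=True)
class RecoveryReport:
    """True vs estimated amplitudes for one synthetic scenario."""

    species: tuple[str, ...]
    a_true: np.ndarray
    a_est: np.ndarray
    da: np.ndarray
    covered: tuple[bool, ...]  # |a_est - a_true| <= 2 da, per species
    fit: DeconvolutionFit


def recovery_experiment(s: MixtureScenario, method: str = "mean") -> RecoveryReport:
    """Simulate, aggregate and refit one scenario; report parameter recovery.

    Runs the full pipeline (simulate -> aggregate peak heights -> weighted
    least squares) and flags, per species, whether the true amplitude lies
    within 2 estimated sigma of the estimate.  Drift scenarios are refused:
    the estimator assumes stationary amplitudes.
    """
    if s.drift is not None:
        raise MsDeconvError(
            "recovery_experiment requires a drift-free scenario"
        )
    readings = simulate_readings(s)
    peaks = aggregate_peak_heights(readings, method=method)
    spectrum = MeasuredSpectrum(peaks)
    fit = fit_coefficients(spectrum, s.basis_set)
    a_true = np.array(
        [s.true_coefficients.get(b.species, 0.0) for b in s.basis_set], dtype=float
    )
    covered = tuple(
        bool(abs(fit.a[i] - a_true[i]) <= 2.0 * fit.da[i])
        for i in range(len(s.basis_set))
    )
    return RecoveryReport(
        species=fit.species,
        a_true=a_true,
        a_est=fit.a.copy(),
        da=fit.da.copy(),
        covered=covered,
        fit=fit,
    )


def load_scenario(source: str) -> MixtureScenario:
    """Load a :class:`MixtureScenario` from a small YAML config.

    Expected keys: ``detector``, ``mz_grid``, ``basis`` (mapping species ->
    {m/z: intensity}, max-normalized on load), ``true_coefficients``
    (species -> amperes), and optionally ``noise_rel_sd``, ``n_repeats``,
    ``seed``, ``drift`` ({species, tau_s, a_start}), ``dwell_s``,
    ``zero_noise_sd``.  ``source`` is a path or YAML text.
    """
    try:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except (OSError, ValueError):
        cfg = yaml.safe_load(source)
    if not isinstance(cfg, dict):
        raise ConfigError("scenario config must be a mapping")
    try:
        detector = cfg.get("detector", "F")
        bases = tuple(
            normalize_basis(sp, {int(k): float(v) for k, v in intens.items()}, detector)
            for sp, intens in cfg["basis"].items()
        )
        drift = None
        if cfg.get("drift"):
            d = cfg["drift"]
            drift = (str(d["species"]), float(d["tau_s"]), float(d["a_start"]))
        return MixtureScenario(
            basis_set=bases,
            true_coefficients={
                str(k): float(v) for k, v in cfg["true_coefficients"].items()
            },
            mz_grid=tuple(int(m) for m in cfg["mz_grid"]),
            noise_rel_sd=float(cfg.get("noise_rel_sd", 0.01)),
            n_repeats=int(cfg.get("n_repeats", 10)),
            seed=int(cfg.get("seed", 0)),
            drift=drift,
            dwell_s=float(cfg.get("dwell_s", 1.0)),
            zero_noise_sd=float(cfg.get("zero_noise_sd", 1e-16)),
        )
    except KeyError as exc:
        raise ConfigError(f"scenario config: missing key {exc}") from exc
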