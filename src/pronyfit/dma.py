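"""Dynamic mechanical analysis reduction: waveforms -> storage/loss moduli.

A steady-state load/displacement record at one drive frequency is reduced to a
complex stiffness magnitude k* = |L(f)|/|D(f)| (N/mm) and a phase lag delta
(rad) at the drive-frequency DFT bin.  A geometric shape factor
SF = area/thickness (mm) then converts stiffness to moduli:

    E' = k* cos(delta) / SF,      E'' = k* sin(delta) / SF    [MPa]

(N/mm divided by mm gives N/mm^2 = MPa, so no unit factor is needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "SpecimenGeometry",
    "StiffnessResult",
    "ModulusTuple",
    "UnusableWaveformError",
    "compute_stiffness",
    "shape_factor",
    "compute_moduli",
    "read_waveform_csv",
]

MIN_PERIODS = 4
MIN_SAMPLES_PER_PERIOD = 16


class UnusableWaveformError(ValueError):
    """Drive frequency not resolvable on the record's time grid."""


@dataclass(frozen=True)
class Waveform:
    """Uniformly sampled load (N) / displacement (mm) record at one frequency."""

    time_s: np.ndarray
    load_n: np.ndarray
    disp_mm: np.ndarray
    drive_frequency_hz: float

    def __post_init__(self) -> None:
        for name in ("time_s", "load_n", "disp_mm"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.time_s.size == self.load_n.size == self.disp_mm.size):
            raise ValueError("time, load and displacement must share one length")
        if self.drive_frequency_hz <= 0:
            raise ValueError("drive frequency must be positive")


@dataclass(frozen=True)
class SpecimenGeometry:
    diameter_mm: float
    thickness_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("diameter and thickness must be positive")


@dataclass(frozen=True)
class StiffnessResult:
    complex_stiffness_n_per_mm: float  # k*
    phase_lag_rad: float               # delta
    frequency_hz: float


@dataclass(frozen=True)
class ModulusTuple:
    frequency_hz: float
    storage_mpa: float
    loss_mpa: float


def _validate_grid(w: Waveform) -> float:
    dt = np.diff(w.time_s)
    if w.time_s.size < 2 or np.any(dt <= 0):
        raise ValueError("time must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
        raise ValueError("time must be uniformly sampled")
    return float(dt[0])


def compute_stiffness(w: Waveform) -> StiffnessResult:
    """Complex stiffness and phase lag at the drive-frequency DFT bin.

    The record is truncated to the largest integer number of drive periods
    (steady-state sinusoid assumption; no window).  Raises
    :class:`UnusableWaveformError` when the drive frequency sits fewer than
    2 bins below Nyquist, resolves to bin 0, or falls off an integer bin of
    the truncated record.
    """
    dt = _validate_grid(w)
    f = w.drive_frequency_hz
    duration = w.time_s.size * dt
    periods = math.floor(duration * f + 1e-9)
    if periods < MIN_PERIODS:
        raise ValueError(
            f"record covers {periods} periods of {f} Hz; need >= {MIN_PERIODS}")
    samples_per_period = 1.0 / (f * dt)
    if samples_per_period < MIN_SAMPLES_PER_PERIOD:
        raise ValueError(
            f"{samples_per_period:.1f} samples per period; need >= {MIN_SAMPLES_PER_PERIOD}")

    n_keep = round(periods / (f * dt))
    if n_keep > w.time_s.size:
        n_keep = w.time_s.size
    k = periods  # DFT bin index of the drive frequency in the truncated record
    if abs(f * n_keep * dt - k) > 0.01:
        raise UnusableWaveformError(
            f"drive frequency {f} Hz not close to an integer DFT bin")
    if k < 1 or k > n_keep / 2 - 2:
        raise UnusableWaveformError(
            f"drive frequency {f} Hz unresolvable (bin {k} of {n_keep} samples)")

    load_hat = np.fft.rfft(w.load_n[:n_keep])[k]
    disp_hat = np.fft.rfft(w.disp_mm[:n_keep])[k]
    if abs(disp_hat) == 0.0:
        raise UnusableWaveformError("no displacement content at the drive frequency")
    kstar = abs(load_hat) / abs(disp_hat)
    delta = math.remainder(np.angle(load_hat) - np.angle(disp_hat), 2.0 * math.pi)
    delta = delta % math.pi  # wrap to [0, pi)
    return StiffnessResult(complex_stiffness_n_per_mm=float(kstar),
                           phase_lag_rad=float(delta),
                           frequency_hz=f)


def shape_factor(geom: SpecimenGeometry) -> float:
    """SF = cross-sectional area / thickness = pi (d/2)^2 / h, in mm."""
    return math.pi * (geom.diameter_mm / 2.0) ** 2 / geom.thickness_mm


def compute_moduli(stiff: StiffnessResult, sf_mm: float) -> ModulusTuple:
    """E' = k* cos(delta)/SF and E'' = k* sin(delta)/SF, in MPa."""
    if sf_mm <= 0:
        raise ValueError("shape factor must be positive")
    k, d = stiff.complex_stiffness_n_per_mm, stiff.phase_lag_rad
    return ModulusTuple(frequency_hz=stiff.frequency_hz,
                        storage_mpa=k * math.cos(d) / sf_mm,
                        loss_mpa=k * math.sin(d) / sf_mm)


def read_waveform_csv(path: str | Path, drive_frequency_hz: float) -> Waveform:
    """Read a per-frequency waveform CSV with columns time_s, load_N, disp_mm."""
    df = pd.read_csv(path)
    return Waveform(time_s=df["time_s"].to_numpy(),
                    load_n=df["load_N"].to_numpy(),
                    disp_mm=df["disp_mm"].to_numpy(),
                    drive_frequency_hz=drive_frequency_hz)
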