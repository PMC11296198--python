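"""Prony-series (generalized Maxwell) material description.

The normalized relaxation modulus is

    mu(t) = g_inf + sum_k g_k * exp(-t / tau_k),          mu(0) = g_inf + sum g_k

with dimensionless relaxation strengths ``g_k`` and relaxation times ``tau_k``
in seconds.  Its one-sided Fourier transform gives the complex dynamic modulus

    u*(j w) = g_inf + sum_k g_k * (j w tau_k) / (1 + j w tau_k)

whose real and imaginary parts are the (normalized) storage and loss moduli.
The vector (g, tau) lives on an Abaqus-style simplex: 0 < g_k < 1,
sum g_k <= 1, tau ascending, with the equilibrium fraction g_inf = 1 - sum g_k.

Measured storage/loss moduli (in MPa) are compared to these dimensionless
forms after division by an instantaneous-modulus scale ``normalization_scale``
(see :class:`DMADataset`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PronySeries",
    "DMADataset",
    "viability_check",
    "relaxation_modulus",
    "storage_modulus",
    "loss_modulus",
    "complex_modulus",
    "equation_objective",
]

TRAIN = "training"
VALID = "validation"


class CorruptDatasetError(ValueError):
    """A measured modulus is non-positive, so relative misfits are undefined."""


@dataclass(frozen=True)
class PronySeries:
    """Normalized relaxation spectrum: strengths ``g``, times ``tau`` (s), ``g_inf``.

    ``g_inf`` defaults to ``1 - sum(g)``; the constructor performs only type
    normalization — use :func:`viability_check` to test the constraint set.
    """

    g: np.ndarray
    tau: np.ndarray
    g_inf: float | None = None

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.g, dtype=float))
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if g.shape != tau.shape or g.ndim != 1:
            raise ValueError("g and tau must be 1-D sequences of equal length")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "tau", tau)
        if self.g_inf is None:
            object.__setattr__(self, "g_inf", float(1.0 - g.sum()))
        else:
            object.__setattr__(self, "g_inf", float(self.g_inf))

    @property
    def order(self) -> int:
        return self.g.size

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "g": [float(v) for v in self.g],
            "tau_s": [float(v) for v in self.tau],
            "g_inf": float(self.g_inf),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PronySeries":
        p = cls(g=np.asarray(d["g"], dtype=float),
                tau=np.asarray(d["tau_s"], dtype=float),
                g_inf=float(d["g_inf"]) if "g_inf" in d else None)
        if "order" in d and int(d["order"]) != p.order:
            raise ValueError("declared order does not match coefficient count")
        return p

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PronySeries":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_abaqus_table(self) -> str:
        """Rows of an Abaqus ``*VISCOELASTIC, TIME=PRONY`` table: g_k, 0, tau_k."""
        lines = ["*Viscoelastic, time=PRONY"]
        for gk, tk in zip(self.g, self.tau):
            lines.append(f"{gk:.10g}, 0., {tk:.10g}")
        return "\n".join(lines) + "\n"


def viability_check(p: PronySeries, *, atol: float = 1e-9) -> bool:
    """True iff the constraint set holds.

    Checks 0 < g_k < 1, sum g_k <= 1, tau ascending, tau > 0,
    and g_inf consistent with 1 - sum g_k (equilibrium identity).
    Pure predicate; never raises for finite inputs.
    """
    g, tau = p.g, p.tau
    if g.size == 0 or not (np.all(np.isfinite(g)) and np.all(np.isfinite(tau))):
        return False
    if np.any(g <= 0.0) or np.any(g >= 1.0):
        return False
    if g.sum() > 1.0 + atol:
        return False
    if np.any(tau <= 0.0) or np.any(np.diff(tau) < -atol):
        return False
    if not np.isfinite(p.g_inf) or p.g_inf < -atol:
        return False
    if abs(p.g_inf - (1.0 - g.sum())) > 1e-6:
        return False
    return True


# -- frequency- and time-domain forms -------------------------------------

def relaxation_modulus(p: PronySeries, t):
    """Normalized relaxation modulus g_inf + sum g_k exp(-t/tau_k) for t >= 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation modulus defined for t >= 0")
    val = p.g_inf + np.sum(p.g[..., :] * np.exp(-t[..., None] / p.tau), axis=-1)
    return val if val.ndim else float(val)


def storage_modulus(p: PronySeries, omega):
    """Normalized storage modulus g_inf + sum g_k (w tau)^2 / (1 + (w tau)^2)."""
    omega = np.asarray(omega, dtype=float)
    wt = omega[..., None] * p.tau
    val = p.g_inf + np.sum(p.g * wt**2 / (1.0 + wt**2), axis=-1)
    return val if val.ndim else float(val)


def loss_modulus(p: PronySeries, omega):
    """Normalized loss modulus sum g_k (w tau) / (1 + (w tau)^2)."""
    omega = np.asarray(omega, dtype=float)
    wt = omega[..., None] * p.tau
    val = np.sum(p.g * wt / (1.0 + wt**2), axis=-1)
    return val if val.ndim else float(val)


def complex_modulus(p: PronySeries, omega):
    """Complex dynamic modulus g_inf + sum g_k (j w tau)/(1 + j w tau)."""
    omega = np.asarray(omega, dtype=float)
    jwt = 1j * omega[..., None] * p.tau
    val = p.g_inf + np.sum(p.g * jwt / (1.0 + jwt), axis=-1)
    return val if val.ndim else complex(val)


# -- dataset ---------------------------------------------------------------

@dataclass
class DMADataset:
    """Frequency-sweep (f, E', E'') tuples with a training/validation split.

    ``normalization_scale`` (MPa) is the instantaneous-modulus scale dividing
    the measured moduli before comparison with the dimensionless Prony forms.
    """

    freq_hz: np.ndarray
    storage_mpa: np.ndarray
    loss_mpa: np.ndarray
    split: np.ndarray
    normalization_scale: float

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.storage_mpa = np.asarray(self.storage_mpa, dtype=float)
        self.loss_mpa = np.asarray(self.loss_mpa, dtype=float)
        self.split = np.asarray(self.split, dtype=object)
        n = self.freq_hz.size
        if not (self.storage_mpa.size == self.loss_mpa.size == self.split.size == n):
            raise ValueError("all dataset columns must have equal length")
        if np.any(self.freq_hz <= 0):
            raise ValueError("frequencies must be positive")
        labels = set(self.split.tolist())
        if not labels <= {TRAIN, VALID}:
            raise ValueError(f"unknown split labels: {labels - {TRAIN, VALID}}")
        if self.normalization_scale <= 0:
            raise ValueError("normalization_scale must be positive")

    @property
    def n(self) -> int:
        return int(self.freq_hz.size)

    def mask(self, subset: str) -> np.ndarray:
        return self.split == subset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "freq_hz": self.freq_hz,
            "storage_mpa": self.storage_mpa,
            "loss_mpa": self.loss_mpa,
            "split": self.split,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, *, normalization_scale: float,
                 default_split: str = TRAIN) -> "DMADataset":
        df = pd.read_csv(path)
        split = (df["split"].to_numpy(dtype=object) if "split" in df.columns
                 else np.full(len(df), default_split, dtype=object))
        return cls(freq_hz=df["freq_hz"].to_numpy(),
                   storage_mpa=df["storage_mpa"].to_numpy(),
                   loss_mpa=df["loss_mpa"].to_numpy(),
                   split=split,
                   normalization_scale=normalization_scale)


def equation_objective(p: PronySeries, data: DMADataset, subset: str = TRAIN) -> float:
    """Mean squared relative misfit of the Prony dynamic moduli on one split.

    For each tuple i in the subset, with w_i = 2*pi*f_i and measured moduli
    normalized by ``data.normalization_scale``:

        r_i = (u'(w_i)/u_i' - 1)^2 + (u''(w_i)/u_i'' - 1)^2

    and the objective is mean_i r_i (>= 0; zero iff the model reproduces every
    tuple exactly).
    """
    m = data.mask(subset)
    if not np.any(m):
        raise ValueError(f"subset {subset!r} is empty")
    if np.any(data.storage_mpa[m] <= 0) or np.any(data.loss_mpa[m] <= 0):
        raise CorruptDatasetError("measured moduli must be strictly positive")
    omega = 2.0 * np.pi * data.freq_hz[m]
    u1 = data.storage_mpa[m] / data.normalization_scale
    u2 = data.loss_mpa[m] / data.normalization_scale
    r = (storage_modulus(p, omega) / u1 - 1.0) ** 2 \
        + (loss_modulus(p, omega) / u2 - 1.0) ** 2
    return float(np.mean(r))
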