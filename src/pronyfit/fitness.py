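"""Two-track fitness: equation misfit screen + model-based validation errors.

Every candidate gets the cheap equation-based score (mean squared relative
misfit of the Prony dynamic moduli on the training split).  Only the best
``num_in_gen`` candidates are forward-simulated and scored against frozen
validation curves: the averaged ramp test fitted to y = a1 log(b1 x), and the
hysteresis loop's loading branch fitted to the same log form and unloading
branch to y = a2 exp(b2 x) (y stress in MPa, x displacement in mm).  Model
errors are averaged percentage differences in the stress direction at the
model's displacements — loading is stress-controlled, so displacement is the
model's free output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import curve_fit

from .prony import TRAIN, DMADataset, PronySeries, equation_objective
from .simulator import (HysteresisLoop, LoadingProfile, OgdenModel,
                        TimeResponse, extract_hysteresis, simulate,
                        suggested_dt)

__all__ = ["LogCurve", "ExpCurve", "ValidationCurves", "FitnessReport",
           "SimulationSettings", "build_validation_curves", "model_error",
           "evaluate_population", "simulate_candidate"]

log = logging.getLogger(__name__)

RAMP_GRID_POINTS = 100  # common stress grid for replicate averaging


@dataclass(frozen=True)
class LogCurve:
    """y = a * log(b * x) on the displacement interval ``domain``."""

    a: float
    b: float
    domain: tuple
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive for a real logarithm")

    def __call__(self, x):
        return self.a * np.log(self.b * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ExpCurve:
    """y = a * exp(b * x) on the displacement interval ``domain``."""

    a: float
    b: float
    domain: tuple
    rms_residual: float = 0.0

    def __call__(self, x):
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ValidationCurves:
    """Frozen experimental approximations used for every generation."""

    ramp: LogCurve
    upper: LogCurve
    lower: ExpCurve

    def to_yaml(self, path) -> None:
        d = {}
        for name in ("ramp", "upper", "lower"):
            c = getattr(self, name)
            d[name] = {"form": "a*log(b*x)" if isinstance(c, LogCurve) else "a*exp(b*x)",
                       "a": float(c.a), "b": float(c.b),
                       "domain": [float(c.domain[0]), float(c.domain[1])],
                       "rms_residual": float(c.rms_residual)}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def fit_log(x: np.ndarray, y: np.ndarray) -> LogCurve:
    """Least-squares fit of y = a log(b x); linear in (a, a log b).

    Non-positive x are dropped (with a logged warning) since the logarithm
    is undefined there; the domain is truncated accordingly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = x > 0
    if not np.all(keep):
        log.warning("log fit: dropped %d non-positive displacement points",
                    int((~keep).sum()))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need >= 2 positive-displacement points for a log fit")
    A = np.column_stack([np.log(x), np.ones_like(x)])
    (a, c), *_ = np.linalg.lstsq(A, y, rcond=None)
    b = math.exp(c / a)
    resid = y - (a * np.log(x) + c)
    return LogCurve(a=float(a), b=float(b),
                    domain=(float(x.min()), float(x.max())),
                    rms_residual=float(np.sqrt(np.mean(resid**2))))


def fit_exp(x: np.ndarray, y: np.ndarray) -> ExpCurve:
    """Nonlinear least-squares fit of y = a exp(b x), log-linearized start."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points for an exponential fit")
    if np.all(y > 0):
        A = np.column_stack([x, np.ones_like(x)])
        (b0, loga0), *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
        p0 = (math.exp(loga0), b0)
    else:
        p0 = (float(np.mean(y)), 0.0)
    popt, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=10000)
    resid = y - popt[0] * np.exp(popt[1] * x)
    return ExpCurve(a=float(popt[0]), b=float(popt[1]),
                    domain=(float(x.min()), float(x.max())),
                    rms_residual=float(np.sqrt(np.mean(resid**2))))


RESIDUAL_BAND = 0.01  # target max relative lack-of-fit inside a validity window
MIN_WINDOW_FRACTION = 0.4


def _fit_windowed(x: np.ndarray, y: np.ndarray, fitter, band: float,
                  min_keep: float):
    """Fit over the widest displacement window where the form is faithful.

    The two-parameter log/exp forms are empirical descriptions that are not
    valid near zero displacement (the log diverges there) or through the loop
    turning points, so the fit's validity window is chosen from the data: the
    widest fraction-of-range window whose maximum relative residual stays
    within ``band`` (falling back to the window of smallest residual when no
    window meets it, never narrower than ``min_keep`` of the range).  The
    resulting curve ``domain`` bounds where model errors are evaluated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xmax = float(np.max(x))
    best = None
    for lo in np.arange(0.0, 0.51, 0.05):
        for hi in (1.0, 0.95, 0.9, 0.85, 0.8):
            if hi - lo < min_keep:
                continue
            k = (x >= lo * xmax) & (x <= hi * xmax)
            if k.sum() < 4:
                continue
            try:
                c = fitter(x[k], y[k])
            except (ValueError, RuntimeError):
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                ref = np.asarray(c(x[k]))
            if not np.all(np.isfinite(ref)) or np.any(ref <= 0):
                continue
            r = float(np.max(np.abs(y[k] - ref) / ref))
            key = (0, -(hi - lo), r) if r <= band else (1, r, -(hi - lo))
            if best is None or key < best[0]:
                best = (key, c)
    if best is None:
        raise ValueError("no displacement window admits a positive fitted curve")
    return best[1]


def build_validation_curves(ramp_replicates, loop: HysteresisLoop,
                            residual_band: float = RESIDUAL_BAND,
                            min_window_fraction: float = MIN_WINDOW_FRACTION
                            ) -> ValidationCurves:
    """Average ramp replicates on a common stress grid, then fit all three forms.

    ``ramp_replicates``: sequence of (displacement_mm, stress_mpa) pairs from
    repeated load-controlled ramp tests.  Replicates are interpolated onto a
    100-point grid over the overlapping stress range and averaged pointwise.
    Each fit is restricted to a data-driven validity window (see
    :func:`_fit_windowed`), which excludes the seating region of the ramp and
    the reversal transitions of the loop when the forms fail there.
    """
    if len(ramp_replicates) < 1:
        raise ValueError("need at least one ramp replicate")
    lo = max(float(np.min(s)) for _, s in ramp_replicates)
    hi = min(float(np.max(s)) for _, s in ramp_replicates)
    if hi <= lo:
        raise ValueError("ramp replicates have no overlapping stress range")
    grid = np.linspace(lo, hi, RAMP_GRID_POINTS)
    disp_avg = np.mean([np.interp(grid, np.asarray(s), np.asarray(d))
                        for d, s in ramp_replicates], axis=0)
    ramp_fit = _fit_windowed(disp_avg, grid, fit_log,
                             residual_band, min_window_fraction)
    upper_fit = _fit_windowed(loop.upper_disp_mm, loop.upper_stress_mpa,
                              fit_log, residual_band, min_window_fraction)
    lower_fit = _fit_windowed(loop.lower_disp_mm, loop.lower_stress_mpa,
                              fit_exp, residual_band, min_window_fraction)
    return ValidationCurves(ramp=ramp_fit, upper=upper_fit, lower=lower_fit)


def model_error(disp_mm, stress_mpa, curve) -> float:
    """Averaged percentage stress difference against a fitted curve.

    mean over points of |sigma_model - curve(d_model)| / |curve(d_model)| * 100,
    restricted to the curve's fit domain; points where the curve evaluates to 0
    are excluded (count logged).
    """
    d = np.asarray(disp_mm, dtype=float)
    s = np.asarray(stress_mpa, dtype=float)
    lo, hi = curve.domain
    keep = (d >= lo) & (d <= hi)
    d, s = d[keep], s[keep]
    if d.size == 0:
        return float("inf")  # model never enters the validated range
    ref = np.asarray(curve(d), dtype=float)
    nz = ref != 0.0
    if not np.all(nz):
        log.warning("model_error: excluded %d zero-reference points", int((~nz).sum()))
    if not np.any(nz):
        return float("inf")
    return float(np.mean(np.abs(s[nz] - ref[nz]) / np.abs(ref[nz])) * 100.0)


@dataclass(frozen=True)
class FitnessReport:
    """Per-candidate scores; model errors are None for unsimulated candidates."""

    equation_error: float
    ramp_error_pct: float | None = None
    upper_error_pct: float | None = None
    lower_error_pct: float | None = None

    @property
    def mean_error_pct(self) -> float | None:
        parts = (self.ramp_error_pct, self.upper_error_pct, self.lower_error_pct)
        if any(p is None for p in parts):
            return None
        return float(np.mean(parts))

    @property
    def rank_key(self) -> tuple:
        """Simulated candidates (by mean error) rank ahead of screened-only ones."""
        m = self.mean_error_pct
        return (0, m) if m is not None else (1, self.equation_error)

    def to_dict(self) -> dict:
        return {"equation_error": self.equation_error,
                "ramp_error_pct": self.ramp_error_pct,
                "upper_error_pct": self.upper_error_pct,
                "lower_error_pct": self.lower_error_pct,
                "mean_error_pct": self.mean_error_pct}


@dataclass(frozen=True)
class SimulationSettings:
    """Forward-model settings shared by every candidate of a run."""

    ogden: OgdenModel
    profile: LoadingProfile = LoadingProfile()
    thickness_mm: float = 1.5
    dt_refinement: float = 1.0


def simulate_candidate(p: PronySeries, sim: SimulationSettings):
    """Run the two-stage program; return (ramp disp/stress arrays, loop)."""
    dt = suggested_dt(p, sim.profile, sim.dt_refinement)
    resp = simulate(p, sim.ogden, sim.profile, dt=dt, thickness_mm=sim.thickness_mm)
    ramp_mask = resp.time_s < sim.profile.stage_start_time_s
    loop = extract_hysteresis(resp, sim.profile)
    return (resp.disp_mm[ramp_mask], resp.stress_mpa[ramp_mask]), loop


def evaluate_population(pop, data: DMADataset, curves: ValidationCurves,
                        sim: SimulationSettings, num_in_gen: int) -> list[FitnessReport]:
    """Equation screen for everyone; forward simulation for the best num_in_gen.

    A simulation failure (non-physical parameter set) scores the candidate
    worst-in-generation rather than aborting the run.
    """
    eq = [equation_objective(p, data, TRAIN) for p in pop]
    order = np.argsort(eq, kind="stable")
    simulated = set(order[:max(0, num_in_gen)].tolist())

    reports: list[FitnessReport | None] = [None] * len(pop)
    for i, p in enumerate(pop):
        if i not in simulated:
            reports[i] = FitnessReport(equation_error=eq[i])
            continue
        try:
            (ramp_d, ramp_s), loop = simulate_candidate(p, sim)
            reports[i] = FitnessReport(
                equation_error=eq[i],
                ramp_error_pct=model_error(ramp_d, ramp_s, curves.ramp),
                upper_error_pct=model_error(loop.upper_disp_mm,
                                            loop.upper_stress_mpa, curves.upper),
                lower_error_pct=model_error(loop.lower_disp_mm,
                                            loop.lower_stress_mpa, curves.lower))
        except Exception as exc:  # non-physical candidate: worst-in-generation
            log.warning("simulation failed for candidate %d: %s", i, exc)
            reports[i] = FitnessReport(equation_error=eq[i],
                                       ramp_error_pct=float("inf"),
                                       upper_error_pct=float("inf"),
                                       lower_error_pct=float("inf"))
    return reports
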