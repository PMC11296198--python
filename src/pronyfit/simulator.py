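"""Single-material-point forward simulation of the Ogden + Prony solid.

Replaces a meshed finite-element forward model with its exact homogeneous
solution: a uniform bar under uniform uniaxial stress admits a spatially
constant state, so the boundary-value problem reduces to one material point.
Spatial refinement options therefore become time-step refinement options.

Kinematics: incompressible uniaxial compression, principal stretch ``lambda``
(<= 1 in compression), lateral stretches ``lambda^(-1/2)``.  The instantaneous
(hyperelastic) Cauchy stress magnitude of the Ogden solid is

    sigma0(lam) = | sum_i (2 mu_i / alpha_i) (lam^alpha_i - lam^(-alpha_i/2)) |

obtained from U = sum_i 2 mu_i/alpha_i^2 (l1^a + l2^a + l3^a - 3) with the
pressure eliminated by the traction-free lateral condition.

Viscoelasticity: quasi-linear hereditary integral on the instantaneous stress
with the normalized Prony relaxation function, integrated with the standard
exponential recursive update (exact for piecewise-linear sigma0 histories):

    h_k[n+1] = e_k h_k[n] + g_k (1-e_k)/(dt/tau_k) (sigma0[n+1]-sigma0[n]),
    sigma    = g_inf sigma0 + sum_k h_k,         e_k = exp(-dt/tau_k).

The loading is stress-controlled (the experiments are load-led), so each step
solves sigma(lambda) = applied stress by scalar root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .prony import PronySeries

__all__ = [
    "OgdenModel",
    "LoadingProfile",
    "TimeResponse",
    "HysteresisLoop",
    "NonPhysicalParameterError",
    "load_factor",
    "instantaneous_stress",
    "simulate",
    "simulate_stress_history",
    "extract_hysteresis",
    "suggested_dt",
    "measure_dynamic_moduli",
]

LAMBDA_MIN = 0.05
LAMBDA_MAX = 2.0


class NonPhysicalParameterError(RuntimeError):
    """Applied stress exceeds the material capacity on the search interval."""


@dataclass(frozen=True)
class OgdenModel:
    """Ogden hyperelastic coefficient pairs (mu_i in Pa, alpha_i dimensionless)."""

    mu_pa: tuple
    alpha: tuple

    def __post_init__(self) -> None:
        mu = tuple(float(m) for m in self.mu_pa)
        al = tuple(float(a) for a in self.alpha)
        if len(mu) != len(al) or len(mu) == 0:
            raise ValueError("mu and alpha must be non-empty and of equal length")
        if any(m <= 0 for m in mu):
            raise ValueError("shear coefficients mu_i must be positive")
        if any(a == 0 for a in al):
            raise ValueError("exponents alpha_i must be nonzero")
        object.__setattr__(self, "mu_pa", mu)
        object.__setattr__(self, "alpha", al)

    @property
    def order(self) -> int:
        return len(self.mu_pa)

    @property
    def shear_modulus_pa(self) -> float:
        return sum(self.mu_pa)

    @property
    def e_inst_mpa(self) -> float:
        """Instantaneous small-strain Young's modulus, 3*sum(mu), in MPa.

        3G is the incompressible value; it is also the exact small-strain slope
        of this module's uniaxial stress, so it is the natural normalization
        scale for comparing simulated loops with the dimensionless Prony forms.
        """
        return 3.0 * self.shear_modulus_pa / 1e6


@dataclass(frozen=True)
class LoadingProfile:
    """Ramp-then-sinusoid stress program (MPa, s).

    Defaults follow the cartilage protocol: 1 s ramp 0 -> 1.225 MPa, then a
    1 s sinusoid a(t) = 1.225 + 0.493 cos(2 pi f (t - t0)), i.e. 0.732-1.718
    MPa at 1 Hz.  As printed the sinusoid starts at its maximum, a stress jump
    at the stage boundary; set ``phase_continuous`` to start it at the ramp
    end value instead.
    """

    ramp_end_stress_mpa: float = 1.225
    ramp_duration_s: float = 1.0
    sine_mean_mpa: float = 1.225
    sine_amplitude_mpa: float = 0.493
    sine_frequency_hz: float = 1.0
    sine_duration_s: float = 1.0
    phase_continuous: bool = False

    def __post_init__(self) -> None:
        if self.ramp_duration_s <= 0 or self.sine_duration_s <= 0:
            raise ValueError("stage durations must be positive")
        if self.sine_mean_mpa - self.sine_amplitude_mpa <= 0:
            raise ValueError("sinusoid must stay compressive (mean - amplitude > 0)")
        if self.sine_frequency_hz <= 0:
            raise ValueError("sine frequency must be positive")

    @property
    def stage_start_time_s(self) -> float:
        """t0: start of the sinusoidal stage."""
        return self.ramp_duration_s

    @property
    def total_duration_s(self) -> float:
        return self.ramp_duration_s + self.sine_duration_s


def load_factor(t, profile: LoadingProfile):
    """Applied compressive stress (MPa) at time t under the two-stage program."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    t0 = profile.stage_start_time_s
    ramp = profile.ramp_end_stress_mpa * t / profile.ramp_duration_s
    phase = 2.0 * np.pi * profile.sine_frequency_hz * (t - t0)
    if profile.phase_continuous:
        # start the cosine at the phase whose value equals the ramp endpoint
        shift = math.acos(np.clip(
            (profile.ramp_end_stress_mpa - profile.sine_mean_mpa)
            / profile.sine_amplitude_mpa, -1.0, 1.0))
        phase = phase + shift
    sine = profile.sine_mean_mpa + profile.sine_amplitude_mpa * np.cos(phase)
    out = np.where(t < t0, ramp, sine)
    return out if out.ndim else float(out)


# -- Ogden uniaxial stress -------------------------------------------------

def _sigma0_and_slope(lam: float, mu_mpa, alpha):
    """Signed uniaxial Cauchy stress s(lam) (>=0 in compression) and ds/dlam."""
    s = 0.0
    ds = 0.0
    for m, a in zip(mu_mpa, alpha):
        c = 2.0 * m / a
        s -= c * (lam ** a - lam ** (-a / 2.0))
        ds -= c * (a * lam ** (a - 1.0) + (a / 2.0) * lam ** (-a / 2.0 - 1.0))
    return s, ds


def instantaneous_stress(stretch, ogden: OgdenModel):
    """Compressive Cauchy stress magnitude sigma0(lambda) in MPa.

    Zero at lambda = 1 and strictly increasing as lambda decreases.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    mu_mpa = np.asarray(ogden.mu_pa) / 1e6
    al = np.asarray(ogden.alpha)
    terms = (2.0 * mu_mpa / al) * (lam[..., None] ** al - lam[..., None] ** (-al / 2.0))
    val = np.abs(-np.sum(terms, axis=-1))
    return val if val.ndim else float(val)


def _invert_sigma0(target: float, mu_mpa, alpha, lam0: float) -> float:
    """Solve s(lam) = target (signed: positive = compression) for lam.

    Newton from ``lam0`` with a bracketed bisection fallback; s is strictly
    decreasing in lam on (0, inf).
    """
    s_cap, _ = _sigma0_and_slope(LAMBDA_MIN, mu_mpa, alpha)
    s_ten, _ = _sigma0_and_slope(LAMBDA_MAX, mu_mpa, alpha)
    if target > s_cap or target < s_ten:
        raise NonPhysicalParameterError(
            f"applied stress {target:.4g} MPa outside material capacity "
            f"[{s_ten:.4g}, {s_cap:.4g}] MPa on lambda in "
            f"[{LAMBDA_MIN}, {LAMBDA_MAX}]")
    lam = min(max(lam0, LAMBDA_MIN), LAMBDA_MAX)
    tol = 1e-10 * max(1.0, abs(target))
    for _ in range(60):
        s, ds = _sigma0_and_slope(lam, mu_mpa, alpha)
        resid = s - target
        if abs(resid) < tol:
            return lam
        step = resid / ds  # ds < 0
        new = lam - step
        if not (LAMBDA_MIN <= new <= LAMBDA_MAX):
            break
        lam = new
    # fallback: robust bracketing
    return brentq(lambda x: _sigma0_and_slope(x, mu_mpa, alpha)[0] - target,
                  LAMBDA_MIN, LAMBDA_MAX, xtol=1e-14, rtol=8.9e-16)


# -- time integration ------------------------------------------------------

@dataclass
class TimeResponse:
    """Simulated stress-controlled history at one material point."""

    time_s: np.ndarray
    stress_mpa: np.ndarray
    stretch: np.ndarray
    disp_mm: np.ndarray
    internal: np.ndarray  # per-branch memory stresses h_k, shape (n, N)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s,
                             "stress_mpa": self.stress_mpa,
                             "disp_mm": self.disp_mm})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _check_structural(prony: PronySeries) -> None:
    if np.any(prony.g < 0) or prony.g.sum() > 1.0 + 1e-9:
        raise ValueError("relaxation strengths must be >= 0 with sum <= 1")
    if np.any(prony.tau <= 0):
        raise ValueError("relaxation times must be positive")


def simulate_stress_history(prony: PronySeries, ogden: OgdenModel,
                            time_s: np.ndarray, stress_mpa: np.ndarray,
                            thickness_mm: float = 1.5) -> TimeResponse:
    """Integrate the QLV response to an arbitrary uniform-grid stress history.

    The first sample is treated as an instantaneous step from the virgin state
    (h_k = g_k * sigma0, the exact hereditary response to a jump).
    """
    _check_structural(prony)
    time_s = np.asarray(time_s, dtype=float)
    stress = np.asarray(stress_mpa, dtype=float)
    n = time_s.size
    if n < 2 or stress.size != n:
        raise ValueError("need matching time/stress arrays with >= 2 samples")
    dt = float(time_s[1] - time_s[0])
    if not np.allclose(np.diff(time_s), dt, rtol=1e-8, atol=1e-12):
        raise ValueError("time grid must be uniform")

    mu_mpa = tuple(m / 1e6 for m in ogden.mu_pa)
    alpha = ogden.alpha
    g = prony.g.tolist()
    tau = prony.tau.tolist()
    g_inf = float(prony.g_inf)
    nb = len(g)
    e_k = [math.exp(-dt / tk) for tk in tau]
    c_k = [gk * (1.0 - ek) / (dt / tk) for gk, tk, ek in zip(g, tau, e_k)]
    a_coef = g_inf + sum(c_k)
    c_sum = sum(c_k)
    g_sum = sum(g)

    lam_hist = np.empty(n)
    h_hist = np.empty((n, nb))
    h = [0.0] * nb
    # initial step: instantaneous (glassy) response to stress[0]
    s0 = stress[0] / (g_inf + g_sum) if stress[0] != 0.0 else 0.0
    lam = _invert_sigma0(s0, mu_mpa, alpha, 1.0) if s0 != 0.0 else 1.0
    h = [gk * s0 for gk in g]
    lam_hist[0] = lam
    h_hist[0] = h
    sig0_prev = s0

    for i in range(1, n):
        b = sum(ek * hk for ek, hk in zip(e_k, h)) - c_sum * sig0_prev
        s0_target = (stress[i] - b) / a_coef
        lam = _invert_sigma0(s0_target, mu_mpa, alpha, lam)
        d_s0 = s0_target - sig0_prev
        h = [ek * hk + ck * d_s0 for ek, hk, ck in zip(e_k, h, c_k)]
        sig0_prev = s0_target
        lam_hist[i] = lam
        h_hist[i] = h

    return TimeResponse(time_s=time_s,
                        stress_mpa=stress,
                        stretch=lam_hist,
                        disp_mm=thickness_mm * (1.0 - lam_hist),
                        internal=h_hist)


def suggested_dt(prony: PronySeries, profile: LoadingProfile,
                 refinement: float = 1.0) -> float:
    """Default integration step, scaled down by ``refinement`` (<= 1; the
    analog of choosing a finer mesh).

    Meets the resolution requirements dt <= min(tau)/5 and dt <= 1/(50 f),
    and additionally samples each sine cycle with >= 200 points so that
    pointwise statistics over the extracted loop (branch-mean model errors)
    approximate their continuous averages.
    """
    dt = min(float(np.min(prony.tau)) / 5.0,
             1.0 / (200.0 * profile.sine_frequency_hz))
    return dt * refinement


def simulate(prony: PronySeries, ogden: OgdenModel, profile: LoadingProfile,
             dt: float | None = None, thickness_mm: float = 1.5) -> TimeResponse:
    """Stress-controlled response to the two-stage ramp + sinusoid program."""
    if dt is None:
        dt = suggested_dt(prony, profile)
    if prony.g.sum() > 0 and dt > float(np.min(prony.tau)) / 5.0 * (1 + 1e-9):
        raise ValueError("dt must be <= min(tau)/5")
    if dt > 1.0 / (50.0 * profile.sine_frequency_hz) * (1 + 1e-9):
        raise ValueError("dt must be <= 1/(50 * sine frequency)")
    n = int(math.ceil(profile.total_duration_s / dt - 1e-9)) + 1
    t = np.arange(n) * dt
    stress = load_factor(t, profile)
    return simulate_stress_history(prony, ogden, t, stress, thickness_mm)


# -- hysteresis extraction -------------------------------------------------

@dataclass
class HysteresisLoop:
    """Loading/unloading branches of the final steady-state stress cycle.

    Displacements are shifted so the loop minimum is exactly 0.  ``area`` is
    the signed cyclic integral of stress over displacement (MPa*mm): the
    energy dissipated per cycle per unit cross-section.
    """

    upper_disp_mm: np.ndarray
    upper_stress_mpa: np.ndarray
    lower_disp_mm: np.ndarray
    lower_stress_mpa: np.ndarray
    cycle_index: int
    area: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "disp_mm": np.concatenate([self.upper_disp_mm, self.lower_disp_mm]),
            "stress_mpa": np.concatenate([self.upper_stress_mpa, self.lower_stress_mpa]),
            "branch": ["upper"] * self.upper_disp_mm.size
                      + ["lower"] * self.lower_disp_mm.size,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class InsufficientCyclesError(ValueError):
    """The response does not cover one full sinusoid cycle after the ramp."""


def extract_hysteresis(resp: TimeResponse, profile: LoadingProfile) -> HysteresisLoop:
    """Final-cycle hysteresis loop, normalized and split at stress turning points.

    Rising-stress samples form the upper (loading) branch, falling-stress the
    lower (unloading) branch.
    """
    period = 1.0 / profile.sine_frequency_hz
    t_end = float(resp.time_s[-1])
    if t_end - profile.stage_start_time_s < period * (1 - 1e-9):
        raise InsufficientCyclesError(
            "response must cover at least one full sinusoid cycle after the ramp")
    mask = resp.time_s >= t_end - period - 1e-12
    disp = resp.disp_mm[mask]
    stress = resp.stress_mpa[mask]
    disp = disp - disp.min()  # loop minimum normalized to 0

    rising = np.empty(stress.size, dtype=bool)
    d = np.diff(stress)
    rising[:-1] = d > 0
    rising[-1] = rising[-2]

    # signed path integral of sigma over displacement around the cycle
    area = float(np.trapezoid(stress, disp))

    cycle_index = int(round((t_end - profile.stage_start_time_s) / period)) - 1
    return HysteresisLoop(upper_disp_mm=disp[rising],
                          upper_stress_mpa=stress[rising],
                          lower_disp_mm=disp[~rising],
                          lower_stress_mpa=stress[~rising],
                          cycle_index=cycle_index,
                          area=area)


# -- frequency-domain readout of the time-domain model ---------------------

def measure_dynamic_moduli(prony: PronySeries, ogden: OgdenModel,
                           omega_rad_s: float,
                           rel_amplitude: float = 1e-4,
                           rel_mean: float = 1e-3) -> tuple[float, float]:
    """Storage/loss moduli (MPa) read off a small-amplitude steady-state loop.

    Applies sigma(t) = (rel_mean + rel_amplitude cos(w t)) * E_inst, integrates
    past the transient (10 * max tau), and extracts the fundamental of the
    final cycle by DFT; E* = sigma_hat / eps_hat with eps = 1 - lambda.
    In the linear limit E*/E_inst reproduces the Prony storage/loss forms.
    """
    e_inst = ogden.e_inst_mpa
    period = 2.0 * math.pi / omega_rad_s
    tau_min = float(np.min(prony.tau))
    tau_max = float(np.max(prony.tau))
    # the phase error of the trapezoidal hereditary update is O((w dt)^2) and
    # is amplified relative to a small loss tangent, so sample cycles densely
    spc = max(400, int(math.ceil(5.0 * period / tau_min)))
    dt = period / spc
    # under stress control the transient decays with the creep (retardation)
    # time ~ tau/g_inf, not the relaxation time
    creep_time = tau_max / max(float(prony.g_inf), 0.05)
    n_cycles = int(math.ceil(12.0 * creep_time / period)) + 2
    n = n_cycles * spc + 1
    t = np.arange(n) * dt
    stress = e_inst * (rel_mean + rel_amplitude * np.cos(omega_rad_s * t))
    resp = simulate_stress_history(prony, ogden, t, stress, thickness_mm=1.0)

    eps = 1.0 - resp.stretch
    sl = slice(n - 1 - spc, n - 1)  # exactly one final period
    phase = np.exp(-2j * math.pi * np.arange(spc) / spc)
    sig_hat = np.sum((stress[sl] - stress[sl].mean()) * phase)
    eps_hat = np.sum((eps[sl] - eps[sl].mean()) * phase)
    e_star = sig_hat / eps_hat
    return float(e_star.real), float(e_star.imag)
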