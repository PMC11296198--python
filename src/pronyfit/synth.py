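"""Synthetic study-shaped datasets from known ground-truth parameters.

Emulates the shape of a cartilage DMA study: a 1-90 Hz frequency sweep of
168 (frequency, storage, loss) tuples with a random 128/40 train/validation
split, six replicate load-controlled ramp tests, and a steady-state
hysteresis loop under 0.7-1.7 MPa sinusoidal stress.  Moduli noise is
multiplicative lognormal (biological moduli vary over orders of magnitude and
must stay positive); ramp displacement noise is additive Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .config import DEFAULT_OGDEN, split_dataset
from .prony import DMADataset, PronySeries, loss_modulus, storage_modulus, viability_check
from .simulator import (HysteresisLoop, LoadingProfile, OgdenModel,
                        extract_hysteresis, simulate, suggested_dt)

__all__ = ["GroundTruth", "default_truth", "make_dma_dataset",
           "make_validation_series", "make_workspace"]


@dataclass(frozen=True)
class GroundTruth:
    """Known generating parameters for synthetic fixtures."""

    prony: PronySeries
    ogden: OgdenModel = DEFAULT_OGDEN
    e_inst_mpa: float | None = None
    noise_cv: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not viability_check(self.prony):
            raise ValueError("ground-truth Prony series must be viable")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def scale_mpa(self) -> float:
        return self.e_inst_mpa if self.e_inst_mpa is not None else self.ogden.e_inst_mpa


def default_truth(noise_cv: float = 0.0, rng_seed: int = 0) -> GroundTruth:
    """N=3 fixture with transitions placed inside the 1-90 Hz window."""
    prony = PronySeries(g=np.array([0.1, 0.15, 0.2]),
                        tau=np.array([0.005, 0.05, 0.5]))
    return GroundTruth(prony=prony, noise_cv=noise_cv, rng_seed=rng_seed)


def make_dma_dataset(truth: GroundTruth, n_tuples: int = 168,
                     f_range: tuple = (1.0, 90.0),
                     rng: np.random.Generator | None = None) -> DMADataset:
    """Log-spaced frequency sweep with replicates, lognormal noise and split.

    Frequencies are log-spaced over ``f_range`` with ~3 replicates per
    frequency to reach ``n_tuples``; storage/loss follow the Prony forms at
    w = 2 pi f scaled by the instantaneous modulus, each multiplied by
    lognormal noise of coefficient of variation ``truth.noise_cv``.  A
    168-tuple sweep splits 128/40 (training/validation); other sizes use the
    same ratio.
    """
    if n_tuples < 2:
        raise ValueError("need at least two tuples")
    if not (0 < f_range[0] < f_range[1]):
        raise ValueError("f_range must be a positive increasing interval")
    rng = rng if rng is not None else np.random.default_rng(truth.rng_seed)

    n_unique = max(2, int(np.ceil(n_tuples / 3)))
    freqs = np.tile(np.geomspace(f_range[0], f_range[1], n_unique), 3)[:n_tuples]
    freqs = np.sort(freqs)
    omega = 2.0 * np.pi * freqs
    storage = truth.scale_mpa * storage_modulus(truth.prony, omega)
    loss = truth.scale_mpa * loss_modulus(truth.prony, omega)
    if truth.noise_cv > 0:
        s = np.sqrt(np.log1p(truth.noise_cv**2))
        storage = storage * np.exp(rng.normal(-s * s / 2.0, s, size=freqs.size))
        loss = loss * np.exp(rng.normal(-s * s / 2.0, s, size=freqs.size))
    return split_dataset(freqs, storage, loss,
                         normalization_scale=truth.scale_mpa, rng=rng)


def make_validation_series(truth: GroundTruth,
                           profile: LoadingProfile = LoadingProfile(),
                           n_ramp_replicates: int = 6,
                           disp_noise_frac: float = 0.005,
                           thickness_mm: float = 1.5,
                           rng: np.random.Generator | None = None):
    """Forward-simulate the truth and emit ramp replicates + hysteresis loop.

    Ramp replicates carry additive Gaussian displacement noise with standard
    deviation ``disp_noise_frac`` times the peak ramp displacement (0 for
    exact replicates).
    """
    if n_ramp_replicates < 1:
        raise ValueError("need at least one ramp replicate")
    rng = rng if rng is not None else np.random.default_rng(truth.rng_seed + 1)

    resp = simulate(truth.prony, truth.ogden, profile,
                    dt=suggested_dt(truth.prony, profile),
                    thickness_mm=thickness_mm)
    ramp_mask = resp.time_s < profile.stage_start_time_s
    base_d = resp.disp_mm[ramp_mask]
    base_s = resp.stress_mpa[ramp_mask]
    sigma = disp_noise_frac * float(base_d.max())
    replicates = []
    for _ in range(n_ramp_replicates):
        noise = rng.normal(0.0, sigma, size=base_d.size) if sigma > 0 else 0.0
        replicates.append((base_d + noise, base_s.copy()))
    loop = extract_hysteresis(resp, profile)
    return replicates, loop


def make_workspace(out_dir, truth: GroundTruth | None = None,
                   profile: LoadingProfile = LoadingProfile(),
                   n_tuples: int = 168) -> dict:
    """Write a complete demo workspace (CSV/YAML) and return the file map."""
    truth = truth if truth is not None else default_truth()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.rng_seed)

    data = make_dma_dataset(truth, n_tuples=n_tuples, rng=rng)
    data.to_csv(out / "dma_data.csv")
    replicates, loop = make_validation_series(truth, profile, rng=rng)
    import pandas as pd
    for i, (d, s) in enumerate(replicates, start=1):
        pd.DataFrame({"disp_mm": d, "stress_mpa": s}).to_csv(
            out / f"ramp_{i:02d}.csv", index=False)
    loop.to_csv(out / "hysteresis_loop.csv")
    (out / "truth.yaml").write_text(yaml.safe_dump({
        "prony": truth.prony.to_dict(),
        "ogden": {"mu_pa": list(truth.ogden.mu_pa), "alpha": list(truth.ogden.alpha)},
        "e_inst_mpa": truth.scale_mpa,
        "noise_cv": truth.noise_cv,
        "rng_seed": truth.rng_seed,
    }, sort_keys=False))
    return {"dma_data": out / "dma_data.csv",
            "ramps": sorted(out.glob("ramp_*.csv")),
            "loop": out / "hysteresis_loop.csv",
            "truth": out / "truth.yaml"}
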