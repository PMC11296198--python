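"""Run configuration: global model constants, material sets, dataset split.

The original workflow drove everything from two spreadsheets (global model
variables + hyperelastic coefficient sets); here those are YAML documents
with the same content.  Mesh-spacing fields from the spreadsheet era
("GridSpace...") have no spatial meaning for the material-point forward
model; when present they are parsed, logged, and mapped to time-step
refinement presets rather than silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .prony import TRAIN, VALID, DMADataset
from .simulator import LoadingProfile, OgdenModel
from .genetic import GAConfig

__all__ = ["DEFAULT_OGDEN", "GlobalConfig", "MaterialConfig", "ConfigError",
           "load_configs", "save_configs", "split_dataset", "DT_PRESETS"]

log = logging.getLogger(__name__)

# Fixed Ogden hyperelastic set for human femoral-head articular cartilage
DEFAULT_OGDEN = OgdenModel(mu_pa=(26_133_000.0, 12_922_000.0, 13_227_000.0),
                           alpha=(2.7190, 3.9960, 1.504))

# Spatial-refinement options of the FE era become dt refinement factors
DT_PRESETS = {"coarse": 1.0, "medium": 0.5, "fine": 0.25}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GlobalConfig:
    """Geometry, loading and discretization constants shared by a run."""

    diameter_mm: float = 8.0
    thickness_mm: float = 1.5
    poisson_ratio: float = 0.45
    e_inst_mpa: float | None = None   # None -> 3 * sum(mu) of the material set
    dt_preset: str = "coarse"
    ramp_end_stress_mpa: float = 1.225
    ramp_duration_s: float = 1.0
    sine_mean_mpa: float = 1.225
    sine_amplitude_mpa: float = 0.493
    sine_frequency_hz: float = 1.0
    sine_duration_s: float = 1.0
    phase_continuous: bool = False
    grid_space: dict | None = None    # legacy mesh fields; logged only

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.thickness_mm <= 0:
            raise ConfigError("geometry lengths must be positive")
        if self.dt_preset not in DT_PRESETS:
            raise ConfigError(f"dt_preset must be one of {sorted(DT_PRESETS)}")
        if self.grid_space:
            log.info("legacy grid fields %s mapped to dt preset %r",
                     self.grid_space, self.dt_preset)

    @property
    def dt_refinement(self) -> float:
        return DT_PRESETS[self.dt_preset]

    def loading_profile(self) -> LoadingProfile:
        return LoadingProfile(ramp_end_stress_mpa=self.ramp_end_stress_mpa,
                              ramp_duration_s=self.ramp_duration_s,
                              sine_mean_mpa=self.sine_mean_mpa,
                              sine_amplitude_mpa=self.sine_amplitude_mpa,
                              sine_frequency_hz=self.sine_frequency_hz,
                              sine_duration_s=self.sine_duration_s,
                              phase_continuous=self.phase_continuous)

    def normalization_scale(self, ogden: OgdenModel) -> float:
        return self.e_inst_mpa if self.e_inst_mpa is not None else ogden.e_inst_mpa


@dataclass(frozen=True)
class MaterialConfig:
    """One or more fixed Ogden coefficient sets (all of matched order)."""

    sets: tuple = (DEFAULT_OGDEN,)

    def __post_init__(self) -> None:
        if len(self.sets) == 0:
            raise ConfigError("need at least one Ogden coefficient set")

    @property
    def primary(self) -> OgdenModel:
        return self.sets[0]


def _material_from_dict(d: dict) -> MaterialConfig:
    sets = []
    for i, s in enumerate(d.get("ogden_sets", [])):
        mu, al = s.get("mu_pa", []), s.get("alpha", [])
        if len(mu) != len(al):
            raise ConfigError(
                f"ogden set {i}: {len(mu)} mu values vs {len(al)} alpha values")
        sets.append(OgdenModel(mu_pa=tuple(mu), alpha=tuple(al)))
    return MaterialConfig(sets=tuple(sets)) if sets else MaterialConfig()


def load_configs(global_path=None, material_path=None, ga_path=None,
                 order: int = 3):
    """Read (GlobalConfig, MaterialConfig, GAConfig) from YAML paths.

    ``None`` paths fall back to packaged defaults (the cartilage protocol and
    its fixed Ogden set); an explicit path that does not exist raises an
    error naming it.
    """
    def read(path):
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        return yaml.safe_load(p.read_text()) or {}

    gconf = GlobalConfig(**read(global_path)) if global_path else GlobalConfig()
    mconf = _material_from_dict(read(material_path)) if material_path else MaterialConfig()
    if ga_path:
        gad = read(ga_path)
        gad.setdefault("order", order)
        gaconf = GAConfig(**gad)
    else:
        gaconf = GAConfig(order=order)
    return gconf, mconf, gaconf


def save_configs(out_dir, gconf: GlobalConfig, mconf: MaterialConfig,
                 gaconf: GAConfig) -> dict:
    """Write the three configs back to YAML (round-trips with load_configs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gp = out / "global.yaml"
    d = asdict(gconf)
    gp.write_text(yaml.safe_dump(d, sort_keys=False))
    mp = out / "material.yaml"
    mp.write_text(yaml.safe_dump({
        "ogden_sets": [{"mu_pa": list(s.mu_pa), "alpha": list(s.alpha)}
                       for s in mconf.sets]}, sort_keys=False))
    ap = out / "ga.yaml"
    gad = asdict(gaconf)
    gad.pop("seed_config", None)
    ap.write_text(yaml.safe_dump(gad, sort_keys=False))
    return {"global": gp, "material": mp, "ga": ap}


def split_dataset(freq_hz, storage_mpa, loss_mpa, *, normalization_scale: float,
                  train_fraction: float = 128.0 / 168.0,
                  rng: np.random.Generator | None = None) -> DMADataset:
    """Uniform random train/validation split; 168 tuples always split 128/40."""
    freq_hz = np.asarray(freq_hz, dtype=float)
    n = freq_hz.size
    if n < 2:
        raise ValueError("need at least two tuples to split")
    rng = rng if rng is not None else np.random.default_rng()
    n_train = 128 if n == 168 else int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    idx = rng.choice(n, size=n_train, replace=False)
    split = np.full(n, VALID, dtype=object)
    split[idx] = TRAIN
    return DMADataset(freq_hz=freq_hz, storage_mpa=storage_mpa,
                      loss_mpa=loss_mpa, split=split,
                      normalization_scale=normalization_scale)
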