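"""Study configuration: YAML schema, validation, defaults, and hashing.

A study config fully determines a simulated multi-center study: the root
seed, the cohort (subjects per center and the demographic ranges they are
sampled from), the scanner profiles, the rendering settings, the
second-measurement perturbation, and the analysis thresholds. The default
configuration reproduces the dual-center design: Center 1 scans each
subject twice on both a 1.5-T and a 3-T scanner, Center 2 twice on one 3-T
scanner.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .synth import (
    Grid,
    Perturbation,
    RepeatVariability,
    ScannerProfile,
    SimulationSettings,
)

__all__ = [
    "CenterConfig",
    "DemographicsConfig",
    "StudyConfig",
    "ConfigError",
    "default_config",
    "fixture_config",
    "load_config",
    "save_config",
    "config_hash",
]


class ConfigError(ValueError):
    """Raised for malformed study configurations; lists offending keys."""


@dataclass(frozen=True)
class CenterConfig:
    name: str
    n_subjects: int
    profiles: tuple[str, ...]


@dataclass(frozen=True)
class DemographicsConfig:
    """Sampling ranges for the simulated healthy adult cohort."""

    age_range: tuple[float, float] = (19.0, 45.0)
    female_fraction: float = 0.7
    breathing_frequency_range: tuple[float, float] = (9.0, 18.0)  # breaths/min
    tidal_volume_range: tuple[float, float] = (280.0, 700.0)  # mL
    sv_mean_range: tuple[float, float] = (0.18, 0.32)
    sv_correlation_length: float = 20.0  # mm
    defect_fraction: float = 0.0
    semiaxes_base: tuple[float, float, float] = (40.0, 50.0, 75.0)  # mm
    semiaxes_jitter: float = 0.08


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    centers: tuple[CenterConfig, ...] = ()
    profiles: dict[str, ScannerProfile] = field(default_factory=dict)
    demographics: DemographicsConfig = DemographicsConfig()
    grid: Grid = Grid((24, 24, 24), (8.0, 8.0, 8.0))
    n_phases: int = 12
    navigator_duration_s: float = 120.0
    navigator_dt_s: float = 0.1
    navigator_noise_sd: float = 0.05
    perturbation: Perturbation = Perturbation()
    repeat_variability: RepeatVariability = RepeatVariability()
    vvp_rvent_fraction: float = 0.4
    vvp_rvent_percentile: float = 90.0
    fvlcm_threshold: float = 0.9
    map_cov_ddof: int = 0

    def simulation_settings(self) -> SimulationSettings:
        return SimulationSettings(
            grid=self.grid,
            n_phases=self.n_phases,
            navigator_duration_s=self.navigator_duration_s,
            navigator_dt_s=self.navigator_dt_s,
            navigator_noise_sd=self.navigator_noise_sd,
            repeat_variability=self.repeat_variability,
        )

    def analysis_kwargs(self) -> dict:
        return {
            "vvp_fraction": self.vvp_rvent_fraction,
            "vvp_percentile": self.vvp_rvent_percentile,
            "fvlcm_threshold": self.fvlcm_threshold,
            "cov_ddof": self.map_cov_ddof,
        }

    def validate(self) -> None:
        problems: list[str] = []
        names = [c.name for c in self.centers]
        if len(set(names)) != len(names):
            problems.append("centers: duplicate center names")
        for c in self.centers:
            if c.n_subjects < 0:
                problems.append(f"centers.{c.name}.n_subjects: must be >= 0")
            for p in c.profiles:
                if p not in self.profiles:
                    problems.append(f"centers.{c.name}.profiles: unknown profile '{p}'")
        if self.n_phases < 3:
            problems.append("n_phases: must be >= 3")
        if self.navigator_dt_s <= 0:
            problems.append("navigator_dt_s: must be > 0")
        if not 0 < self.vvp_rvent_fraction:
            problems.append("vvp_rvent_fraction: must be > 0")
        if not 0 < self.vvp_rvent_percentile <= 100:
            problems.append("vvp_rvent_percentile: must be in (0, 100]")
        if problems:
            raise ConfigError("invalid study config: " + "; ".join(problems))


def default_config(seed: int = 0) -> StudyConfig:
    """Full-scale dual-center study: 24 + 26 subjects, three scanners.

    The scanner profiles encode the expected field-strength contrast: the
    3-T profiles have lower parenchymal SNR and a more heterogeneous
    ventilation-weighted signal than 1.5 T.
    """
    profiles = {
        "C1-1.5T": ScannerProfile("C1-1.5T", 1.5, snr=500.0, heterogeneity_scale=1.0),
        "C1-3T": ScannerProfile("C1-3T", 3.0, snr=320.0, heterogeneity_scale=1.3),
        "C2-3T": ScannerProfile("C2-3T", 3.0, snr=320.0, heterogeneity_scale=1.3),
    }
    cfg = StudyConfig(
        seed=seed,
        centers=(
            CenterConfig("Center1", 24, ("C1-1.5T", "C1-3T")),
            CenterConfig("Center2", 26, ("C2-3T",)),
        ),
        profiles=profiles,
    )
    cfg.validate()
    return cfg


def fixture_config(seed: int = 0, n_per_center: int = 4) -> StudyConfig:
    """Small fast study for tests and smoke runs (same design, fewer subjects)."""
    cfg = default_config(seed)
    return replace(
        cfg,
        centers=tuple(
            CenterConfig(c.name, n_per_center, c.profiles) for c in cfg.centers
        ),
    )


def _to_plain(cfg: StudyConfig) -> dict:
    d = asdict(cfg)
    d["centers"] = [asdict(c) for c in cfg.centers]
    d["profiles"] = {k: asdict(v) for k, v in cfg.profiles.items()}
    return d


def save_config(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(_to_plain(cfg))), fh, sort_keys=True)


def _tuple3(x, key: str, problems: list[str]):
    try:
        t = tuple(float(v) for v in x)
    except (TypeError, ValueError):
        problems.append(f"{key}: expected a 3-vector")
        return (1.0, 1.0, 1.0)
    if len(t) != 3:
        problems.append(f"{key}: expected a 3-vector")
        return (1.0, 1.0, 1.0)
    return t


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study config; unknown keys are reported."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    problems: list[str] = []

    known = {
        "seed", "centers", "profiles", "demographics", "grid", "n_phases",
        "navigator_duration_s", "navigator_dt_s", "navigator_noise_sd",
        "perturbation", "repeat_variability", "vvp_rvent_fraction", "vvp_rvent_percentile",
        "fvlcm_threshold", "map_cov_ddof",
    }
    for key in raw:
        if key not in known:
            problems.append(f"unknown key '{key}'")

    profiles = {}
    for name, pr in (raw.get("profiles") or {}).items():
        try:
            profiles[name] = ScannerProfile(
                label=name,
                field_strength=float(pr["field_strength"]),
                snr=float(pr.get("snr", np.inf)),
                heterogeneity_scale=float(pr.get("heterogeneity_scale", 1.0)),
                signal_scale=float(pr.get("signal_scale", 100.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"profiles.{name}: {exc}")

    centers = []
    for c in raw.get("centers") or []:
        try:
            centers.append(
                CenterConfig(
                    name=str(c["name"]),
                    n_subjects=int(c["n_subjects"]),
                    profiles=tuple(c["profiles"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"centers: {exc}")

    demo_raw = raw.get("demographics") or {}
    demo_kwargs = {}
    demo_fields = DemographicsConfig.__dataclass_fields__
    for key, val in demo_raw.items():
        if key not in demo_fields:
            problems.append(f"demographics: unknown key '{key}'")
            continue
        if key == "semiaxes_base":
            demo_kwargs[key] = _tuple3(val, f"demographics.{key}", problems)
        elif key.endswith("_range"):
            demo_kwargs[key] = (float(val[0]), float(val[1]))
        else:
            demo_kwargs[key] = float(val)
    demographics = DemographicsConfig(**demo_kwargs)

    grid_raw = raw.get("grid") or {}
    grid = Grid(
        shape=tuple(int(v) for v in grid_raw.get("shape", (24, 24, 24))),
        voxel_size=_tuple3(grid_raw.get("voxel_size", (8.0, 8.0, 8.0)), "grid.voxel_size", problems),
    )

    pert_raw = raw.get("perturbation") or {}
    perturbation = Perturbation(
        tidal_factor=float(pert_raw.get("tidal_factor", 1.0)),
        frequency_factor=float(pert_raw.get("frequency_factor", 1.0)),
    )

    rv_raw = raw.get("repeat_variability") or {}
    repeat_variability = RepeatVariability(
        amplitude_sd=float(rv_raw.get("amplitude_sd", 0.10)),
        frequency_sd=float(rv_raw.get("frequency_sd", 0.08)),
        regional_sd=float(rv_raw.get("regional_sd", 0.12)),
        lag_sd=float(rv_raw.get("lag_sd", 0.03)),
    )

    if problems:
        raise ConfigError("invalid study config: " + "; ".join(problems))

    cfg = StudyConfig(
        seed=int(raw.get("seed", 0)),
        centers=tuple(centers),
        profiles=profiles,
        demographics=demographics,
        grid=grid,
        n_phases=int(raw.get("n_phases", 12)),
        navigator_duration_s=float(raw.get("navigator_duration_s", 120.0)),
        navigator_dt_s=float(raw.get("navigator_dt_s", 0.1)),
        navigator_noise_sd=float(raw.get("navigator_noise_sd", 0.05)),
        perturbation=perturbation,
        repeat_variability=repeat_variability,
        vvp_rvent_fraction=float(raw.get("vvp_rvent_fraction", 0.4)),
        vvp_rvent_percentile=float(raw.get("vvp_rvent_percentile", 90.0)),
        fvlcm_threshold=float(raw.get("fvlcm_threshold", 0.9)),
        map_cov_ddof=int(raw.get("map_cov_ddof", 0)),
    )
    cfg.validate()
    return cfg


def config_hash(cfg: StudyConfig) -> str:
    """Stable short hash of the canonical config serialization."""
    canon = json.dumps(_to_plain(cfg), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
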