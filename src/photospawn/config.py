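"""Pipeline configuration: validated, fully-defaulted, seed-disciplined.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name (SHA-256 of ``"{seed}:{stage}"``, reduced below
2^31), so a single integer reproduces the entire pipeline bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass, field, fields

__all__ = ["PipelineConfig", "CampaignBlock", "AnalysisBlock",
           "LandscapeBlock", "ConfigError", "load_config", "dump_config",
           "stage_seed"]


class ConfigError(ValueError):
    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class CampaignBlock:
    n_ics: int = 300                 # thermal FC ensemble size
    temperature: float = 300.0       # K
    n_select: int = 15               # bright-S2 ICs promoted for SSAIMS
    ic_delta_e_center: float = -0.6  # eV, center of the selection window
    runs_per_ic: int = 5
    horizon: float = 500.0           # fs
    dt: float = 0.25                 # fs
    spawn_threshold: float = 0.01    # fs^-1
    overlap_threshold: float = 1e-3
    max_tbfs: int = 12
    n_nve: int = 50                  # FC-launched S1 trajectories
    nve_horizon: float = 1000.0      # fs
    n_nvt: int = 15
    nvt_horizon: float = 900.0       # fs
    nvt_friction: float = 1e-3       # fs^-1


@dataclass
class AnalysisBlock:
    le_max: float = 20.0             # Debye
    ct_min: float = 25.0             # Debye
    dwell: float = 10.0              # fs
    sigma_dipole: float = 1.91       # Debye
    sigma_time: float = 0.75         # fs
    n_boot: int = 1000
    spectrum_fwhm: float = 0.15      # eV


@dataclass
class LandscapeBlock:
    n_images: int = 20
    climbing: bool = True
    n_meci_points: int = 5
    n_env_snapshots: int = 24


@dataclass
class PipelineConfig:
    model_path: str | None = None    # None -> packaged calibrated model
    seed: int = 1
    out_root: str = "runs"
    campaign: CampaignBlock = field(default_factory=CampaignBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)
    landscape: LandscapeBlock = field(default_factory=LandscapeBlock)

    def stage_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)


_BLOCKS = {"campaign": CampaignBlock, "analysis": AnalysisBlock,
           "landscape": LandscapeBlock}


def _build(cls, data, where, problems):
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, val in data.items():
        if key not in known:
            problems.append(f"unknown key {where}{key}")
            continue
        ftype = known[key].type
        if isinstance(val, dict):
            problems.append(f"{where}{key}: unexpected table")
            continue
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:
        problems.append(f"{where}: {exc}")
        return cls()


def load_config(path) -> PipelineConfig:
    """Load and validate a TOML pipeline configuration.

    All violations (unknown keys, type mismatches, missing model file) are
    collected and reported together in a single :class:`ConfigError`.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    problems = []
    top = {}
    for key, val in data.items():
        if key in _BLOCKS:
            top[key] = _build(_BLOCKS[key], val, f"{key}.", problems)
        elif key in ("model_path", "seed", "out_root"):
            top[key] = val
        else:
            problems.append(f"unknown key {key}")
    cfg = PipelineConfig(**top) if not problems else None
    if cfg is None:
        raise ConfigError(problems)
    for name, typ in (("seed", int), ("out_root", str)):
        if not isinstance(getattr(cfg, name), typ):
            problems.append(f"{name}: expected {typ.__name__}")
    if cfg.model_path is not None:
        import os
        if not isinstance(cfg.model_path, str):
            problems.append("model_path: expected string")
        elif not os.path.exists(cfg.model_path):
            problems.append(f"model file not found: {cfg.model_path}")
    if problems:
        raise ConfigError(problems)
    return cfg


def _to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_dict(getattr(obj, f.name))
                for f in fields(obj)}
    return obj


def dump_config(cfg: PipelineConfig, path):
    """Write a config back to TOML (round-trips through load_config)."""
    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, str):
            return f'"{v}"'
        return repr(v)

    d = _to_dict(cfg)
    lines = []
    for key in ("model_path", "seed", "out_root"):
        if d[key] is not None:
            lines.append(f"{key} = {fmt(d[key])}")
    for block in _BLOCKS:
        lines.append(f"\n[{block}]")
        for k, v in d[block].items():
            lines.append(f"{k} = {fmt(v)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
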