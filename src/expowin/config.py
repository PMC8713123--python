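"""Run configuration: YAML-backed constants and paths for the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from expowin.exposure import DEFAULT_WINDOWS


@dataclass
class RunConfig:
    # inputs (any may be None when a stage is driven from fixtures)
    weather_csv: str | None = None
    aq_csv: str | None = None
    panel_csv: str | None = None
    cohort_csv: str | None = None
    out_dir: str = "runs/run"

    outcome: str = "EASI10"
    family: str = "binomial"
    variables: tuple = ("wind", "humidity", "temperature", "NO", "NO2", "O3", "PM10", "PM2.5")
    windows: tuple = DEFAULT_WINDOWS
    collinearity_threshold: float = 0.8
    delta_aic: float = 6.0
    nesting_tolerance: float = 2.0
    dp_edf_threshold: float = 0.05
    bootstrap_resamples: int = 2000
    env_k: int = 10
    confounder_k: int = 10
    tensor_k: int = 5
    confounder_smooths: tuple = ("age", "BMI", "TEWL", "SH")
    confounder_tensor: tuple = ()          # e.g. ("lon", "lat")
    confounder_factors: tuple = ("sex", "season", "investigator", "esec")
    seed: int = 0
    em_df_per_year: float = 12.0
    em_max_iterations: int = 100
    em_tolerance: float = 1e-4

    def __post_init__(self) -> None:
        self.windows = tuple(sorted(int(w) for w in self.windows))
        for name in ("collinearity_threshold", "delta_aic", "nesting_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dp_edf_threshold < 0:
            raise ValueError("dp_edf_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variables", "windows", "confounder_smooths",
                    "confounder_tensor", "confounder_factors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def write_resolved(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]
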