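"""Study configuration (YAML-loadable)."""

from __future__ import annotations

import hashlib
import json

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError
from .synthetic_ehr import GeneratorConfig


def default_d_grid() -> list[float]:
    # 0..30 km in 0.5 km steps: 61 points, fine resolution below 10 km included
    return [i / 2.0 for i in range(61)]


class StudyConfig(BaseModel):
    cohort_year: int = 2018
    index_date: str | None = None  # ISO date; default Jan 1 of cohort_year + 1
    window_months: list[int] = Field(default_factory=lambda: [6, 12])
    d_km: float | None = 8.0
    d_grid: list[float] = Field(default_factory=default_d_grid)
    rounding_decimals: int = 2
    # phenotype-mode toggles
    ckd_window_mode: str = "full"  # "full" | "cohort_year"
    ckd_mixed_pairs: bool = True
    klompas_span: tuple[str, str] = ("2011-01-01", "2018-12-31")
    klompas_distinct_days: bool = False
    seed: int = 0
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    plots: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.ckd_window_mode not in ("full", "cohort_year"):
            raise ConfigError(f"unknown ckd_window_mode {self.ckd_window_mode!r}")
        grid = self.d_grid
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("d_grid must be strictly increasing")
        return self

    @property
    def index_timestamp(self) -> pd.Timestamp:
        if self.index_date is not None:
            return pd.Timestamp(self.index_date)
        return pd.Timestamp(year=self.cohort_year + 1, month=1, day=1)

    @property
    def ckd_window(self):
        if self.ckd_window_mode == "cohort_year":
            return (pd.Timestamp(year=self.cohort_year, month=1, day=1),
                    pd.Timestamp(year=self.cohort_year, month=12, day=31))
        return None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
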