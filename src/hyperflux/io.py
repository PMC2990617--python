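"""Run configuration, CSV formats and provenance.

Conventions enforced everywhere: UTF-8 CSV with a header row and '.'
decimal separator, no index column; times in seconds, rates in s⁻¹,
chemical shifts in ppm.  Configs are YAML validated against pydantic
schemas; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .cohort import NoiseConfig, SchedulePoint, TreatmentSchedule
from .kinetics import DEFAULT_R1, AcquisitionScheme
from .model import PeakSeries

__all__ = [
    "ConfigError",
    "SeriesFormatError",
    "SchemeConfig",
    "SimulateConfig",
    "CohortConfig",
    "load_config",
    "read_peak_series",
    "write_provenance",
]

SERIES_COLUMNS = ("time_s", "peak", "intensity")


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


class SeriesFormatError(ValueError):
    """Malformed series CSV (missing column, wrong types, ...)."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SchemeConfig(_StrictModel):
    flip_angle_deg: float
    repetition_time_s: float = 1.0
    n_transients: int
    t_first_s: float | None = None
    excluded_indices: list[int] = Field(default_factory=list)

    def to_scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(
            flip_angle_deg=self.flip_angle_deg,
            repetition_time_s=self.repetition_time_s,
            n_transients=self.n_transients,
            t_first_s=self.t_first_s,
            excluded_indices=frozenset(self.excluded_indices),
        )


class SimulateConfig(_StrictModel):
    scheme: SchemeConfig
    k_fwd: float
    k_rev: float = 0.0
    r1_sub: float = DEFAULT_R1
    r1_prod: float = DEFAULT_R1
    m0_sub: float = 1.0
    m0_prod: float = 0.0
    noise_sd: float = 0.0  # fraction of the initial substrate signal
    substrate: str = "pyruvate"
    product: str = "lactate"
    seed: int = 0


class SchedulePointConfig(_StrictModel):
    time_h: float
    kp_scale: float = 1.0
    kf_true: float = 0.0
    nadh_scale: float = 1.0
    apoptotic_frac: float = 0.0
    necrotic_frac: float = 0.0


class CohortConfig(_StrictModel):
    schedule: list[SchedulePointConfig]
    kp_baseline: float = 0.075
    scheme: SchemeConfig = SchemeConfig(flip_angle_deg=6.0, n_transients=240)
    n_per_group: int = 4
    biological_cv: float = 0.10
    observation_noise: float = 0.02
    n_events: int = 20_000
    seed: int = 0

    def to_schedule(self) -> TreatmentSchedule:
        return TreatmentSchedule(
            points=tuple(SchedulePoint(**p.model_dump()) for p in self.schedule),
            kp_baseline=self.kp_baseline,
        )

    def to_noise(self) -> NoiseConfig:
        return NoiseConfig(
            biological_cv=self.biological_cv,
            observation_noise=self.observation_noise,
        )


def load_config(path, model: type[_StrictModel]):
    """Load and validate a YAML config; raise ConfigError on any problem."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def read_peak_series(path, substrate: str, product: str) -> PeakSeries:
    """Read a long-format series CSV (time_s, peak, intensity)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface parser errors verbatim
        raise SeriesFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for col in SERIES_COLUMNS:
        if col not in df.columns:
            raise SeriesFormatError(
                f"{path}: missing required column {col!r} "
                f"(expected columns {', '.join(SERIES_COLUMNS)})"
            )
    try:
        return PeakSeries.from_dataframe(df, substrate, product)
    except ValueError as exc:
        raise SeriesFormatError(f"{path}: {exc}") from exc


def config_hash(config: BaseModel) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def write_provenance(path, config: BaseModel | dict, seed: int) -> None:
    """Record what produced an output: config hash, seed, versions.

    Deliberately excludes timestamps so repeated runs are byte-identical.
    """
    import numpy
    import scipy

    if isinstance(config, BaseModel):
        digest = config_hash(config)
        dump = config.model_dump(mode="json")
    else:
        payload = json.dumps(config, sort_keys=True)
        digest = hashlib.sha256(payload.encode()).hexdigest()
        dump = config
    record = {
        "config": dump,
        "config_sha256": digest,
        "seed": seed,
        "versions": {
            "hyperflux": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=1, sort_keys=True) + "\n")
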