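"""Single JSON configuration document shared by the CLI and the pipeline.

The document has optional blocks ``constants``, ``electrode``, ``kinetics``,
``peak_windows``, ``loads_by_scan_rate``, ``transport``, ``mc``, ``ionic``
and ``battery``; omitted blocks fall back to the package defaults, so an
empty document is a valid configuration. Validation failures are reported
with a JSON-pointer-style path to the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .battery import BatteryInputs
from .constants import ElectrodeConfig, KineticsParams, PhysicalConstants
from .cv_energetics import DEFAULT_PEAK_WINDOWS
from .electrolyte import IonicModelConfig
from .errors import ConfigurationError
from .mc_engine import MCConfig
from .transport import TransportConfig

__all__ = ["AppConfig", "load_config", "DEFAULT_LOADS_BY_SCAN_RATE"]

#: Published pairing of scan rate (V/s) with applied load (MOhm) — tabulated
#: data, not a formula.
DEFAULT_LOADS_BY_SCAN_RATE: dict[float, float] = {
    0.010: 1.81,
    0.020: 2.21,
    0.050: 3.85,
    0.100: 5.13,
    0.150: 7.35,
    0.200: 8.00,
}


class AppConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    constants: PhysicalConstants = Field(default_factory=PhysicalConstants)
    electrode: ElectrodeConfig = Field(default_factory=ElectrodeConfig)
    kinetics: KineticsParams = Field(default_factory=KineticsParams)
    peak_windows: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: dict(DEFAULT_PEAK_WINDOWS)
    )
    loads_by_scan_rate: dict[float, float] = Field(
        default_factory=lambda: dict(DEFAULT_LOADS_BY_SCAN_RATE)
    )
    transport: TransportConfig = Field(default_factory=TransportConfig)
    mc: MCConfig = Field(default_factory=MCConfig)
    ionic: IonicModelConfig = Field(default_factory=IonicModelConfig)
    battery: BatteryInputs = Field(default_factory=BatteryInputs)


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load (or default-construct) the configuration document."""
    if path is None:
        return AppConfig()
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(raw) if raw.strip() else {}
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return AppConfig.model_validate(data)
    except ValidationError as exc:
        pointers = "; ".join(
            "/" + "/".join(str(loc) for loc in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        )
        raise ConfigurationError(f"{path}: {pointers}") from exc
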