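"""Run configuration: defaults, flat key=value round-trip, hashing.

The whole pipeline is driven by one ``RunConfig`` whose sections mirror the
library's parameter objects (physiologic constants, scenario, measurement
model, analysis options). The on-disk form is a flat ``section.key = value``
text file; every field has a documented default and the file round-trips
losslessly, so a config hash identifies a run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .physiology import PhysioConstants
from .simulate import MeasurementModel, ScenarioParams

__all__ = ["AnalysisConfig", "RunConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Options for the comparison stage."""

    reference: str = "co_oximetry"
    #: Override for the concordance exclusion zone in percentage points;
    #: non-negative value uses that zone, negative derives it from the
    #: reference method's LSC and mean baseline SvO2.
    exclusion_zone_points: float = -1.0
    ci_method: str = "wilson"
    ba_variant: str = "repeated"  # or "simple"
    round_report: bool = True


@dataclass(frozen=True)
class RunConfig:
    constants: PhysioConstants = field(default_factory=PhysioConstants)
    scenario: ScenarioParams = field(default_factory=ScenarioParams)
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = -1  # required for simulation; negative means unset
    n_animals: int = 10
    outdir: str = "results"

    _SECTIONS = ("constants", "scenario", "measurement", "analysis")

    def to_flat(self) -> dict[str, object]:
        out: dict[str, object] = {}
        for section in self._SECTIONS:
            obj = getattr(self, section)
            for f in fields(obj):
                out[f"{section}.{f.name}"] = getattr(obj, f.name)
        out["run.seed"] = self.seed
        out["run.n_animals"] = self.n_animals
        out["run.outdir"] = self.outdir
        return out

    def to_text(self) -> str:
        lines = []
        for key, value in sorted(self.to_flat().items()):
            if isinstance(value, tuple):
                value = ",".join(repr(v) if isinstance(v, str) else str(v) for v in value)
            lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        defaults = cls()
        flat = defaults.to_flat()
        overrides: dict[str, object] = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in flat:
                raise ValueError(f"config line {lineno}: unknown key '{key}'")
            overrides[key] = _coerce(val, flat[key])
        flat.update(overrides)
        return cls._from_flat(flat)

    @classmethod
    def _from_flat(cls, flat: dict[str, object]) -> "RunConfig":
        kwargs = {}
        for section, typ in (
            ("constants", PhysioConstants),
            ("scenario", ScenarioParams),
            ("measurement", MeasurementModel),
            ("analysis", AnalysisConfig),
        ):
            section_kwargs = {
                f.name: flat[f"{section}.{f.name}"] for f in fields(typ)
            }
            kwargs[section] = typ(**section_kwargs)
        return cls(
            seed=int(flat["run.seed"]),
            n_animals=int(flat["run.n_animals"]),
            outdir=str(flat["run.outdir"]),
            **kwargs,
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_text(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def replace(self, **changes) -> "RunConfig":
        return dataclasses.replace(self, **changes)

    def exclusion_zone_or_none(self) -> float | None:
        z = self.analysis.exclusion_zone_points
        return None if z < 0 else z


def _coerce(val: str, default: object):
    """Parse a config value string according to the default's type."""
    if isinstance(default, bool):
        if val.lower() in ("true", "1", "yes"):
            return True
        if val.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"expected boolean, got '{val}'")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(val)
    if isinstance(default, float):
        return float(val)
    if isinstance(default, tuple):
        if not val:
            return ()
        return tuple(float(v) for v in val.split(","))
    return val
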