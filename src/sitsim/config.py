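"""Scenario configuration: defaults, YAML round-trip, release sizing.

A :class:`ScenarioConfig` fully specifies one simulation experiment —
life history, intervention system with overrides, release schedule,
horizon, mode, realizations and seed — and is what the ensemble layer
consumes. Defaults ship in ``sitsim/data/defaults.yaml``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field, replace
from functools import lru_cache
from typing import Any

import yaml

from .cubes import InterventionCube, build_cube
from .dynamics import LifeHistory, ReleaseSchedule


@lru_cache(maxsize=1)
def load_defaults() -> dict[str, Any]:
    """Parsed contents of the packaged defaults file."""
    text = (
        importlib.resources.files("sitsim.data").joinpath("defaults.yaml").read_text()
    )
    return yaml.safe_load(text)


def default_life_history(**overrides) -> LifeHistory:
    vals = dict(load_defaults()["life_history"])
    vals.update(overrides)
    return LifeHistory(**vals)


@dataclass
class ScenarioConfig:
    """One fully specified simulation scenario.

    ``release_reference`` selects what 'per wild adult' means when sizing
    releases: ``total_adults`` (equilibrium males + females, the default),
    or ``females`` (equilibrium females only). The reference count is
    fixed at the pre-intervention equilibrium for all events.
    """

    system: str = "wild"
    life_history: dict[str, Any] = field(default_factory=dict)
    cube_overrides: dict[str, Any] = field(default_factory=dict)
    ratio: float | None = None
    period: int = 7
    n_releases: int = 26
    first_day: int = 1
    release_reference: str = "total_adults"
    horizon: int = 365
    mode: str = "stochastic"
    realizations: int = 100
    seed: int = 1

    def make_life_history(self) -> LifeHistory:
        return default_life_history(**self.life_history)

    def make_cube(self) -> InterventionCube:
        defaults = load_defaults()["intervention"].get(self.system, {})
        overrides = dict(self.cube_overrides)
        c = overrides.pop("c", defaults.get("competitiveness"))
        omega = overrides.pop("omega", defaults.get("mortality_multiplier"))
        if self.system == "wild":
            c = None
            omega = None
        return build_cube(self.system, c=c, omega=omega, **overrides)

    def release_ratio(self) -> float:
        if self.ratio is not None:
            return self.ratio
        defaults = load_defaults()["intervention"].get(self.system)
        return 0.0 if defaults is None else float(defaults["ratio"])

    def make_schedule(self, cube: InterventionCube, lh: LifeHistory) -> ReleaseSchedule:
        ratio = self.release_ratio()
        if self.system == "wild" or ratio == 0 or cube.release_stage is None:
            return ReleaseSchedule()
        if self.release_reference == "total_adults":
            reference = 2.0 * lh.n_female_eq
        elif self.release_reference == "females":
            reference = lh.n_female_eq
        else:
            raise ValueError(
                f"unknown release_reference {self.release_reference!r}"
            )
        return ReleaseSchedule.periodic(
            ratio=ratio,
            reference_adults=reference,
            stage=cube.release_stage,
            genotype=cube.release_genotype,
            period=self.period,
            n_releases=self.n_releases,
            first_day=self.first_day,
        )

    def scaled(self, scale_factor: float) -> "ScenarioConfig":
        """Rescale the equilibrium population (release sizes follow the
        ratio convention automatically)."""
        if not 0 < scale_factor <= 1:
            raise ValueError("scale_factor must be in (0, 1]")
        lh = dict(self.life_history)
        base = lh.get("n_female_eq", load_defaults()["life_history"]["n_female_eq"])
        lh["n_female_eq"] = base * scale_factor
        return replace(self, life_history=lh)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "ScenarioConfig":
        return cls(**doc)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "ScenarioConfig":
        try:
            with open(path_or_text) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(path_or_text)
        return cls.from_dict(doc)
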