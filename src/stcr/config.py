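"""Declarative pipeline configuration with YAML loading and overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import yaml

from . import reference
from .basic_params import Conversions
from .prescription import Credits, FymSpec
from .synthetic_trial import GroundTruth, TrialDesign


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with reference defaults."""

    seed: int = 20230901
    n_strips: int = 3
    uptake_noise_cv: float = 0.05
    yield_noise_cv: float = 0.05
    stv_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(reference.STRIP_STV_MEANS)
    )
    stv_cvs_pct: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(reference.STRIP_STV_CVS_PCT)
    )
    nr: dict[str, float] = field(default_factory=lambda: dict(reference.BASIC_PARAMETERS.nr))
    cs_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.BASIC_PARAMETERS.cs_pct)
    )
    cf_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.BASIC_PARAMETERS.cf_pct)
    )
    cfym_pct: dict[str, float] = field(
        default_factory=lambda: dict(reference.BASIC_PARAMETERS.cfym_pct)
    )
    fym_moisture_fraction: float = 0.26
    fym_n_pct: float = 0.56
    fym_p_pct: float = 0.23
    fym_k_pct: float = 0.47
    fym_basis: str = "fresh"
    p_to_p2o5: float = 2.2914
    k_to_k2o: float = 1.2046
    floors: dict[str, float] = field(default_factory=lambda: dict(reference.DOSE_FLOORS))
    caps: dict[str, float] = field(default_factory=lambda: dict(reference.DOSE_CAPS))
    reckoner_target_q: float = reference.RECKONER_TARGET_Q
    reckoner_stv_grids: dict[str, list[float]] = field(
        default_factory=lambda: {j: list(g) for j, g in reference.RECKONER_STV_GRIDS.items()}
    )
    reckoner_fym_rates: tuple[float, ...] = (6.25, 12.5)
    #: optional explicit credits at the highest manure rate, overriding FymSpec
    reckoner_fym_credits: tuple[float, float, float] | None = None
    validation_targets_t_ha: tuple[float, ...] = (35.0, 40.0, 45.0)
    estimator_method: str = "mean_of_ratios"
    nr_method: str = "ratio"
    outdir: str = "stcr_out"
    verbosity: int = 1

    def conversions(self) -> Conversions:
        return Conversions(self.p_to_p2o5, self.k_to_k2o)

    def fym_spec(self) -> FymSpec:
        return FymSpec(
            self.fym_moisture_fraction,
            self.fym_n_pct,
            self.fym_p_pct,
            self.fym_k_pct,
            self.fym_basis,
        )

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            nr=dict(self.nr),
            cs_pct=dict(self.cs_pct),
            cf_pct=dict(self.cf_pct),
            cfym_pct=dict(self.cfym_pct),
            stv_means={j: tuple(v) for j, v in self.stv_means.items()},
            stv_cvs_pct={j: tuple(v) for j, v in self.stv_cvs_pct.items()},
            uptake_noise_cv=self.uptake_noise_cv,
            yield_noise_cv=self.yield_noise_cv,
            fym=self.fym_spec(),
            conversions=self.conversions(),
            seed=self.seed,
        )

    def design(self) -> TrialDesign:
        return TrialDesign(n_strips=self.n_strips)

    def reckoner_credit_options(self) -> list[tuple[str, Credits]]:
        rates = sorted(self.reckoner_fym_rates)
        top = max(rates)
        if self.reckoner_fym_credits is not None:
            full = Credits(*self.reckoner_fym_credits)
        else:
            full = self.fym_spec().credit(top)
        return [(f"fym_{r:g}", full.scaled(r / top)) for r in rates]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_FIELD_NAMES = {f.name for f in fields(PipelineConfig)}


def _coerce(value: str) -> Any:
    return yaml.safe_load(value)


def load_config(
    path: str | Path | None = None, overrides: Sequence[str] = ()
) -> PipelineConfig:
    """Build a config from an optional YAML file plus ``key=value`` overrides.

    Unknown keys are rejected by name.  Override values are parsed as YAML
    scalars (``--set seed=7``, ``--set 'floors={n: 50}'``).
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override must look like key=value, got {item!r}")
        key, value = item.split("=", 1)
        data[key.strip()] = _coerce(value)
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        return PipelineConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
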