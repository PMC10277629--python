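"""Declarative pipeline configuration with strict key checking."""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


def _from_mapping(cls, data: Mapping[str, Any]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the simulated cohort.

    Defaults are a desk-scale analog of the motivating design: 14 subjects
    sampled at baseline, three trimesters and three months postpartum, with a
    neutrophil-like type expanding during pregnancy and reverting after
    childbirth, and a twentieth of genes under planted regulation that also
    reverts postpartum.
    """

    n_subjects: int = 14
    timepoints: tuple[str, ...] = ("T0", "T1", "T2", "T3", "PP3")
    n_genes: int = 2000
    n_cell_types: int = 8
    markers_per_type: int = 25
    marker_fold: float = 50.0
    # Dirichlet concentrations: first type (neutrophils) ~10% at baseline on
    # average, with modest subject-to-subject spread
    baseline_alpha: tuple[float, ...] = (6.0, 14.0, 10.0, 8.0, 7.0, 6.0, 5.0, 4.0)
    shifted_type: str = "neutrophils"
    shift_schedule: tuple[tuple[str, float], ...] = (("T1", 0.6), ("T2", 0.85), ("T3", 1.0))
    regulated_fraction: float = 0.05
    regulation_effect: float = math.log(4.0)
    mixed_markers: int = 8
    tau: float = 0.3
    phi_min: float = 0.01
    phi_max: float = 0.5
    lib_size_mean: float = 2e6
    lib_size_cv: float = 0.2
    revert_postpartum: bool = True


@dataclasses.dataclass(frozen=True)
class ThresholdConfig:
    fdr: float = 0.05
    fc: float = 2.0
    cpm_numerator: float = 10.0
    min_samples: int = 8
    power_beta: float = 5.0
    merge_cut: float = 0.25
    max_p_outliers: float = 0.1
    min_module_size: int = 30
    cut_height: float = 0.995
    pc_fdr: float = 0.05
    pc_min_genes_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("fdr", "fc", "cpm_numerator", "power_beta", "merge_cut", "max_p_outliers"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    corstr: str = "independence"
    covariates: tuple[str, ...] = ("age",)
    coexpr_universe: str = "all"  # "all" analyzed genes or "significant" (adjusted screen)

    def __post_init__(self) -> None:
        if self.corstr not in ("independence", "exchangeable"):
            raise ConfigError(f"corstr must be independence or exchangeable, got {self.corstr}")
        if self.coexpr_universe not in ("all", "significant"):
            raise ConfigError("coexpr_universe must be 'all' or 'significant'")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = CohortConfig()
    thresholds: ThresholdConfig = ThresholdConfig()
    model: ModelConfig = ModelConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        tps = self.cohort.timepoints
        if not tps or tps[0] != "T0":
            raise ConfigError("timepoints must be ordered with T0 first")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - {"cohort", "thresholds", "model", "seed"}
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        cohort = _from_mapping(CohortConfig, _tuplify(data.get("cohort", {})))
        thresholds = _from_mapping(ThresholdConfig, data.get("thresholds", {}))
        model = _from_mapping(ModelConfig, _tuplify(data.get("model", {})))
        return cls(cohort=cohort, thresholds=thresholds, model=model, seed=int(data.get("seed", 0)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _tuplify(data: Mapping[str, Any]) -> dict[str, Any]:
    out = {}
    for k, v in data.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out
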