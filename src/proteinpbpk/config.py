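"""Run configuration, bundled parameter libraries and scenario plumbing.

Configurations are YAML (or JSON) documents validated by pydantic with
``extra="forbid"``: unknown keys and invalid values are reported
exhaustively with their locations.  Compounds and species are referenced
by name from the bundled libraries or defined inline.
"""

from __future__ import annotations

import importlib.resources as resources
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .assembly import (
    CompoundProperties,
    DoseEvent,
    TargetBindingParams,
    build_model,
    load_tumor_params,
)
from .fcrn import EndogenousIgGPool, EndosomalRates, FcRnBindingParams
from .constants import KD_NEUTRAL_DRUG
from .physiology import available_species, load_species
from .twopore import SoluteGeometry

__all__ = [
    "RunConfig",
    "load_config",
    "load_compound",
    "available_compounds",
    "load_fcrn_defaults",
    "available_scenarios",
    "load_scenario",
    "build_from_config",
]


def _read_packaged(name: str) -> dict:
    with resources.files("proteinpbpk.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


# --------------------------------------------------------------------------
# Bundled libraries


def load_fcrn_defaults() -> tuple[EndosomalRates, dict[str, EndogenousIgGPool], float]:
    """Global endosomal rates, per-species IgG pools, and k_ass."""
    raw = _read_packaged("fcrn.yaml")
    rates = EndosomalRates(
        k_up=raw["k_up"], k_rec=raw["k_rec"],
        f_vas_up=raw["f_vas_up"], f_vas_rec=raw["f_vas_rec"],
    )
    pools = {
        name: EndogenousIgGPool(
            C_igg_plasma=rec["igg_plasma_umol_l"],
            Kd_acidic=rec["kd_igg_acidic"],
            C_fcrn_free=rec["free_fcrn_umol_l"],
            Kd_neutral=raw["kd_igg_neutral"],
        )
        for name, rec in raw["species"].items()
    }
    return rates, pools, raw["k_ass"]


def _compound_from_record(name: str, rec: dict, k_ass: float) -> CompoundProperties:
    target = None
    if "target" in rec and rec["target"] is not None:
        t = rec["target"]
        target = TargetBindingParams(
            Kd=t["kd_umol_l"],
            k_on=t["k_on_l_umol_min"],
            turnover_half_life_h=t["turnover_half_life_h"],
            baseline=t["baseline_umol_l"],
            k_int=t["k_int_per_min"],
        )
    return CompoundProperties(
        name=name,
        molecular_weight=rec["molecular_weight_g_mol"],
        geometry=SoluteGeometry(a_e=rec["radius_nm"]),
        fcrn=FcRnBindingParams(
            k_ass=k_ass,
            Kd_acidic=rec["kd_fcrn_acidic_umol_l"],
            Kd_neutral=rec.get("kd_fcrn_neutral_umol_l", KD_NEUTRAL_DRUG),
        ),
        no_endosomal_uptake=rec.get("no_endosomal_uptake", False),
        f_GFR=rec.get("f_gfr"),
        target=target,
    )


def available_compounds() -> tuple[str, ...]:
    return tuple(_read_packaged("compounds.yaml"))


def load_compound(name: str) -> CompoundProperties:
    lib = _read_packaged("compounds.yaml")
    if name not in lib:
        raise KeyError(f"unknown compound {name!r}; available: {tuple(lib)}")
    _, _, k_ass = load_fcrn_defaults()
    return _compound_from_record(name, lib[name], k_ass)


# --------------------------------------------------------------------------
# Run configuration schema


class DoseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    time_min: float = Field(ge=0)
    mg_per_kg: float = Field(gt=0)
    duration_min: float = Field(default=0.0, ge=0)


class ObservationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tissue: str
    residual_blood_fraction: float = Field(default=0.0, ge=0, le=1)
    mode: str = "tissue"


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "BDF"
    rtol: float = Field(default=1e-9, gt=0)
    atol: float = Field(default=1e-13, gt=0)


class InlineCompoundConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    molecular_weight_g_mol: float = Field(gt=0)
    radius_nm: float = Field(gt=0)
    kd_fcrn_acidic_umol_l: float = Field(gt=0)
    kd_fcrn_neutral_umol_l: float = Field(default=KD_NEUTRAL_DRUG, gt=0)
    no_endosomal_uptake: bool = False
    f_gfr: float | None = Field(default=None, ge=0, le=1)


class RunConfig(BaseModel):
    """A complete simulation request (schema-validated)."""

    model_config = ConfigDict(extra="forbid")

    species: str
    compound: str | InlineCompoundConfig
    doses: list[DoseConfig] = Field(min_length=1)
    t_end_min: float = Field(gt=0)
    n_points: int = Field(default=400, ge=10)
    tumor: bool = False
    fcrn_knockout: bool = False
    explicit_neutral_binding: bool = False
    observations: list[ObservationConfig] = Field(default_factory=list)
    solver: SolverConfig = Field(default_factory=SolverConfig)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.species not in available_species():
            raise ValueError(f"unknown species {self.species!r}; available: {available_species()}")
        if isinstance(self.compound, str) and self.compound not in available_compounds():
            raise ValueError(
                f"unknown compound {self.compound!r}; available: {available_compounds()}"
            )
        if self.explicit_neutral_binding:
            raise ValueError(
                "explicit neutral-pH FcRn binding is not implemented; all bundled "
                "parameterizations use the no-binding sentinel Kd at neutral pH"
            )
        return self


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Schema violations are reported exhaustively (pydantic collects every
    error with its location), not first-failure.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise ValueError(f"invalid configuration {path.name}:\n{err}") from err


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)


# --------------------------------------------------------------------------
# Scenario library and execution


def available_scenarios() -> tuple[str, ...]:
    root = resources.files("proteinpbpk.data").joinpath("scenarios")
    return tuple(sorted(p.name.removesuffix(".yaml") for p in root.iterdir()
                        if p.name.endswith(".yaml")))


def load_scenario(name: str) -> RunConfig:
    root = resources.files("proteinpbpk.data").joinpath("scenarios")
    ref = root.joinpath(f"{name}.yaml")
    try:
        with ref.open() as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise KeyError(f"unknown scenario {name!r}; available: {available_scenarios()}")
    return RunConfig.model_validate(raw)


def build_from_config(cfg: RunConfig):
    """Materialize (model, doses, simulate kwargs) from a validated config."""
    species = load_species(cfg.species)
    if isinstance(cfg.compound, str):
        compound = load_compound(cfg.compound)
    else:
        c = cfg.compound
        compound = _compound_from_record(
            c.name,
            {
                "molecular_weight_g_mol": c.molecular_weight_g_mol,
                "radius_nm": c.radius_nm,
                "kd_fcrn_acidic_umol_l": c.kd_fcrn_acidic_umol_l,
                "kd_fcrn_neutral_umol_l": c.kd_fcrn_neutral_umol_l,
                "no_endosomal_uptake": c.no_endosomal_uptake,
                "f_gfr": c.f_gfr,
            },
            load_fcrn_defaults()[2],
        )
    tumor = load_tumor_params() if cfg.tumor else None
    if compound.target is not None and tumor is None:
        tumor = load_tumor_params()
    model = build_model(species, compound, tumor=tumor, fcrn_knockout=cfg.fcrn_knockout)
    doses = [
        DoseEvent(
            time=d.time_min,
            amount=compound.dose_umol(d.mg_per_kg, species.body_weight),
            duration=d.duration_min,
        )
        for d in cfg.doses
    ]
    sim_kwargs = dict(
        t_end=cfg.t_end_min,
        n_points=cfg.n_points,
        method=cfg.solver.method,
        rtol=cfg.solver.rtol,
        atol=cfg.solver.atol,
    )
    return model, doses, sim_kwargs
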