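"""Run configuration: schema validation, defaults, hashing, round-tripping."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from pydantic import ValidationError as PydanticValidationError

from . import __version__
from .aligner import TCMParams
from .dentition import ArchParams
from .errors import ValidationError
from .mechanics import AnchorageConfig, CouplingConstants, PDLConstants
from .remodeling import SimulationSettings
from .staging import DEFAULT_TOTALS, GROUP_NAMES


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DentitionSection(_Section):
    c2: float = Field(0.05, gt=0)
    c4: float = Field(1.5e-5, ge=0)
    interdental_gap: float = Field(0.5, ge=0)
    crest_height: float = Field(7.0, gt=0)
    jitter_sd: float = Field(0.0, ge=0)
    seed: int = 0

    def arch_params(self) -> ArchParams:
        return ArchParams(c2=self.c2, c4=self.c4,
                          interdental_gap=self.interdental_gap,
                          crest_height=self.crest_height)


class StagingSection(_Section):
    totals: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_TOTALS))
    posterior_step: float = Field(0.1, gt=0)
    incisor_step: float = Field(0.15, gt=0)
    overlap_fraction: float = Field(0.5, ge=0.0, le=1.0)

    @field_validator("totals")
    @classmethod
    def _known_groups(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(GROUP_NAMES)
        if unknown:
            raise ValueError(f"unknown staging groups: {sorted(unknown)}")
        merged = dict(DEFAULT_TOTALS)
        merged.update(v)
        if any(val < 0 for val in merged.values()):
            raise ValueError("staging totals must be non-negative")
        return merged


class PDLSection(_Section):
    e1: float = Field(0.05, gt=0)
    e2: float = Field(0.22, gt=0)
    strain_break: float = Field(0.075, gt=0, lt=1)
    pdl_thickness: float = Field(0.85, gt=0)
    sample_count: int = Field(160, ge=8)
    confinement_factor: float = Field(20.0, gt=0)

    def constants(self) -> PDLConstants:
        return PDLConstants(**self.model_dump())


class CouplingSection(_Section):
    k_interface: float = Field(CouplingConstants.k_interface, gt=0)
    k_interface_rot: float = Field(CouplingConstants.k_interface_rot, gt=0)
    k_chain: float = Field(CouplingConstants.k_chain, gt=0)
    k_chain_rot: float = Field(CouplingConstants.k_chain_rot, gt=0)
    attachment_rot_multiplier: float = Field(
        CouplingConstants.attachment_rot_multiplier, gt=0)
    attachment_teeth: list[int] = Field(
        default_factory=lambda: list(CouplingConstants.attachment_teeth))
    programming_memory: float = Field(CouplingConstants.programming_memory,
                                      ge=0.0, le=1.0)

    def constants(self) -> CouplingConstants:
        d = self.model_dump()
        d["attachment_teeth"] = tuple(d["attachment_teeth"])
        return CouplingConstants(**d)


class TCMSection(_Section):
    k: float = Field(0.025, gt=0)
    lambda_: float = Field(1.0, gt=0, alias="lambda")
    half_width: float = Field(1.0, gt=0)
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    def params(self) -> TCMParams:
        return TCMParams(k=self.k, lambda_=self.lambda_, half_width=self.half_width)


class AnchorageSection(_Section):
    group: str = "control"
    force_gf: float = Field(150.0, ge=0)
    elastic_angle_deg: float = Field(15.0, ge=0, le=90)
    tad_lateral_offset: float = Field(4.0, gt=0)
    tad_height_above_crest: float = Field(4.0, ge=0)
    cut_lateral_offset: float = Field(3.0, ge=0)
    cut_mesial_fraction: float = Field(0.25, ge=0, le=1)

    @field_validator("group")
    @classmethod
    def _known_group(cls, v: str) -> str:
        if v not in AnchorageConfig.GROUPS:
            raise ValueError(f"group must be one of {AnchorageConfig.GROUPS}")
        return v

    def config(self) -> AnchorageConfig:
        return AnchorageConfig(**self.model_dump())


class DiagnosticsSection(_Section):
    third_iteration: bool = True
    refit_curve_each_step: bool = True
    iterations_per_step: int = Field(2, ge=1)

    def settings(self) -> SimulationSettings:
        return SimulationSettings(
            iterations_per_step=self.iterations_per_step,
            third_iteration_diagnostic=self.third_iteration,
            refit_curve_each_step=self.refit_curve_each_step)


class RunConfig(_Section):
    """Fully materialized run configuration (all defaults filled)."""

    dentition: DentitionSection = Field(default_factory=DentitionSection)
    staging: StagingSection = Field(default_factory=StagingSection)
    pdl: PDLSection = Field(default_factory=PDLSection)
    coupling: CouplingSection = Field(default_factory=CouplingSection)
    tcm: TCMSection = Field(default_factory=TCMSection)
    anchorage: AnchorageSection = Field(default_factory=AnchorageSection)
    diagnostics: DiagnosticsSection = Field(default_factory=DiagnosticsSection)
    output_dir: str = "runs"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(by_alias=True), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def dump(self, path) -> None:
        doc = self.model_dump(by_alias=True)
        doc["_meta"] = {"package_version": __version__,
                        "config_hash": self.config_hash()}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing keys get defaults.

    An empty or absent file yields the all-defaults configuration (control
    group, 70-step plan). Unknown keys, type mismatches and out-of-range
    values raise :class:`ValidationError` naming the offending key.
    """
    doc: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config root must be a mapping, got {type(loaded).__name__}")
        loaded.pop("_meta", None)
        doc = loaded
    if overrides:
        for dotted, value in overrides.items():
            parts = dotted.split(".")
            node = doc
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = value
    try:
        return RunConfig.model_validate(doc)
    except PydanticValidationError as exc:
        names = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ValidationError(f"invalid configuration ({names}): {exc}") from exc
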