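"""Run configuration schema and validation.

YAML configurations are validated against a strict pydantic schema (unknown
keys are rejected) before any stage executes; `validate_config` produces a
full report without running anything.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticError

from .errors import ValidationError
from .io import read_yaml
from .simulate import DEFAULT_REFERENCE_PEPTIDE, PRESETS


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KineticBlock(_Strict):
    """Either a named preset or explicit rate constants."""

    preset: Optional[str] = None
    synthesis_rate: Optional[float] = Field(default=None, ge=0)
    k_mat: Optional[float] = Field(default=None, ge=0)
    k_deg_b: Optional[float] = Field(default=None, ge=0)
    k_deg_c: Optional[float] = Field(default=None, ge=0)
    pulse_duration: Optional[float] = Field(default=None, gt=0)

    def resolve(self):
        from .model import KineticParams

        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValidationError(
                    f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}"
                )
            return PRESETS[self.preset]
        fields = ["synthesis_rate", "k_mat", "k_deg_b", "k_deg_c"]
        missing = [f for f in fields if getattr(self, f) is None]
        if missing:
            raise ValidationError(f"kinetic block missing: {missing} (or use preset)")
        return KineticParams(
            synthesis_rate=self.synthesis_rate,
            k_mat=self.k_mat,
            k_deg_b=self.k_deg_b,
            k_deg_c=self.k_deg_c,
            pulse_duration=self.pulse_duration or 0.5,
        )


class PulseChaseBlock(_Strict):
    treatments: dict[str, KineticBlock | str] = Field(
        default_factory=lambda: {"WT": "WT", "F508del": "F508del"}
    )
    timepoints: list[float] = [0.0, 1.0, 2.5, 4.0, 6.0]
    replicates: int = Field(default=3, ge=1)
    noise_cv: float = Field(default=0.10, ge=0)
    scheme: Literal["heavy_pulse", "heavy_chase"] = "heavy_pulse"
    include_qc: bool = False
    qc_bleed: float = Field(default=0.05, ge=0, le=1)

    def design(self):
        from .simulate import PulseChaseDesign

        treatments = {}
        for name, blk in self.treatments.items():
            if isinstance(blk, str):
                blk = KineticBlock(preset=blk)
            treatments[name] = blk.resolve()
        return PulseChaseDesign(
            treatments=treatments,
            timepoints=tuple(self.timepoints),
            n_replicates=self.replicates,
            scheme=self.scheme,
        )


class FootprintBlock(_Strict):
    n_peptides: int = Field(default=80, ge=2)
    n_experiments: int = Field(default=4, ge=1)
    n_technical: int = Field(default=2, ge=1)
    noise_cv: float = Field(default=0.10, ge=0)
    depletion: dict[str, float] = Field(default_factory=dict)
    probe: str = "IDOR-6A"
    alpha: float = Field(default=0.05, gt=0, lt=1)

    def design(self):
        from .simulate import FootprintDesign, _default_universe

        return FootprintDesign(
            peptides=_default_universe(self.n_peptides),
            n_experiments=self.n_experiments,
            n_technical=self.n_technical,
            depletion=self.depletion,
            probe=self.probe,
            noise_cv=self.noise_cv,
        )


class PlateBlock(_Strict):
    n_wells: int = Field(default=384, ge=8)
    n_controls: int = Field(default=16, ge=2)
    pos_mean: float = 100.0
    pos_sd: float = Field(default=5.0, ge=0)
    neg_mean: float = 0.0
    neg_sd: float = Field(default=2.0, ge=0)
    cutoff: float = 13.0
    n_screened: Optional[int] = Field(default=None, ge=1)


class QuantBlock(_Strict):
    reference_peptide: str = DEFAULT_REFERENCE_PEPTIDE
    wt_treatment: str = "WT"
    anchor_time: float = 0.0
    efficiency_time: float = 2.5
    floor_fraction: float = Field(default=0.05, ge=0, lt=1)


class RunConfig(_Strict):
    """Top-level configuration of a `foldtrace run` pipeline."""

    seed: int = 0
    stages: list[Literal["pulse_chase", "footprint", "screen"]] = [
        "pulse_chase",
        "footprint",
        "screen",
    ]
    pulse_chase: PulseChaseBlock = Field(default_factory=PulseChaseBlock)
    footprint: FootprintBlock = Field(default_factory=FootprintBlock)
    plate: PlateBlock = Field(default_factory=PlateBlock)
    quant: QuantBlock = Field(default_factory=QuantBlock)


def load_config(path) -> RunConfig:
    raw = read_yaml(path)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except PydanticError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValidationError(f"invalid configuration: {msgs}") from exc


def validate_config(path) -> list[str]:
    """Full schema report (empty list = valid); never raises on bad content."""
    try:
        raw = read_yaml(path)
    except OSError as exc:
        raise  # unreadable file is an I/O error, not a validation report
    except Exception as exc:
        return [f"unparseable YAML: {exc}"]
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        return ["top level must be a mapping"]
    try:
        cfg = RunConfig.model_validate(raw)
    except PydanticError as exc:
        return [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
    try:
        cfg.pulse_chase.design()
        cfg.footprint.design()
    except ValidationError as exc:
        return [str(exc)]
    return []
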