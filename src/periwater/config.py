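"""Structured run configuration: one nested, fully serializable document.

A run is reproducible from the configuration plus its seeds alone; unknown
keys are rejected so typos fail loudly before any compute.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import phantom as ph


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Strict):
    grid_shape: tuple[int, int, int] = (31, 31, 31)
    voxel_size_mm: float = 2.0
    lesion_center: tuple[int, int, int] = (7, 15, 15)
    lesion_radii_mm: tuple[float, float, float] = (5.0, 6.0, 6.0)
    wm_margin_mm: float = 2.0
    ventricle_offset_mm: float = 6.0
    ventricle_radii_mm: tuple[float, float, float] = (4.0, 8.0, 6.0)
    baseline_fw: float = 0.15
    baseline_fat: float = 0.55
    baseline_md: float = 0.7e-3

    def to_spec(self, seed: int = 0) -> ph.PhantomSpec:
        return ph.PhantomSpec(seed=seed, **self.model_dump())


class EffectBlock(_Strict):
    fw_lesion_delta: float = ph.FW_LESION_DELTA
    fat_lesion_delta: float = ph.FAT_LESION_DELTA
    fw_multipliers: tuple[float, float, float, float] = ph.FW_MULTIPLIERS
    fat_multipliers: tuple[float, float, float, float] = ph.FAT_MULTIPLIERS
    fw_decay: tuple[float, float, float, float] = ph.FW_DECAY
    fat_decay: tuple[float, float, float, float] = ph.FAT_DECAY

    def to_effect(self) -> ph.EffectProfile:
        return ph.EffectProfile(**self.model_dump())


class CohortBlock(_Strict):
    # pipeline default: a desk-scale cohort; the full study layout
    # (27 subjects, 26/21/19/19 retention) is the CohortDesign default
    n_subjects: int = 8
    missingness: tuple[int, ...] = (8, 7, 6, 6)
    between_subject_sd: dict[str, float] = Field(
        default_factory=lambda: {"fw": 0.15, "fat": 0.03}
    )
    within_subject_sd: dict[str, float] = Field(
        default_factory=lambda: {"fw": 0.30, "fat": 0.06}
    )
    shrink_fraction: float = 0.72

    def to_design(self, effect: ph.EffectProfile, seed: int = 0,
                  baseline_fw: float = 0.15, baseline_fat: float = 0.55) -> ph.CohortDesign:
        return ph.CohortDesign(
            n_subjects=self.n_subjects,
            missingness=tuple(self.missingness),
            effect=effect,
            between_subject_sd=self.between_subject_sd,
            within_subject_sd=self.within_subject_sd,
            shrink_fraction=self.shrink_fraction,
            baseline_fw=baseline_fw,
            baseline_fat=baseline_fat,
            seed=seed,
        )


class AcquisitionBlock(_Strict):
    n_directions: int = 64
    b_value: float = 1500.0
    n_b0: int = 1
    s0: float = 1000.0
    snr: float | None = 30.0


class FitBlock(_Strict):
    d_w: float = 3.0e-3
    epsilon: float = 0.01
    lambda_reg: float = 0.0
    outer_iterations: int = 4
    tol: float = 1e-6
    ftol: float = 1e-10
    max_iter: int = 200
    md_tissue_ref: float = 0.6e-3
    init_mode: str = "profile"
    md_anchor: float = 0.7e-3
    md_anchor_weight: float = 0.5


class ShellsBlock(_Strict):
    n_shells: int = 8
    wm_erode_iterations: int = 2


class StatsBlock(_Strict):
    alpha: float = 0.05
    omnibus: str = "wald"
    cross_sectional: bool = False


class IngestBlock(_Strict):
    dwi: str
    bvals: str
    bvecs: str
    lesion_mask: str
    wm_mask: str
    ventricle_mask: str
    subject_table: str


class RunConfig(_Strict):
    """Top-level pipeline configuration (one block per stage)."""

    seed: int = 0
    out_dir: str = "periwater_run"
    mode: str = "simulate"  # or "ingest"
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    effect: EffectBlock = Field(default_factory=EffectBlock)
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    acquisition: AcquisitionBlock = Field(default_factory=AcquisitionBlock)
    fit: FitBlock = Field(default_factory=FitBlock)
    shells: ShellsBlock = Field(default_factory=ShellsBlock)
    stats: StatsBlock = Field(default_factory=StatsBlock)
    ingest: IngestBlock | None = None

    @model_validator(mode="after")
    def _check_mode(self) -> "RunConfig":
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if self.mode == "ingest" and self.ingest is None:
            raise ValueError("ingest mode requires an 'ingest' block with input paths")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
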