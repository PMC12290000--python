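"""Structured run configuration: one YAML file drives every subcommand.

Unknown keys are rejected so typos fail loudly, and a config round-trips
through serialization unchanged.  One global seed fans out deterministically
to per-stage seeds (fixed offsets) so stages can be rerun in isolation.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .nets import ClassifierConfig, SegmenterConfig, TrainConfig, TverskyParams
from .phantom import PhantomSpec, RaterModel
from .pipeline import PipelineConfig, PostprocessParams
from .preprocess import AugmentParams, RemapParams

# fixed per-stage seed offsets derived from the global seed
SEED_OFFSETS = {
    "phantom": 0,
    "augment": 101,
    "classifier": 211,
    "segmenter": 307,
    "evaluate": 401,
}


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IOSection(_Section):
    out_dir: str = "runs"


class RemapSection(_Section):
    o1: float = 0.22
    o2: float = 0.30


class AugmentSection(_Section):
    max_shift: float = 25.0
    max_rot: float = 25.0
    factor: int = 5


class ClassifierSection(_Section):
    stage_features: tuple[int, int] = (8, 16)
    dropout_p: float = 0.2
    weight_decay: float = 1e-4
    input_size: int = 512


class SegmenterSection(_Section):
    level_features: tuple[int, int, int, int] = (16, 32, 64, 128)
    attention_gates: bool = True


class TverskySection(_Section):
    alpha: float = 0.8
    beta: float = 0.2
    gamma: float = 1.33
    smooth: float = 1e-6


class TrainSection(_Section):
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 10
    val_fraction: float = 0.25


class PostprocessSection(_Section):
    closing_radius: int = 1
    connectivity: int = 26
    min_component_cc: float = 0.5
    max_components: int = 2
    closing_2d: bool = False


class PipelineSection(_Section):
    enable_preprocess: bool = True
    enable_classifier: bool = True
    enable_postprocess: bool = True
    gate_threshold: float = 0.5
    prob_threshold: float = 0.5
    work_size: int = 512
    work_spacing: float = 5.0
    normalize: bool = True
    classifier_checkpoint: str | None = None
    segmenter_checkpoint: str | None = None


class AgreementSection(_Section):
    structures: list[str] = ["uterus", "ovary"]
    roi_dilation: int | None = None


class PhantomSection(_Section):
    grid_shape: tuple[int, int, int] = (96, 96, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    n_ovaries: int = 2
    ovary_radii: tuple[float, float] = (9.0, 14.0)
    ovary_intensity: tuple[float, float] = (0.22, 0.30)
    uterus_radii: tuple[float, float] = (24.0, 38.0)
    uterus_intensity: tuple[float, float] = (0.35, 0.45)
    n_bright_structures: int = 2
    bright_radii: tuple[float, float] = (8.0, 16.0)
    bright_intensity: tuple[float, float] = (0.6, 0.95)
    background_intensity: float = 0.1
    noise_sd: float = 0.02
    rater_jitter_sd: list[float] = [0.0, 1.0, 2.0]
    rater_bias: list[int] = [0, 0, 0]


class RunConfig(_Section):
    """Top-level configuration; see the per-section models for fields."""

    seed: int = 0
    log_level: str = "INFO"
    io: IOSection = IOSection()
    remap: RemapSection = RemapSection()
    augment: AugmentSection = AugmentSection()
    classifier: ClassifierSection = ClassifierSection()
    segmenter: SegmenterSection = SegmenterSection()
    tversky: TverskySection = TverskySection()
    train: TrainSection = TrainSection()
    pipeline: PipelineSection = PipelineSection()
    postprocess: PostprocessSection = PostprocessSection()
    agreement: AgreementSection = AgreementSection()
    phantom: PhantomSection = PhantomSection()

    # -- serialization ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    # -- adapters to the dataclass knobs the modules take ----------------

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2**31 - 1)

    def remap_params(self) -> RemapParams:
        return RemapParams(o1=self.remap.o1, o2=self.remap.o2)

    def augment_params(self) -> AugmentParams:
        return AugmentParams(max_shift=self.augment.max_shift,
                             max_rot=self.augment.max_rot,
                             factor=self.augment.factor,
                             seed=self.stage_seed("augment"))

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(**self.classifier.model_dump())

    def segmenter_config(self) -> SegmenterConfig:
        return SegmenterConfig(**self.segmenter.model_dump())

    def tversky_params(self) -> TverskyParams:
        return TverskyParams(**self.tversky.model_dump())

    def train_config(self, stage: str) -> TrainConfig:
        return TrainConfig(seed=self.stage_seed(stage), **self.train.model_dump())

    def postprocess_params(self) -> PostprocessParams:
        return PostprocessParams(**self.postprocess.model_dump())

    def pipeline_config(self) -> PipelineConfig:
        d = self.pipeline.model_dump()
        return PipelineConfig(remap=self.remap_params(),
                              postprocess=self.postprocess_params(), **d)

    def phantom_spec(self, seed: int | None = None) -> PhantomSpec:
        d = self.phantom.model_dump()
        d.pop("rater_jitter_sd")
        d.pop("rater_bias")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return PhantomSpec(seed=self.stage_seed("phantom") if seed is None else seed, **d)

    def rater_models(self) -> list[RaterModel]:
        return [
            RaterModel(rater_id=f"r{i + 1}", jitter_sd=j, bias=b)
            for i, (j, b) in enumerate(zip(self.phantom.rater_jitter_sd,
                                           self.phantom.rater_bias))
        ]
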