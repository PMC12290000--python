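"""Gated inference and morphological postprocessing for whole volumes.

Inference cascade: normalize -> (optional) ovary-enhancing remap -> resample
every axial slice to the working grid -> gate each slice through the presence
classifier -> run the attention U-Net only on slices that pass the gate ->
restack to the native grid -> (optional) closing + connected-component
filtering.  Each stage has an on/off switch so component contributions can be
ablated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AlignmentError, ConfigurationError
from .nets import (
    AttUSeg,
    ResClass,
    classifier_logits,
    load_checkpoint,
    segmenter_probs,
)
from .preprocess import RemapParams, remap_intensity
from .volume_io import (
    LabelMap,
    Volume3D,
    normalize_volume,
    resample_slice_stack,
    restack_to_volume,
)
from .agreement import dsc

__all__ = [
    "PostprocessParams",
    "PipelineConfig",
    "segment_volume",
    "postprocess_mask",
    "evaluate_pipeline",
    "run_ablation",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class PostprocessParams:
    """Closing + connected-component false-positive suppression.

    ``closing_radius = 1`` uses a 3x3x3 (26-neighbourhood) structuring
    element.  Components smaller than ``min_component_cc`` are dropped and at
    most ``max_components`` largest are kept (two, for the two ovaries).
    """

    closing_radius: int = 1
    connectivity: int = 26
    min_component_cc: float = 0.5
    max_components: int = 2
    closing_2d: bool = False  # per-slice closing instead of across slices

    def __post_init__(self) -> None:
        if self.closing_radius < 0:
            raise ConfigurationError("closing_radius must be >= 0")
        if self.max_components < 1:
            raise ConfigurationError("max_components must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ConfigurationError("connectivity must be one of 6, 18, 26")


@dataclass
class PipelineConfig:
    enable_preprocess: bool = True
    enable_classifier: bool = True
    enable_postprocess: bool = True
    gate_threshold: float = 0.5
    prob_threshold: float = 0.5
    work_size: int = 512
    work_spacing: float = 5.0
    normalize: bool = True
    remap: RemapParams = field(default_factory=RemapParams)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    classifier_checkpoint: str | None = None
    segmenter_checkpoint: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gate_threshold < 1.0):
            raise ConfigurationError("gate_threshold must be in (0, 1)")


def _load_models(cfg: PipelineConfig, classifier, segmenter):
    if segmenter is None:
        if cfg.segmenter_checkpoint is None:
            raise ConfigurationError("no segmenter model or checkpoint provided")
        segmenter = load_checkpoint(cfg.segmenter_checkpoint)
    if classifier is None and cfg.enable_classifier:
        if cfg.classifier_checkpoint is None:
            raise ConfigurationError("no classifier model or checkpoint provided")
        classifier = load_checkpoint(cfg.classifier_checkpoint)
    return classifier, segmenter


def segment_volume(
    v: Volume3D,
    cfg: PipelineConfig,
    classifier: ResClass | None = None,
    segmenter: AttUSeg | None = None,
) -> LabelMap:
    """Run the full gated cascade on one volume; returns a native-grid mask.

    Models may be passed directly or loaded from the checkpoints in ``cfg``.
    With the classifier enabled, a slice whose gate probability falls below
    ``gate_threshold`` yields an empty slice mask; positive voxels therefore
    only ever appear on slices the classifier passed.
    """
    classifier, segmenter = _load_models(cfg, classifier, segmenter)

    work = normalize_volume(v) if cfg.normalize else v
    if cfg.enable_preprocess:
        work = remap_intensity(work, cfg.remap)
    stack = resample_slice_stack(work, out_size=cfg.work_size,
                                 out_spacing=cfg.work_spacing, is_mask=False)
    slices = stack.slices.astype(np.float32)

    if cfg.enable_classifier:
        logits = classifier_logits(classifier, slices)
        gate_prob = 1.0 / (1.0 + np.exp(-logits))
        passed = gate_prob >= cfg.gate_threshold
    else:
        passed = np.ones(len(slices), dtype=bool)

    masks = np.zeros_like(slices, dtype=np.float64)
    if passed.any():
        probs = segmenter_probs(segmenter, slices[passed])
        masks[passed] = (probs >= cfg.prob_threshold).astype(np.float64)

    native = restack_to_volume(replace(stack, slices=masks), v, is_mask=True)
    out = LabelMap(mask=native, spacing=v.spacing, structure="ovary",
                   rater_id="auto", subject_id=v.subject_id)
    if cfg.enable_postprocess:
        out = postprocess_mask(out, cfg.postprocess)
    return out


def postprocess_mask(
    m: LabelMap,
    p: PostprocessParams = PostprocessParams(),
    spacing: tuple[float, float, float] | None = None,
) -> LabelMap:
    """Morphological closing then connected-component false-positive removal.

    Closing runs in 3D by default (across slices); components are labelled at
    ``p.connectivity``, those below ``p.min_component_cc`` are removed, and of
    the remainder at most ``p.max_components`` largest are kept.  The
    operation is idempotent.
    """
    sp = m.spacing if spacing is None else tuple(float(s) for s in spacing)
    mask = m.mask.astype(bool)

    if p.closing_radius > 0 and mask.any():
        r = p.closing_radius
        if p.closing_2d:
            selem = np.ones((2 * r + 1, 2 * r + 1, 1), dtype=bool)
        else:
            selem = np.ones((2 * r + 1,) * 3, dtype=bool)
        # pad so closing near the border behaves like in an unbounded grid
        padded = np.pad(mask, r, mode="constant")
        padded = ndimage.binary_closing(padded, structure=selem)
        mask = padded[r:-r, r:-r, r:-r]

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[p.connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    if n:
        voxel_cc = sp[0] * sp[1] * sp[2] / 1000.0
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.where(sizes * voxel_cc >= p.min_component_cc)[0]
        if len(keep) > p.max_components:
            keep = keep[np.argsort(sizes[keep])[::-1][: p.max_components]]
        mask = np.isin(labels, keep + 1)

    return LabelMap(mask=mask, spacing=m.spacing, structure=m.structure,
                    rater_id=m.rater_id, subject_id=m.subject_id)


def prepare_slice_dataset(
    cohort: dict[str, dict],
    cfg: PipelineConfig,
    structure: str = "ovary",
    rater: str = "truth",
) -> tuple[list, list]:
    """Turn a cohort into 2D training pairs on the working grid.

    Returns ``(classifier_pairs, segmenter_pairs)``: every slice with its
    presence label for the classifier, and only target-bearing slices with
    their masks for the segmenter.  The same normalize/remap/resample chain
    as inference is applied.
    """
    clf_pairs, seg_pairs = [], []
    for _subject, entry in sorted(cohort.items()):
        v = entry["volume"]
        lm = entry["masks"][structure][rater]
        work = normalize_volume(v) if cfg.normalize else v
        if cfg.enable_preprocess:
            work = remap_intensity(work, cfg.remap)
        img_stack = resample_slice_stack(work, out_size=cfg.work_size,
                                         out_spacing=cfg.work_spacing, is_mask=False)
        msk_stack = resample_slice_stack(lm, out_size=cfg.work_size,
                                         out_spacing=cfg.work_spacing, is_mask=True)
        for img, msk in zip(img_stack.slices, msk_stack.slices):
            label = int(msk.sum() > 0)
            clf_pairs.append((img, label))
            if label:
                seg_pairs.append((img, msk))
    return clf_pairs, seg_pairs


def evaluate_pipeline(predictions, references) -> pd.DataFrame:
    """Per-subject 3D DSC between predictions and references, plus the mean.

    Accepts two aligned dicts (subject -> LabelMap) or two aligned sequences.
    Returns a table with one row per subject and a final "mean" row.
    """
    if isinstance(predictions, dict) != isinstance(references, dict):
        raise AlignmentError("predictions and references must be both dicts or both sequences")
    if isinstance(predictions, dict):
        keys = sorted(predictions)
        if sorted(references) != keys:
            raise AlignmentError("prediction and reference subjects differ")
        items = [(k, predictions[k], references[k]) for k in keys]
    else:
        if len(predictions) != len(references):
            raise AlignmentError("prediction and reference counts differ")
        items = [(str(i), p, r) for i, (p, r) in enumerate(zip(predictions, references))]

    rows = [{"subject": k, "dsc": dsc(p, r)} for k, p, r in items]
    mean = float(np.mean([r["dsc"] for r in rows])) if rows else float("nan")
    rows.append({"subject": "mean", "dsc": mean})
    return pd.DataFrame(rows)


def run_ablation(
    dataset: list[tuple[Volume3D, LabelMap]],
    configs: dict[str, PipelineConfig],
    classifier: ResClass | None = None,
    segmenter: AttUSeg | None = None,
) -> pd.DataFrame:
    """Evaluate several pipeline configurations on the same test set.

    ``dataset`` pairs each volume with its reference mask.  Returns one row
    per configuration with its mean 3D DSC, in the given order.
    """
    rows = []
    for name, cfg in configs.items():
        preds = [segment_volume(v, cfg, classifier=classifier, segmenter=segmenter)
                 for v, _ in dataset]
        table = evaluate_pipeline(preds, [ref for _, ref in dataset])
        mean = float(table.loc[table["subject"] == "mean", "dsc"].iloc[0])
        rows.append({"configuration": name, "mean_dsc": mean})
    return pd.DataFrame(rows)
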