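"""Scaled-down study runs used by the test suite and the acceptance script.

These helpers fix the synthetic study conditions the package is validated
under: phantom cohorts at 64 x 64 x 16 voxels (3 x 3 x 5 mm spacing) for the
segmentation cascade, and the default 96 x 96 x 24 grid for the multi-rater
agreement analyses.  Training budgets are sized so a full cascade train +
evaluation completes in minutes on one CPU; the classifier is trained to
convergence in every run because the ablation comparisons isolate its
contribution.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .agreement import alpha_from_mask_stacks
from .nets import (
    ClassifierConfig,
    SegmenterConfig,
    TrainConfig,
    train_classifier,
    train_segmenter,
)
from .phantom import PhantomSpec, RaterModel, generate_phantom, simulate_rater
from .pipeline import (
    PipelineConfig,
    evaluate_pipeline,
    prepare_slice_dataset,
    run_ablation,
    segment_volume,
)

CASCADE_SPEC = dict(grid_shape=(64, 64, 16), spacing=(3.0, 3.0, 5.0))

# working grid matches the phantom in-plane grid; phantom volumes are already
# normalized so the percentile step is skipped
CASCADE_PIPELINE = PipelineConfig(work_size=64, work_spacing=3.0, normalize=False)


def phantom_cohort(n: int, seed: int, **spec_overrides) -> dict[str, dict]:
    """In-memory cohort of phantoms in the load_cohort layout."""
    out: dict[str, dict] = {}
    for i in range(n):
        spec = PhantomSpec(
            **{**CASCADE_SPEC, **spec_overrides, "seed": (seed * 100003 + i * 1009) % (2**31 - 1)}
        )
        v, masks = generate_phantom(spec)
        v.subject_id = f"s{i:03d}"
        for m in masks.values():
            m.subject_id = v.subject_id
        out[v.subject_id] = {
            "volume": v,
            "masks": {name: {"truth": lm} for name, lm in masks.items()},
        }
    return out


def train_cascade(
    cohort: dict[str, dict],
    seed: int,
    clf_epochs: int = 12,
    seg_epochs: int = 10,
):
    """Train both cascade components on a cohort; returns (classifier, segmenter)."""
    clf_pairs, seg_pairs = prepare_slice_dataset(cohort, CASCADE_PIPELINE)
    clf, _ = train_classifier(
        clf_pairs,
        TrainConfig(epochs=clf_epochs, patience=clf_epochs, seed=seed),
        ClassifierConfig(input_size=CASCADE_PIPELINE.work_size),
    )
    seg, _ = train_segmenter(
        seg_pairs,
        TrainConfig(epochs=seg_epochs, patience=seg_epochs, seed=seed + 1),
        SegmenterConfig(),
    )
    return clf, seg


def evaluate_cascade(cohort, cfg, classifier, segmenter) -> float:
    """Mean held-out 3D DSC of a pipeline configuration on a cohort."""
    preds, refs = {}, {}
    for sid, entry in cohort.items():
        preds[sid] = segment_volume(entry["volume"], cfg, classifier=classifier,
                                    segmenter=segmenter)
        refs[sid] = entry["masks"]["ovary"]["truth"]
    table = evaluate_pipeline(preds, refs)
    return float(table.loc[table["subject"] == "mean", "dsc"].iloc[0])


def end_to_end_run(seed: int, n_train: int = 30, n_test: int = 10,
                   clf_epochs: int = 12, seg_epochs: int = 10):
    """Full scaled-down study: train the cascade, return models + cohorts."""
    train = phantom_cohort(n_train, seed=seed * 7 + 1)
    test = phantom_cohort(n_test, seed=seed * 7 + 2)
    clf, seg = train_cascade(train, seed=seed, clf_epochs=clf_epochs,
                             seg_epochs=seg_epochs)
    return clf, seg, test


def ablation_table(test_cohort, classifier, segmenter):
    """Mean DSC for the three pipeline configurations of the component study."""
    base = CASCADE_PIPELINE
    configs = {
        "full": base,
        "no-postprocess": replace(base, enable_postprocess=False),
        "no-classifier": replace(base, enable_classifier=False),
    }
    dataset = [(e["volume"], e["masks"]["ovary"]["truth"])
               for e in test_cohort.values()]
    return run_ablation(dataset, configs, classifier=classifier, segmenter=segmenter)


def simulated_panel_alpha(
    jitter_mm: float,
    seed: int,
    n_subjects: int = 7,
    n_raters: int = 3,
    n_replicates: int = 20,
    structure: str = "ovary",
) -> list[float]:
    """Pooled Krippendorff's alpha of a simulated rater panel, per replicate.

    Subjects use the default phantom grid; each replicate redraws the raters'
    boundary jitter with fresh seeds derived from ``seed``.
    """
    subjects = [generate_phantom(PhantomSpec(seed=(seed * 13 + i) % (2**31 - 1)))[1][structure]
                for i in range(n_subjects)]
    alphas = []
    for rep in range(n_replicates):
        stacks = []
        for i, gt in enumerate(subjects):
            masks = []
            for r in range(n_raters):
                rm = RaterModel(
                    rater_id=f"r{r}",
                    jitter_sd=jitter_mm,
                    seed=(seed + 9973 * rep + 131 * i + r) % (2**31 - 1),
                )
                masks.append(simulate_rater(gt, rm).mask)
            stacks.append(np.stack(masks))
        alphas.append(alpha_from_mask_stacks(stacks))
    return alphas
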