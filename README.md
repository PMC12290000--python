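# ovaseg

Automatic ovary segmentation for 3D pelvic MRI in endometriosis, plus the
multi-rater agreement statistics used to judge it.

Segmenting the ovaries on pelvic MRI of endometriosis patients is hard even
for experts: the ovary is small, mobile and often deformed, and independent
raters disagree far more on the ovary than on the uterus. `ovaseg` provides:

* a **gated segmentation cascade** for T2 fat-suppressed volumes —
  percentile normalization, an ovary-enhancing piecewise intensity remap
  (the band [0.22, 0.30) is saturated to 1, bright voxels are inverted to
  `1 − I₀`), a slice-presence classifier (truncated ResNet18, 8/16
  features), a four-level 2D attention U-Net (16/32/64/128 features) trained
  with the focal Tversky loss (α = 0.8, β = 0.2, γ = 1.33), and
  morphological postprocessing (3D closing + connected-component filtering);
* **inter-rater agreement analysis** on binary voxel masks — pairwise Dice
  (DSC), voxel-level nominal Krippendorff's α with native missing-rater
  handling, pairwise Gwet's AC2, and volume summaries;
* a **synthetic pelvic phantom generator** (ellipsoidal organs with the
  right normalized-intensity structure, plus simulated raters with
  band-limited boundary jitter) so the whole pipeline is testable end to end
  with no imaging data;
* a CLI (`ovaseg`) wiring it all together: `phantom`, `train-classifier`,
  `train-segmenter`, `segment`, `evaluate`, `ablate`, `agreement`.

The networks run on a small NumPy reverse-mode autodiff engine included in
the package (`ovaseg.nn`); everything is single-threaded, deterministic and
CPU-only. See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a 3-rater synthetic cohort, run the agreement analysis, and read
the per-structure summary:

```python
import numpy as np
from ovaseg.phantom import PhantomSpec, RaterModel, generate_phantom, simulate_rater
from ovaseg.agreement import RaterSet, build_report

raters = [RaterModel("r1", jitter_sd=1.0),
          RaterModel("r2", jitter_sd=1.0, bias=1),
          RaterModel("r3", jitter_sd=2.0)]
rs = RaterSet()
for i in range(7):
    _, masks = generate_phantom(PhantomSpec(seed=13 + i))
    for structure in ("uterus", "ovary"):
        gt = masks[structure]; gt.subject_id = f"s{i:03d}"
        for j, m in enumerate(raters):
            rm = RaterModel(m.rater_id, m.jitter_sd, m.bias, seed=653 * i + j)
            rs.add(simulate_rater(gt, rm))

report = build_report(rs, ["uterus", "ovary"])
for s, d in report.per_structure.items():
    print(f"{s:7s} DSC {d['dsc_mean']:.2f}±{d['dsc_sd']:.2f}  "
          f"α {d['krippendorff_alpha']:.2f}  "
          f"AC2median {d['ac2_median']:.2f}  "
          f"vol {d['volume_cc_mean']:.1f}cc")
```

Output:

```
uterus  DSC 0.89±0.03  α 0.88  AC2median 0.99  vol 145.4cc
ovary   DSC 0.73±0.05  α 0.72  AC2median 1.00  vol 16.9cc
```

The same boundary jitter costs the small ovary far more agreement than the
large uterus — pairwise DSC drops from 0.89 to 0.73 and pooled α from 0.88
to 0.72 — reproducing the small-structure penalty that motivates automating
ovary segmentation. (AC2 stays near 1 here because whole-volume background
dominates its percent-agreement term; α corrects for that chance agreement.)

The same analysis from the shell:

```sh
ovaseg phantom --n-subjects 7 --seed 3 --out-dir runs/demo
ovaseg agreement --manifest runs/demo/cohort/manifest.csv \
                 --structures uterus,ovary --out-dir runs/demo
cat runs/demo/agreement/report.csv
```

Training and running the cascade on a phantom cohort:

```sh
ovaseg train-classifier --manifest runs/demo/cohort/manifest.csv --out-dir runs/models
ovaseg train-segmenter  --manifest runs/demo/cohort/manifest.csv --out-dir runs/models
ovaseg segment --input runs/demo/cohort/subj000/t2fs.nii.gz \
               --output runs/demo/subj000_ovary.nii.gz --config cfg.yaml
```

where `cfg.yaml` points `pipeline.classifier_checkpoint` /
`pipeline.segmenter_checkpoint` at the trained models.

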