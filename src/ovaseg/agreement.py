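"""Segmentation-quality and inter-rater reliability statistics.

Implements the voxel-level agreement analysis used to characterise manual
pelvic-organ contours from multiple raters: pairwise Dice similarity (DSC)
and its three-rater average, Krippendorff's alpha at nominal level over the
pooled binary voxel ratings, pairwise Gwet's AC2, and volume summaries.

Krippendorff's alpha uses the standard coincidence-matrix estimator with
native missing-data handling: a voxel (unit) rated by m >= 2 raters
contributes each ordered pair of its ratings with weight 1/(m-1); units with
fewer than two ratings are excluded.  alpha = 1 - D_o / D_e where D_o is the
observed and D_e the expected (marginal-based) nominal disagreement.

Gwet's AC2 corrects percent agreement with Gwet's chance model
p_e = (T_w / (Q (Q-1))) * sum_q pi_q (1 - pi_q), where pi_q averages the two
raters' marginal proportions; with identity weights on binary data (T_w = Q)
it coincides with AC1.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DegenerateInputError
from .volume_io import LabelMap, volume_cc

__all__ = [
    "dsc",
    "dsc_avg",
    "krippendorff_alpha_nominal",
    "gwet_ac2",
    "RaterSet",
    "AgreementReport",
    "build_report",
]


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def _as_bool(m) -> np.ndarray:
    a = m.mask if isinstance(m, LabelMap) else np.asarray(m)
    return a.astype(bool)


def dsc(a, b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) between two binary masks.

    Both masks empty returns 1.0 by convention; exactly one empty returns 0.0.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise AlignmentError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def dsc_avg(d12: float, d13: float, d23: float) -> float:
    """Average of the three pairwise DSCs of a three-rater panel."""
    return (d12 + d13 + d23) / 3.0


# ---------------------------------------------------------------------------
# Krippendorff's alpha (nominal)
# ---------------------------------------------------------------------------

def krippendorff_alpha_nominal(ratings: np.ndarray) -> float:
    """Nominal-level Krippendorff's alpha for a units x raters matrix.

    ``ratings`` holds small non-negative integer category codes with ``np.nan``
    (float array) or negative values (int array) marking missing ratings.
    Units with fewer than two ratings are excluded.
    """
    r = np.asarray(ratings)
    if r.ndim != 2:
        raise AlignmentError("ratings must be a 2D units x raters array")
    if np.issubdtype(r.dtype, np.floating):
        present = ~np.isnan(r)
        codes = np.where(present, np.nan_to_num(r), 0).astype(np.int64)
    else:
        present = r >= 0
        codes = np.where(present, r, 0).astype(np.int64)
    if codes.size and codes.min() < 0:
        raise DegenerateInputError("category codes must be non-negative")
    n_cat = int(codes.max()) + 1 if codes.size else 0

    # per-unit category counts
    m_u = present.sum(axis=1)
    keep = m_u >= 2
    if not np.any(keep):
        raise DegenerateInputError("no unit has >= 2 ratings")
    counts = np.zeros((int(keep.sum()), n_cat), dtype=np.float64)
    kept_codes = codes[keep]
    kept_present = present[keep]
    for q in range(n_cat):
        counts[:, q] = ((kept_codes == q) & kept_present).sum(axis=1)
    return _alpha_from_counts(counts)


def _alpha_from_counts(counts: np.ndarray) -> float:
    """Alpha from per-unit category counts (units x categories), all m_u >= 2."""
    m_u = counts.sum(axis=1)
    if np.any(m_u < 2):
        raise DegenerateInputError("every unit must carry >= 2 ratings")
    w = 1.0 / (m_u - 1.0)
    n_total = float(m_u.sum())
    # pairable disagreements within units: for nominal data the number of
    # disagreeing ordered pairs in unit u is m_u^2 - sum_q n_uq^2
    disagree = (m_u**2 - (counts**2).sum(axis=1)) * w
    d_o = disagree.sum() / n_total
    n_q = counts.sum(axis=0)
    d_e = (n_total**2 - (n_q**2).sum()) / (n_total * (n_total - 1.0))
    if d_e == 0.0:
        raise DegenerateInputError(
            "expected disagreement is zero (all ratings fall in one category); alpha undefined"
        )
    return 1.0 - d_o / d_e


def alpha_from_mask_stacks(stacks: list[np.ndarray]) -> float:
    """Pooled binary alpha over voxel units from per-subject mask stacks.

    Each element of ``stacks`` is an (n_raters, ...) boolean/0-1 array of the
    masks all raters produced for one subject (n_raters may differ between
    subjects).  Every voxel of every subject is a unit; counts are accumulated
    without materialising the voxel x rater matrix.
    """
    ones_list, m_list = [], []
    for s in stacks:
        s = np.asarray(s)
        m = s.shape[0]
        if m < 2:
            continue  # single-rater subjects carry no pairable information
        ones = s.reshape(m, -1).astype(np.int64).sum(axis=0)
        ones_list.append(ones)
        m_list.append(np.full(ones.shape, m, dtype=np.int64))
    if not ones_list:
        raise DegenerateInputError("no subject has >= 2 raters")
    n1 = np.concatenate(ones_list).astype(np.float64)
    m = np.concatenate(m_list).astype(np.float64)
    counts = np.stack([m - n1, n1], axis=1)
    return _alpha_from_counts(counts)


# ---------------------------------------------------------------------------
# Gwet's AC2
# ---------------------------------------------------------------------------

def gwet_ac2(a, b, weights: np.ndarray | str = "identity") -> float:
    """Pairwise Gwet's AC2 between two binary masks (or flat rating vectors).

    With the default identity weights on binary data this is Gwet's AC1:
    p_a the raw proportion of agreeing voxels and
    p_e = 2 * pi * (1 - pi) with pi the mean of the two raters' positive
    marginal proportions.  A general Q x Q weight matrix may be supplied.
    """
    x, y = _as_bool(a).ravel(), _as_bool(b).ravel()
    if x.shape != y.shape:
        raise AlignmentError("rating vectors must be the same length")
    n = x.size
    if n == 0:
        raise DegenerateInputError("empty rating vectors")
    q = 2
    if isinstance(weights, str):
        if weights != "identity":
            raise ValueError(f"unknown weight scheme {weights!r}")
        w = np.eye(q)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (q, q):
            raise AlignmentError("weight matrix must be 2x2 for binary masks")

    # contingency counts over categories {0, 1}
    tab = np.zeros((q, q))
    tab[1, 1] = np.logical_and(x, y).sum()
    tab[1, 0] = np.logical_and(x, ~y).sum()
    tab[0, 1] = np.logical_and(~x, y).sum()
    tab[0, 0] = n - tab[1, 1] - tab[1, 0] - tab[0, 1]
    p = tab / n

    p_a = float((w * p).sum())
    pi = (p.sum(axis=1) + p.sum(axis=0)) / 2.0  # mean marginal per category
    t_w = float(w.sum())
    p_e = t_w / (q * (q - 1)) * float((pi * (1.0 - pi)).sum())
    if p_e >= 1.0:
        raise DegenerateInputError("chance agreement is 1; AC undefined")
    return (p_a - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class RaterSet:
    """Mapping subject -> structure -> rater_id -> LabelMap on a common grid."""

    masks: dict[str, dict[str, dict[str, LabelMap]]] = field(default_factory=dict)

    def add(self, lm: LabelMap) -> None:
        subj = self.masks.setdefault(lm.subject_id, {})
        subj.setdefault(lm.structure, {})[lm.rater_id] = lm

    def subjects(self) -> list[str]:
        return sorted(self.masks)

    def structures(self) -> list[str]:
        seen: set[str] = set()
        for subj in self.masks.values():
            seen.update(subj)
        return sorted(seen)

    @classmethod
    def from_cohort(cls, cohort: dict[str, dict]) -> "RaterSet":
        rs = cls()
        for subject, entry in cohort.items():
            for structure, raters in entry.get("masks", {}).items():
                for rater, lm in raters.items():
                    lm.subject_id = lm.subject_id or subject
                    lm.structure = lm.structure or structure
                    lm.rater_id = lm.rater_id or rater
                    rs.add(lm)
        return rs


@dataclass
class AgreementReport:
    """Per-structure agreement summary plus the long-form pairwise tables."""

    per_structure: dict[str, dict]
    pairwise_dsc: pd.DataFrame
    pairwise_ac2: pd.DataFrame
    volumes: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for structure, d in sorted(self.per_structure.items()):
            rows.append({"structure": structure, **d})
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "report.csv", index=False)
        self.pairwise_dsc.to_csv(out / "pairwise_dsc.csv", index=False)
        self.pairwise_ac2.to_csv(out / "pairwise_ac2.csv", index=False)
        self.volumes.to_csv(out / "volumes.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.per_structure, fh, indent=2, sort_keys=True, default=float)


def build_report(
    rs: RaterSet,
    structures: list[str] | None = None,
    roi_dilation: int | None = None,
) -> AgreementReport:
    """Compute the full agreement report for the requested structures.

    Per structure: all pairwise DSCs across subjects (mean +- sd), the
    three-rater DSC average where three raters exist, pooled Krippendorff's
    alpha over every voxel of every multi-rater subject, Gwet's AC2 per rater
    pair pooled over subjects (min / median / max), and per-rater volumes in
    cc (mean +- sd).  Single-rater subjects contribute volumes only.

    By default every voxel of the common grid is a unit (background included).
    ``roi_dilation`` instead restricts the voxel pool for alpha and AC2 to the
    union of all raters' masks dilated by that many voxels, for sensitivity
    analyses where whole-volume background would dominate.
    """
    structures = structures or rs.structures()
    per_structure: dict[str, dict] = {}
    dsc_rows, ac2_rows, vol_rows = [], [], []

    for structure in structures:
        stacks = []
        dscs = []
        dsc_avgs = []
        pair_ratings: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
        n_multi = 0

        found = False
        for subject in rs.subjects():
            raters = rs.masks.get(subject, {}).get(structure)
            if not raters:
                continue
            found = True
            rater_ids = sorted(raters)
            for rid in rater_ids:
                vol_rows.append(
                    {
                        "structure": structure,
                        "subject": subject,
                        "rater": rid,
                        "volume_cc": volume_cc(raters[rid]),
                    }
                )
            if len(rater_ids) < 2:
                continue
            n_multi += 1
            stack = np.stack([raters[r].mask for r in rater_ids])
            if roi_dilation is not None:
                from scipy import ndimage as _ndi

                roi = stack.any(axis=0)
                if roi_dilation > 0:
                    roi = _ndi.binary_dilation(roi, iterations=roi_dilation)
                flat_roi = roi.ravel()
                stacks.append(stack.reshape(stack.shape[0], -1)[:, flat_roi])
            else:
                flat_roi = None
                stacks.append(stack)
            subj_dscs = {}
            for r1, r2 in itertools.combinations(rater_ids, 2):
                d = dsc(raters[r1], raters[r2])
                subj_dscs[(r1, r2)] = d
                dscs.append(d)
                dsc_rows.append(
                    {
                        "structure": structure,
                        "subject": subject,
                        "rater_1": r1,
                        "rater_2": r2,
                        "dsc": d,
                    }
                )
                x = raters[r1].mask.ravel()
                y = raters[r2].mask.ravel()
                if flat_roi is not None:
                    x, y = x[flat_roi], y[flat_roi]
                pair_ratings.setdefault((r1, r2), []).append((x, y))
            if len(rater_ids) == 3:
                dsc_avgs.append(dsc_avg(*subj_dscs.values()))

        if not found:
            import warnings

            warnings.warn(f"structure {structure!r} absent from all subjects; skipped")
            continue

        summary: dict = {"n_subjects_multirater": n_multi}
        if dscs:
            summary["dsc_mean"] = float(np.mean(dscs))
            summary["dsc_sd"] = float(np.std(dscs, ddof=1)) if len(dscs) > 1 else 0.0
        if dsc_avgs:
            summary["dsc_avg_mean"] = float(np.mean(dsc_avgs))
        if stacks:
            summary["krippendorff_alpha"] = alpha_from_mask_stacks(stacks)
            ac2_vals = []
            for (r1, r2), pairs in sorted(pair_ratings.items()):
                x = np.concatenate([p[0] for p in pairs])
                y = np.concatenate([p[1] for p in pairs])
                ac = gwet_ac2(x, y)
                ac2_vals.append(ac)
                ac2_rows.append(
                    {"structure": structure, "rater_1": r1, "rater_2": r2, "ac2": ac}
                )
            summary["ac2_min"] = float(np.min(ac2_vals))
            summary["ac2_median"] = float(np.median(ac2_vals))
            summary["ac2_max"] = float(np.max(ac2_vals))
        vols = [r["volume_cc"] for r in vol_rows if r["structure"] == structure]
        summary["volume_cc_mean"] = float(np.mean(vols))
        summary["volume_cc_sd"] = float(np.std(vols, ddof=1)) if len(vols) > 1 else 0.0
        per_structure[structure] = summary

    return AgreementReport(
        per_structure=per_structure,
        pairwise_dsc=pd.DataFrame(dsc_rows, columns=["structure", "subject", "rater_1", "rater_2", "dsc"]),
        pairwise_ac2=pd.DataFrame(ac2_rows, columns=["structure", "rater_1", "rater_2", "ac2"]),
        volumes=pd.DataFrame(vol_rows, columns=["structure", "subject", "rater", "volume_cc"]),
    )
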