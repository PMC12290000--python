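"""Agreement statistics against independent oracles and hand computations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ovaseg.agreement import (
    RaterSet,
    alpha_from_mask_stacks,
    build_report,
    dsc,
    dsc_avg,
    gwet_ac2,
    krippendorff_alpha_nominal,
)
from ovaseg.errors import AlignmentError, DegenerateInputError
from ovaseg.volume_io import LabelMap


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def alpha_bruteforce(ratings: np.ndarray) -> float:
    """Krippendorff's alpha by direct enumeration of all pairable pairs."""
    pooled = []
    d_o_num = 0.0
    n_pairable = 0
    for row in ratings:
        vals = row[~np.isnan(row)]
        m = len(vals)
        if m < 2:
            continue
        n_pairable += m
        pooled.extend(vals)
        for i in range(m):
            for j in range(m):
                if i != j:
                    d_o_num += float(vals[i] != vals[j]) / (m - 1)
    d_o = d_o_num / n_pairable
    pooled = np.array(pooled)
    diff = pooled[:, None] != pooled[None, :]
    n = len(pooled)
    d_e = diff.sum() / (n * (n - 1))
    return 1.0 - d_o / d_e


def dsc_bruteforce(a, b):
    inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
    return 2 * inter / (a.sum() + b.sum())


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------

class TestDsc:
    def test_identical_nonempty_masks(self, rng):
        m = rng.random((6, 6, 3)) > 0.5
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, 0, 0] = True
        b[1, 1, 0] = True
        assert dsc(a, b) == 0.0

    def test_counting_example(self):
        # |a| = 4, |b| = 6, |a ∩ b| = 3 -> 2*3/10
        a = np.zeros(16, bool)
        b = np.zeros(16, bool)
        a[:4] = True
        b[1:7] = True
        assert dsc(a.reshape(4, 4, 1), b.reshape(4, 4, 1)) == pytest.approx(0.6)

    def test_empty_conventions(self):
        e = np.zeros((3, 3, 1), bool)
        f = np.ones((3, 3, 1), bool)
        assert dsc(e, e) == 1.0
        assert dsc(e, f) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(bool, (4, 4, 2), elements=st.booleans()),
        arrays(bool, (4, 4, 2), elements=st.booleans()),
    )
    def test_symmetric_and_matches_direct_counting(self, a, b):
        assert dsc(a, b) == dsc(b, a)
        if a.sum() + b.sum() > 0:
            assert dsc(a, b) == pytest.approx(dsc_bruteforce(a, b))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            dsc(np.zeros((2, 2, 1), bool), np.zeros((3, 3, 1), bool))

    @pytest.mark.parametrize(
        "triple,expected", [((1, 1, 1), 1.0), ((0.6, 0.3, 0.9), 0.6), ((0, 0, 0), 0.0)]
    )
    def test_three_rater_average(self, triple, expected):
        assert dsc_avg(*triple) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------

class TestKrippendorffAlpha:
    def test_perfect_agreement_is_one(self):
        r = np.tile(np.array([0.0, 1, 1, 0, 1])[:, None], (1, 3))
        assert krippendorff_alpha_nominal(r) == pytest.approx(1.0)

    def test_two_rater_four_voxel_case_matches_bruteforce(self):
        r = np.array([[1, 1], [1, 0], [0, 0], [0, 0]], dtype=float)
        assert krippendorff_alpha_nominal(r) == pytest.approx(
            alpha_bruteforce(r), abs=1e-12
        )

    def test_random_problems_match_bruteforce(self, rng):
        for _ in range(100):
            n_units = int(rng.integers(4, 51))
            n_raters = int(rng.integers(2, 5))
            r = rng.integers(0, 2, size=(n_units, n_raters)).astype(float)
            # missing ratings, keeping at least one unit with >= 2 ratings
            miss = rng.random(r.shape) < 0.2
            r[miss] = np.nan
            ok = (~np.isnan(r)).sum(axis=1) >= 2
            retained = r[ok][~np.isnan(r[ok])]
            if not ok.any() or len(np.unique(retained)) < 2:
                continue
            assert krippendorff_alpha_nominal(r) == pytest.approx(
                alpha_bruteforce(r), abs=1e-12
            )

    def test_independent_raters_give_alpha_near_zero(self, rng):
        r = rng.integers(0, 2, size=(100_000, 2)).astype(float)
        assert abs(krippendorff_alpha_nominal(r)) < 0.02

    def test_mask_stack_pooling_equals_matrix_form(self, rng):
        stacks = [rng.integers(0, 2, size=(3, 4, 4, 2)), rng.integers(0, 2, size=(2, 4, 4, 2))]
        # equivalent units x raters matrix with missing third rater for subject 2
        m1 = stacks[0].reshape(3, -1).T.astype(float)
        m2 = np.concatenate([stacks[1].reshape(2, -1).T.astype(float),
                             np.full((32, 1), np.nan)], axis=1)
        expected = krippendorff_alpha_nominal(np.concatenate([m1, m2]))
        assert alpha_from_mask_stacks(stacks) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            krippendorff_alpha_nominal(np.array([[1.0, np.nan], [0.0, np.nan]]))
        with pytest.raises(DegenerateInputError):
            krippendorff_alpha_nominal(np.ones((5, 3)))  # single category


# ---------------------------------------------------------------------------
# Gwet's AC2
# ---------------------------------------------------------------------------

class TestGwetAC2:
    def test_identical_masks_with_both_categories(self, rng):
        m = rng.random((5, 5, 2)) > 0.5
        assert gwet_ac2(m, m) == pytest.approx(1.0)

    def test_hand_computed_contingency_case(self):
        # voxel counts: both-positive 40, only-a 5, only-b 10, both-negative 45
        a = np.array([1] * 45 + [0] * 55, bool)
        b = np.array([1] * 40 + [0] * 5 + [1] * 10 + [0] * 45, bool)
        # p_a = 0.85; pi = 0.475; p_e = 2*pi*(1-pi) = 0.49875
        expected = (0.85 - 0.49875) / (1 - 0.49875)
        assert gwet_ac2(a, b) == pytest.approx(expected)
        assert gwet_ac2(a, b) == pytest.approx(0.7007, abs=5e-5)

    def test_complete_disagreement_negative(self):
        a = np.array([1, 1, 0, 0], bool)
        assert gwet_ac2(a, ~a) < 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(bool, 30, elements=st.booleans()),
        arrays(bool, 30, elements=st.booleans()),
    )
    def test_rater_swap_and_category_relabel_invariance(self, a, b):
        pi = (a.mean() + b.mean()) / 2
        if pi in (0.0, 1.0) and (a == b).all():
            return  # chance agreement 1: undefined
        assert gwet_ac2(a, b) == pytest.approx(gwet_ac2(b, a), abs=1e-12)
        assert gwet_ac2(a, b) == pytest.approx(gwet_ac2(~a, ~b), abs=1e-12)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def _rater_set(rng, n_subjects=3, raters=("r1", "r2", "r3"), identical=False):
    rs = RaterSet()
    for s in range(n_subjects):
        base = rng.random((8, 8, 4)) > 0.6
        for r in raters:
            m = base if identical else base ^ (rng.random(base.shape) > 0.9)
            rs.add(LabelMap(m, spacing=(2, 2, 4), structure="ovary",
                            rater_id=r, subject_id=f"s{s}"))
    return rs


class TestBuildReport:
    def test_perfect_agreement_panel(self, rng):
        rs = _rater_set(rng, identical=True)
        rep = build_report(rs, ["ovary"])
        s = rep.per_structure["ovary"]
        assert s["dsc_mean"] == 1.0
        assert s["krippendorff_alpha"] == pytest.approx(1.0)
        assert s["ac2_min"] == pytest.approx(1.0)

    def test_single_rater_subjects_contribute_volumes_only(self, rng):
        rs = _rater_set(rng, n_subjects=2)
        rs.add(LabelMap(rng.random((8, 8, 4)) > 0.5, spacing=(2, 2, 4),
                        structure="ovary", rater_id="r1", subject_id="s_lone"))
        rep = build_report(rs, ["ovary"])
        assert rep.per_structure["ovary"]["n_subjects_multirater"] == 2
        assert set(rep.volumes["subject"]) == {"s0", "s1", "s_lone"}
        assert "s_lone" not in set(rep.pairwise_dsc["subject"])

    def test_report_regeneration_is_byte_identical(self, rng, tmp_path):
        rs = _rater_set(rng)
        build_report(rs, ["ovary"]).write(tmp_path / "a")
        build_report(rs, ["ovary"]).write(tmp_path / "b")
        for name in ["report.csv", "pairwise_dsc.csv", "pairwise_ac2.csv", "report.json"]:
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_absent_structure_warns_and_skips(self, rng):
        rs = _rater_set(rng)
        with pytest.warns(UserWarning):
            rep = build_report(rs, ["uterus"])
        assert "uterus" not in rep.per_structure

    def test_pairwise_dsc_table_covers_all_pairs(self, rng):
        rs = _rater_set(rng)
        rep = build_report(rs, ["ovary"])
        assert len(rep.pairwise_dsc) == 3 * len(list(itertools.combinations("abc", 2)))
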