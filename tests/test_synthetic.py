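import numpy as np
import pytest
from scipy import ndimage

from segqa.mask_model import Compartment, extract_compartment
from segqa.overlap_metrics import dice, missing_fraction
from segqa.synthetic import (
    DegradationSpec,
    PhantomSpec,
    TargetUnattainableError,
    degrade,
    make_cohort,
    make_reference_case,
    nested_regions,
    simulate_rater_pair,
)


class TestReferencePhantoms:
    def test_deterministic_given_seed(self):
        spec = PhantomSpec(seed=42)
        a = make_reference_case(spec)
        b = make_reference_case(spec)
        assert np.array_equal(a.voxels, b.voxels)

    def test_single_focus_volumes_ordered(self):
        m = make_reference_case(PhantomSpec(n_foci=1, seed=3))
        counts = [(m.voxels == lab).sum() for lab in (1, 2, 3)]
        assert counts[0] < counts[1] < counts[2]
        struct = np.ones((3, 3, 3))
        _, n = ndimage.label(m.voxels > 0, structure=struct)
        assert n == 1

    @pytest.mark.parametrize("n_foci", [2, 3])
    def test_multifocal_component_count(self, n_foci):
        m = make_reference_case(
            PhantomSpec(
                grid_shape=(48, 48, 48),
                n_foci=n_foci,
                radii=((1.6, 2.2), (2.8, 3.6), (4.2, 5.6)),
                seed=7,
            )
        )
        _, n = ndimage.label(m.voxels > 0, structure=np.ones((3, 3, 3)))
        assert n == n_foci

    @pytest.mark.parametrize("seed", [0, 5, 9])
    def test_nesting_invariant(self, seed):
        """Solid compartment regions satisfy ET <= ADC <= FLAIR per focus."""
        spec = PhantomSpec(n_foci=1, seed=seed)
        for et, adc, flair in nested_regions(spec):
            assert not np.any(et & ~adc)
            assert not np.any(adc & ~flair)

    def test_cavity_carves_core(self):
        solid = make_reference_case(PhantomSpec(seed=11, cavity=False))
        hollow = make_reference_case(PhantomSpec(seed=11, cavity=True))
        assert (hollow.voxels > 0).sum() < (solid.voxels > 0).sum()
        # rim survives: some enhancing voxels remain
        assert (hollow.voxels == 1).sum() > 0

    def test_infeasible_geometry_errors(self):
        with pytest.raises(ValueError):
            make_reference_case(
                PhantomSpec(grid_shape=(12, 12, 12), n_foci=3, seed=0)
            )


@pytest.fixture(scope="module")
def reference():
    return make_reference_case(PhantomSpec(seed=4))


class TestDegrade:
    def test_zero_target_returns_reference(self, reference):
        cand = degrade(reference, DegradationSpec("erode", missing_fraction=0.0))
        assert np.array_equal(cand.voxels, reference.voxels)

    def test_erode_hits_missing_target(self, reference):
        spec = DegradationSpec("erode", missing_fraction=0.30, seed=1)
        cand = degrade(reference, spec)
        achieved = missing_fraction(reference.voxels > 0, cand.voxels > 0)
        assert 0.28 <= achieved <= 0.32
        # candidate is a subset: nothing falsely included
        assert not np.any((cand.voxels > 0) & (reference.voxels == 0))

    def test_erode_hits_dice_target(self, reference):
        cand = degrade(reference, DegradationSpec("erode", wt_dice=0.75, seed=2))
        d = dice(reference.voxels > 0, cand.voxels > 0)
        assert abs(d - 0.75) <= 0.02

    def test_dilate_hits_dice_target(self, reference):
        cand = degrade(reference, DegradationSpec("dilate", wt_dice=0.8, seed=3))
        d = dice(reference.voxels > 0, cand.voxels > 0)
        assert abs(d - 0.8) <= 0.02
        # dilation only adds: nothing missing
        assert missing_fraction(reference.voxels > 0, cand.voxels > 0) == 0.0

    def test_translate_hits_dice_target(self, reference):
        cand = degrade(reference, DegradationSpec("translate", wt_dice=0.6, seed=5))
        d = dice(reference.voxels > 0, cand.voxels > 0)
        assert abs(d - 0.6) <= 0.02

    def test_drop_focus_missing_matches_volume_share(self):
        ref = make_reference_case(
            PhantomSpec(
                grid_shape=(48, 48, 48),
                n_foci=3,
                radii=((1.6, 2.2), (2.8, 3.6), (4.2, 5.6)),
                seed=8,
            )
        )
        labels, _ = ndimage.label(ref.voxels > 0)
        sizes = ndimage.sum_labels(ref.voxels > 0, labels, index=[1, 2, 3])
        cand = degrade(ref, DegradationSpec("drop_focus"))
        achieved = missing_fraction(ref.voxels > 0, cand.voxels > 0)
        assert achieved == pytest.approx(sizes.min() / sizes.sum())

    def test_drop_focus_on_unifocal_errors(self, reference):
        with pytest.raises(TargetUnattainableError):
            degrade(reference, DegradationSpec("drop_focus"))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            DegradationSpec("erode")  # no target
        with pytest.raises(ValueError):
            DegradationSpec("dilate", missing_fraction=0.3)
        with pytest.raises(ValueError):
            DegradationSpec("shear", wt_dice=0.5)

    @pytest.mark.parametrize(
        "mode,kwargs",
        [
            ("erode", {"missing_fraction": 0.15}),
            ("erode", {"missing_fraction": 0.5}),
            ("erode", {"wt_dice": 0.85}),
            ("erode", {"wt_dice": 0.55}),
            ("dilate", {"wt_dice": 0.9}),
            ("dilate", {"wt_dice": 0.7}),
        ],
    )
    def test_achieved_within_tolerance_sweep(self, reference, mode, kwargs):
        spec = DegradationSpec(mode, seed=6, **kwargs)
        cand = degrade(reference, spec)
        ref_wt, cand_wt = reference.voxels > 0, cand.voxels > 0
        if spec.wt_dice is not None:
            assert abs(dice(ref_wt, cand_wt) - spec.wt_dice) <= spec.tolerance
        else:
            assert (
                abs(missing_fraction(ref_wt, cand_wt) - spec.missing_fraction)
                <= spec.tolerance
            )


class TestCohort:
    def test_subgroup_counts_match_composition(self):
        cases = make_cohort(97, seed=0)
        focal = [c.focality for c in cases]
        status = [c.status for c in cases]
        assert focal.count("unifocal") == 74
        assert focal.count("multifocal") == 23
        assert status.count("newly_diagnosed") == 16
        assert status.count("recurrent") == 81

    def test_perfect_profile_all_score_5(self):
        from segqa.pipeline import evaluate_cases

        cases = make_cohort(
            8,
            quality_profile={"newly_diagnosed": 1.0, "recurrent": 1.0},
            seed=2,
        )
        _, scores = evaluate_cases(cases)
        assert (scores["score"] == 5).all()
        assert (scores["wt_dice"] == 1.0).all()

    def test_cohort_deterministic(self):
        a = make_cohort(6, seed=9)
        b = make_cohort(6, seed=9)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.candidate.voxels, cb.candidate.voxels)


def test_simulate_rater_pair_stays_on_scale():
    scores = [1, 2, 3, 4, 5] * 6
    mat = simulate_rater_pair(scores, seed=3)
    assert mat.shape == (30, 2)
    assert mat.min() >= 1 and mat.max() <= 5
    assert np.array_equal(mat[:, 0], scores)
    assert np.abs(mat[:, 1] - mat[:, 0]).max() <= 1
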