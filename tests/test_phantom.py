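"""Phantom generation, enhancement measurement and the rule-based labeler."""

import numpy as np
import pytest

from ctphase import (
    Examination,
    make_edge_case,
    make_phantom_exam,
    measure_enhancement,
    rule_label,
)
from ctphase.phantom import (
    LabelThresholds,
    STRUCTURES,
    baseline_volume,
    build_masks,
    simulate_dataset,
)
from ctphase.volumes import PhaseVolume


def _geometry(spec, seed):
    masks = build_masks(spec, seed)
    return masks, baseline_volume(spec, masks)


class TestGeneration:
    def test_three_phase_exam_has_requested_labels(self, spec32, profile):
        exam = make_phantom_exam(spec32, profile, {"LAP", "PVP", "DP"}, rng_seed=7)
        assert [p.true_phase for p in exam.phases] == ["LAP", "PVP", "DP"]
        assert all(p.shape == spec32.shape for p in exam.phases)

    def test_single_phase_exam(self, spec32, profile):
        exam = make_phantom_exam(spec32, profile, {"PVP"}, rng_seed=1)
        assert len(exam.phases) == 1 and exam.phases[0].true_phase == "PVP"

    def test_determinism_voxel_identical(self, spec32, profile):
        a = make_phantom_exam(spec32, profile, {"EAP", "PVP"}, rng_seed=42)
        b = make_phantom_exam(spec32, profile, {"EAP", "PVP"}, rng_seed=42)
        for pa, pb in zip(a.phases, b.phases):
            np.testing.assert_array_equal(pa.values, pb.values)

    def test_rejects_both_arterial_subphases(self, spec32, profile):
        with pytest.raises(ValueError, match="arterial"):
            make_phantom_exam(spec32, profile, {"EAP", "LAP"}, rng_seed=0)

    def test_rejects_empty_label_set(self, spec32, profile):
        with pytest.raises(ValueError):
            make_phantom_exam(spec32, profile, set(), rng_seed=0)

    def test_masks_mutually_exclusive_and_nonempty(self, spec32):
        masks = build_masks(spec32, 3)
        total = np.zeros(spec32.shape, dtype=int)
        for m in masks.values():
            total += m.voxels
        assert total.max() == 1  # every voxel belongs to exactly one mask
        for name in STRUCTURES:
            assert masks[name].voxels.any()


class TestMeasurement:
    def test_identity_gives_zero_deltas(self, spec32):
        masks, base = _geometry(spec32, 0)
        deltas = measure_enhancement(base, base, masks)
        assert all(v == 0.0 for v in deltas.values())

    def test_constructed_delta_recovered_exactly(self, spec32):
        masks, base = _geometry(spec32, 0)
        vals = base.values.copy()
        vals[masks["portal_vein"].voxels] += 100.0
        vol = PhaseVolume(vals, spec32.spacing, "t")
        deltas = measure_enhancement(vol, base, masks)
        assert deltas["portal_vein"] == pytest.approx(100.0)
        for s in ("artery", "hepatic_vein", "parenchyma"):
            assert deltas[s] == pytest.approx(0.0)

    def test_shape_mismatch_rejected(self, spec32):
        masks, base = _geometry(spec32, 0)
        small = PhaseVolume(np.zeros((16, 16, 16)), spec32.spacing, "t")
        with pytest.raises(ValueError, match="shape"):
            measure_enhancement(small, base, masks)


class TestRuleLabel:
    @pytest.mark.parametrize(
        "deltas,expected",
        [
            ({"artery": 250, "portal_vein": 5, "hepatic_vein": 0, "parenchyma": 5}, "EAP"),
            ({"artery": 200, "portal_vein": 45, "hepatic_vein": 5, "parenchyma": 20}, "LAP"),
            ({"artery": 80, "portal_vein": 100, "hepatic_vein": 90, "parenchyma": 50}, "PVP"),
            ({"artery": 60, "portal_vein": 70, "hepatic_vein": 60, "parenchyma": 35}, "DP"),
        ],
    )
    def test_decision_ladder(self, deltas, expected):
        assert rule_label(deltas) == expected

    def test_pvp_dp_pair_with_same_exam_reference(self):
        # near-flat washout: portal difference 34 HU, hepatic vein 9 HU
        pvp = {"artery": 80, "portal_vein": 100, "hepatic_vein": 90, "parenchyma": 50}
        dp = {"artery": 60, "portal_vein": 66, "hepatic_vein": 81, "parenchyma": 35}
        ref = LabelThresholds(pvp_reference={k: pvp[k] for k in
                                            ("portal_vein", "hepatic_vein", "parenchyma")})
        assert rule_label(pvp, ref) == "PVP"
        assert rule_label(dp, ref) == "DP"

    def test_missing_structure_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rule_label({"artery": 100, "portal_vein": 10, "parenchyma": 5})


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(8))
    def test_label_recovery_all_phases(self, spec32, profile, seed):
        """rule_label(measure_enhancement(generate(phase))) == phase."""
        for labels in ({"EAP", "PVP", "DP"}, {"LAP", "PVP", "DP"}):
            exam = make_phantom_exam(spec32, profile, labels, rng_seed=seed)
            masks, base = _geometry(spec32, seed)
            for p in exam.phases:
                deltas = measure_enhancement(p, base, masks)
                assert rule_label(deltas) == p.true_phase

    @pytest.mark.parametrize("seed", range(5))
    def test_pvp_exceeds_dp_on_every_generated_exam(self, spec32, profile, seed):
        exam = make_phantom_exam(spec32, profile, {"LAP", "PVP", "DP"}, rng_seed=seed)
        masks, base = _geometry(spec32, seed)
        by_phase = {p.true_phase: measure_enhancement(p, base, masks)
                    for p in exam.phases}
        for s in ("portal_vein", "hepatic_vein", "parenchyma"):
            assert by_phase["PVP"][s] > by_phase["DP"][s]


class TestEdgeCases:
    def test_eap_portal_flash_measured_delta(self, spec32):
        exam = make_edge_case("eap_portal_flash", spec32, seed=3)
        masks, base = _geometry(spec32, 3)
        ap = next(p for p in exam.phases if p.true_phase == "EAP")
        delta = measure_enhancement(ap, base, masks)["portal_vein"]
        assert 8.0 <= delta <= 17.0

    def test_pvp_dp_flat_differences(self, spec32):
        exam = make_edge_case("pvp_dp_flat", spec32, seed=5)
        masks, base = _geometry(spec32, 5)
        d = {p.true_phase: measure_enhancement(p, base, masks) for p in exam.phases}
        assert d["PVP"]["portal_vein"] - d["DP"]["portal_vein"] == pytest.approx(34, abs=6)
        assert d["PVP"]["hepatic_vein"] - d["DP"]["hepatic_vein"] == pytest.approx(9, abs=6)

    def test_lap_low_portal_just_above_moderate(self, spec32):
        exam = make_edge_case("lap_low_portal", spec32, seed=9)
        masks, base = _geometry(spec32, 9)
        lap = next(p for p in exam.phases if p.true_phase == "LAP")
        delta = measure_enhancement(lap, base, masks)["portal_vein"]
        t = LabelThresholds()
        assert t.portal_moderate < delta < t.portal_moderate + 10

    def test_unknown_kind_rejected(self, spec32):
        with pytest.raises(ValueError, match="unknown"):
            make_edge_case("bogus", spec32, seed=0)


def test_simulate_dataset_mixes_arterial_subphases(spec32, profile):
    exams = simulate_dataset(6, spec32, profile, seed=0)
    arterials = {p.true_phase for e in exams for p in e.phases
                 if p.true_phase in ("EAP", "LAP")}
    assert arterials == {"EAP", "LAP"}
    assert all(isinstance(e, Examination) and len(e.phases) == 3 for e in exams)
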