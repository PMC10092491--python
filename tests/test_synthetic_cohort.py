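"""Phantom generator: determinism, planted geometry/dosimetry, dose-model laws."""

import numpy as np
import pytest

from cardiospare import (
    PLAN_CSP,
    PLAN_NONCS,
    stratify_bundle,
    volume_cc,
)
from cardiospare.synthetic_cohort import (
    PhantomSpec,
    SCENARIO_FAR,
    SCENARIO_SPAREABLE,
    SCENARIO_UNSPAREABLE,
    SIGMA_PENUMBRA_MM,
    ball_mask,
    generate_cohort,
    generate_patient,
)
from scipy.special import erfc

DEFAULT_LATTICE = PhantomSpec.__dataclass_fields__["lattice"].default


class TestBallMask:
    def test_ptv_volume_calibration_28_1cc(self):
        """A ball targeted at the cohort-median 28.1 cm³ realises that volume
        to within one voxel on the 1×1×3 mm lattice."""
        ball = ball_mask(DEFAULT_LATTICE, (70.0, 70.0, 100.0), 28.1, "PTV")
        assert abs(volume_cc(ball) - 28.1) <= DEFAULT_LATTICE.voxel_volume_cc

    def test_center_outside_lattice_rejected(self):
        with pytest.raises(ValueError, match="outside lattice"):
            ball_mask(DEFAULT_LATTICE, (70.0, 70.0, 500.0), 28.1, "PTV")

    def test_subvoxel_volume_rejected(self):
        with pytest.raises(ValueError):
            ball_mask(DEFAULT_LATTICE, (70.0, 70.0, 100.0), 1e-4, "PTV")


class TestPhantomSpec:
    def test_volume_outside_cohort_range_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec("p", SCENARIO_FAR, (70, 70, 190), 500.0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec("p", "mystery", (70, 70, 190), 28.0)


class TestGeneratePatient:
    def test_far_ptv_plants_no_violations(self):
        """A PTV far cranial of every CS cannot violate any constraint: the
        erfc falloff puts < 1 Gy beyond ~17 mm and the planted gap is larger."""
        spec = PhantomSpec("p", SCENARIO_FAR, (70.0, 72.0, 195.0), 28.1)
        assert 60.0 * erfc(30.0 / (np.sqrt(2) * SIGMA_PENUMBRA_MM)) < 1.0
        _, truth = generate_patient(spec)
        assert not truth["needs_sparing"]
        assert truth["csp_class"] == "not_required"

    def test_abutting_ptv_plants_left_atrium_violation(self):
        """A PTV sharing axial planes with the left atrium at zero in-plane
        surface gap must exceed the 4.7 Gy EQD2 near-maximum limit."""
        # left-atrium centroid sits at heart center + (15, 8, 15) mm with
        # 12 mm in-plane surface radius; place a 19 mm-radius PTV abutting it
        center = (85.0 + 12.0 + 19.0, 80.0, 99.0)
        spec = PhantomSpec("p", SCENARIO_SPAREABLE, center, 28.1, make_csp=True)
        bundle, truth = generate_patient(spec)
        assert truth["needs_sparing"]
        assert truth["eqd2_noncs_left_atrium"] > 4.7
        strat = stratify_bundle(bundle)
        assert "left_atrium" in strat.violated_cs_noncs

    def test_same_spec_reproducible(self):
        spec = PhantomSpec("p", SCENARIO_SPAREABLE, (120.0, 95.0, 99.0), 20.0, make_csp=True)
        b1, t1 = generate_patient(spec)
        b2, t2 = generate_patient(spec)
        assert t1 == t2
        np.testing.assert_array_equal(
            b1.doses[PLAN_CSP].dose, b2.doses[PLAN_CSP].dose
        )
        for name in b1.masks:
            np.testing.assert_array_equal(b1.masks[name].voxels, b2.masks[name].voxels)

    def test_anatomy_disjoint_and_inside_heart(self):
        spec = PhantomSpec("p", SCENARIO_FAR, (70.0, 72.0, 195.0), 28.1)
        bundle, _ = generate_patient(spec)
        chambers = ["left_atrium", "left_ventricle", "right_ventricle", "right_atrium",
                    "ascending_aorta"]
        total = 0
        acc = np.zeros(DEFAULT_LATTICE.shape, bool)
        for name in chambers:
            vox = bundle.masks[name].voxels
            assert not (acc & vox).any()   # mutually disjoint
            acc |= vox
            total += vox.sum()
        heart = bundle.masks["heart"].voxels
        assert (acc & ~heart).sum() == 0    # CS ⊂ heart
        boh = bundle.masks["base_of_heart"].voxels
        expected = bundle.masks["right_atrium"].voxels | bundle.masks["ascending_aorta"].voxels
        np.testing.assert_array_equal(boh, expected)

    def test_gtv_is_eroded_ptv(self):
        spec = PhantomSpec("p", SCENARIO_FAR, (70.0, 72.0, 195.0), 28.1)
        bundle, _ = generate_patient(spec)
        ptv, gtv = bundle.masks["PTV"], bundle.masks["GTV"]
        assert gtv.voxel_count > 0
        assert not (gtv.voxels & ~ptv.voxels).any()
        assert gtv.voxel_count < ptv.voxel_count


@pytest.fixture(scope="module")
def steered_patient():
    spec = PhantomSpec(
        "p", SCENARIO_SPAREABLE, (120.0, 95.0, 99.0), 20.0, make_csp=True
    )
    return generate_patient(spec)


class TestDoseModel:

    def test_prescription_exact_on_ptv(self, steered_patient):
        bundle, _ = steered_patient
        ptv = bundle.masks["PTV"].voxels
        for plan in (PLAN_NONCS, PLAN_CSP):
            np.testing.assert_allclose(bundle.doses[plan].dose[ptv], 60.0)

    def test_monotone_nonincreasing_in_distance_from_ptv(self, steered_patient):
        """Dose declines monotonically with (steering-weighted) distance from
        the PTV, recomputed here independently — so along any ray, where both
        distance and the steering weight grow, dose can only fall."""
        from scipy import ndimage

        bundle, _ = steered_patient
        lat = bundle.lattice
        ptv = bundle.masks["PTV"]
        d = ndimage.distance_transform_edt(~ptv.voxels, sampling=lat.spacing)

        noncs = bundle.doses[PLAN_NONCS].dose
        order = np.argsort(d, axis=None)
        vals = noncs.flat[order]
        assert np.all(np.diff(vals) <= 1e-9)
        assert np.all(vals[d.flat[order] == 0] == vals.max())

        # steered plan: monotone in the direction-weighted effective distance
        centroid = ptv.coordinates_mm().mean(axis=0)
        steer = np.asarray(
            (70.0, 72.0, 84.0)  # heart center, the steering target
        ) - centroid
        steer /= np.linalg.norm(steer)
        xs, ys, zs = lat.center_grids()
        vx, vy, vz = xs - centroid[0], ys - centroid[1], zs - centroid[2]
        norm = np.sqrt(vx**2 + vy**2 + vz**2)
        with np.errstate(invalid="ignore"):
            cos = (vx * steer[0] + vy * steer[1] + vz * steer[2]) / norm
        cos = np.nan_to_num(np.clip(cos, 0.0, 1.0))
        d_eff = d * (1.0 + 5.0 * cos)
        csp = bundle.doses[PLAN_CSP].dose
        order = np.argsort(d_eff, axis=None)
        assert np.all(np.diff(csp.flat[order]) <= 1e-9)
        # steering can only remove dose
        assert np.all(csp <= noncs + 1e-9)

    def test_csp_spares_cardiac_side_and_preserves_coverage(self, steered_patient):
        bundle, _ = steered_patient
        noncs = bundle.doses[PLAN_NONCS].dose
        csp = bundle.doses[PLAN_CSP].dose
        la = bundle.masks["left_atrium"].voxels
        assert np.all(csp[la] <= noncs[la] + 1e-9)
        assert csp[la].max() < noncs[la].max()
        ptv = bundle.masks["PTV"].voxels
        v100_noncs = (noncs[ptv] >= 60.0).mean()
        v100_csp = (csp[ptv] >= 60.0).mean()
        assert abs(v100_csp - v100_noncs) <= 0.01


class TestGenerateCohort:
    def test_mix_18_10_6_plants_16_needing_sparing(self, phantom_cohort):
        # the session cohort is 3/3/2: five planted need-sparing patients
        _, truth = phantom_cohort
        assert int(truth["needs_sparing"].sum()) == 5
        assert (truth[truth.scenario == "far"]["csp_class"] == "not_required").all()
        assert (truth[truth.scenario == "near_spareable"]["csp_class"] == "successful").all()
        assert (
            truth[truth.scenario == "near_unspareable"]["csp_class"]
            == "partially_successful"
        ).all()

    def test_fraction_mix_resolution(self):
        _, truth = generate_cohort(4, {"far": 1.0}, seed=0)
        assert (~truth["needs_sparing"]).all()
        assert len(truth) == 4

    def test_degenerate_mix_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            generate_cohort(2, {"far": 2}, seed=0)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(4, {"far": 1, "near_spareable": 1}, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(4, {"mystery": 4}, seed=0)

    def test_same_seed_identical_bundles(self):
        b1, t1 = generate_cohort(3, {"far": 1, "near_spareable": 1, "near_unspareable": 1}, seed=7)
        b2, t2 = generate_cohort(3, {"far": 1, "near_spareable": 1, "near_unspareable": 1}, seed=7)
        assert t1.equals(t2)
        for x, y in zip(b1, b2):
            np.testing.assert_array_equal(
                x.doses[PLAN_NONCS].dose, y.doses[PLAN_NONCS].dose
            )

    def test_two_seeds_differ_but_class_counts_match(self):
        mix = {"far": 1, "near_spareable": 1, "near_unspareable": 1}
        _, t1 = generate_cohort(3, mix, seed=1)
        _, t2 = generate_cohort(3, mix, seed=2)
        assert not np.allclose(t1["ptv_cc"], t2["ptv_cc"])
        assert t1["scenario"].value_counts().equals(t2["scenario"].value_counts())
        assert t1["needs_sparing"].sum() == t2["needs_sparing"].sum()

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, {"far": 1}, seed=0)


class TestEndToEndRecovery:
    def test_planted_labels_recovered_by_constraints_module(self, phantom_cohort):
        """The pipeline's core property: stratification recomputed through
        dvh/eqd2/evaluate_plan equals the generator's independently computed
        planted truth for every patient."""
        bundles, truth = phantom_cohort
        for bundle, (_, row) in zip(bundles, truth.iterrows()):
            strat = stratify_bundle(bundle)
            assert strat.needs_sparing == row["needs_sparing"]
            assert strat.csp_class.value == row["csp_class"]
            assert ";".join(strat.violated_cs_noncs) == row["violated_cs_noncs"]
            assert ";".join(strat.violated_cs_csp) == row["violated_cs_csp"]
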