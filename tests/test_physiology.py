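"""Reference physiology, population sampling, and liver-disease scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import etrapbpk as ep
from etrapbpk.physiology import (
    BLOOD_POOLS,
    ENZYMES,
    ChildPughScalers,
    apply_child_pugh,
    build_reference_adult,
    sample_population,
    scale_fraction_unbound,
)


class TestReferenceAdult:
    def test_identity_scaling_at_reference_weight(self, reference_adult):
        again = build_reference_adult(73.0, 30.0)
        assert again.organs["liver"].volume_l == reference_adult.organs["liver"].volume_l
        assert again.weight_kg == 73.0

    def test_flow_conservation(self, reference_adult):
        regional = sum(
            o.blood_flow_l_per_h for n, o in reference_adult.organs.items()
            if n != "lung" and n not in BLOOD_POOLS
        )
        assert regional == pytest.approx(
            reference_adult.cardiac_output_l_per_h, rel=1e-9
        )
        # lung carries the full cardiac output in series
        assert reference_adult.organs["lung"].blood_flow_l_per_h == pytest.approx(
            regional, rel=1e-9
        )

    def test_double_weight_doubles_volumes(self, reference_adult):
        big = build_reference_adult(146.0, 30.0)
        for name, organ in reference_adult.organs.items():
            assert big.organs[name].volume_l == pytest.approx(
                2.0 * organ.volume_l, rel=1e-12
            )
        # flows scale allometrically, not linearly
        assert big.cardiac_output_l_per_h == pytest.approx(
            reference_adult.cardiac_output_l_per_h * 2.0 ** 0.75, rel=1e-12
        )

    @pytest.mark.parametrize("weight,age", [(20.0, 30.0), (250.0, 30.0),
                                            (73.0, 10.0), (73.0, 120.0)])
    def test_out_of_range_rejected(self, weight, age):
        with pytest.raises(ValueError):
            build_reference_adult(weight, age)


class TestPopulationSampling:
    def test_zero_cv_yields_identical_copies(self, reference_adult):
        pop = sample_population(
            reference_adult, 20,
            variability={"volume": 0.0, "flow": 0.0, "enzyme": 0.0}, seed=1,
        )
        assert len(pop) == 20
        for ind in pop.individuals:
            assert ind.organs["liver"].volume_l == reference_adult.organs["liver"].volume_l
            assert ind.enzyme_abundance_umol == reference_adult.enzyme_abundance_umol

    def test_seeded_reproducibility_bitwise(self, reference_adult):
        a = sample_population(reference_adult, 50, seed=1)
        b = sample_population(reference_adult, 50, seed=1)
        assert a.to_frame().equals(b.to_frame())
        c = sample_population(reference_adult, 50, seed=2)
        assert not a.to_frame().equals(c.to_frame())

    def test_sample_cv_recovers_requested_cv(self, reference_adult):
        pop = sample_population(
            reference_adult, 2000, variability={"enzyme": 0.35}, seed=7
        )
        amounts = np.array([
            ind.enzyme_abundance_umol["CYP3A4"] for ind in pop.individuals
        ])
        cv = amounts.std(ddof=1) / amounts.mean()
        assert 0.30 <= cv <= 0.40

    def test_population_mean_tracks_reference(self, reference_adult):
        pop = sample_population(reference_adult, 2000, seed=3)
        vols = np.array([
            ind.organs["liver"].volume_l for ind in pop.individuals
        ])
        se = vols.std(ddof=1) / np.sqrt(vols.size)
        assert abs(vols.mean() - reference_adult.organs["liver"].volume_l) < 3 * se

    def test_negative_cv_rejected(self, reference_adult):
        with pytest.raises(ValueError):
            sample_population(reference_adult, 5, variability={"enzyme": -0.1})


class TestChildPugh:
    def test_grade_c_portal_flow_scaler(self):
        assert ChildPughScalers.from_grade("C").portal_vein_flow == 0.04

    def test_grade_b_cyp_activity_scalers(self):
        b = ChildPughScalers.from_grade("B")
        assert b.cyp_activity["CYP3A4"] == 0.40
        assert b.cyp_activity["CYP2C9"] == 0.52
        assert b.cyp_activity["CYP2J2"] == 1.0

    def test_apply_scales_portal_flow_and_liver(self, reference_adult):
        c = ChildPughScalers.from_grade("C")
        impaired = apply_child_pugh(reference_adult, c)
        assert impaired.portal_flow_l_per_h == pytest.approx(
            0.04 * reference_adult.portal_flow_l_per_h, rel=1e-12
        )
        assert impaired.organs["liver"].volume_l == pytest.approx(
            0.28 * reference_adult.organs["liver"].volume_l, rel=1e-12
        )
        assert impaired.enzyme_activity["CYP3A4"] == pytest.approx(0.40)
        assert impaired.child_pugh_grade == "C"

    def test_apply_is_pure(self, reference_adult):
        before = reference_adult.parameter_row()
        apply_child_pugh(reference_adult, ChildPughScalers.from_grade("B"))
        assert reference_adult.parameter_row() == before

    def test_identity_scalers_change_nothing(self, reference_adult):
        out = apply_child_pugh(reference_adult, ChildPughScalers.identity())
        for name in reference_adult.organs:
            assert out.organs[name].volume_l == pytest.approx(
                reference_adult.organs[name].volume_l
            )
            assert out.organs[name].blood_flow_l_per_h == pytest.approx(
                reference_adult.organs[name].blood_flow_l_per_h
            )
        assert out.albumin_ratio == reference_adult.albumin_ratio

    def test_double_application_rejected(self, reference_adult):
        once = apply_child_pugh(reference_adult, ChildPughScalers.from_grade("A"))
        with pytest.raises(ValueError):
            apply_child_pugh(once, ChildPughScalers.from_grade("B"))

    def test_flow_conservation_after_scaling(self, reference_adult):
        for grade in "ABC":
            imp = apply_child_pugh(
                reference_adult, ChildPughScalers.from_grade(grade)
            )
            regional = sum(
                o.blood_flow_l_per_h for n, o in imp.organs.items()
                if n != "lung" and n not in BLOOD_POOLS
            )
            assert imp.organs["lung"].blood_flow_l_per_h == pytest.approx(
                regional, rel=1e-9
            )

    def test_monotone_severity_of_packaged_scalers(self):
        grades = [ChildPughScalers.identity()] + [
            ChildPughScalers.from_grade(g) for g in "ABC"
        ]
        for worse, better in zip(grades[1:], grades[:-1]):
            assert worse.functional_liver_mass <= better.functional_liver_mass
            assert worse.portal_vein_flow <= better.portal_vein_flow
            assert worse.albumin <= better.albumin
            for enz in ENZYMES:
                assert worse.cyp_activity[enz] <= better.cyp_activity[enz]


class TestFractionUnboundScaling:
    def test_reference_values(self):
        assert scale_fraction_unbound(0.021, 1.0) == pytest.approx(0.021)
        # closed form: 1 / (1 + 0.5 * 0.979 / 0.021) = 0.041136...
        assert scale_fraction_unbound(0.021, 0.50) == pytest.approx(
            0.0411361410, rel=1e-8
        )
        assert scale_fraction_unbound(0.021, 0.50) == pytest.approx(0.0412, abs=1e-4)
        assert scale_fraction_unbound(1.0, 0.5) == pytest.approx(1.0)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            scale_fraction_unbound(0.0, 1.0)
        with pytest.raises(ValueError):
            scale_fraction_unbound(0.5, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(fu=st.floats(1e-6, 1.0), ratio=st.floats(1e-3, 10.0))
    def test_bounds_and_identity(self, fu, ratio):
        fu2 = scale_fraction_unbound(fu, ratio)
        assert 0.0 < fu2 <= 1.0
        if ratio <= 1.0:
            assert fu2 >= fu * (1 - 1e-12)
        assert scale_fraction_unbound(fu, 1.0) == pytest.approx(fu, rel=1e-12)
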