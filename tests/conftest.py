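"""Shared fixtures: reference subject, drug, and a cached reference run."""

import dataclasses

import pytest

import etrapbpk as ep


@pytest.fixture(scope="session")
def reference_adult():
    return ep.build_reference_adult()


@pytest.fixture(scope="session")
def etrasimod():
    return ep.load_drug("etrasimod")


@pytest.fixture(scope="session")
def reference_simulation(reference_adult, etrasimod):
    """Healthy reference adult, 2 mg single oral dose, 336 h hourly grid."""
    model = ep.assemble(
        reference_adult, etrasimod, regimen=ep.DoseRegimen.single(2.0)
    )
    return ep.simulate(model, 336.0, 1.0)


@pytest.fixture(scope="session")
def reference_pk(reference_simulation):
    return ep.nca(
        reference_simulation.time_h,
        reference_simulation.plasma_conc_ng_per_ml,
    )


def make_water_organ(name="muscle", volume_l=1.0, flow=50.0):
    """An organ of pure extracellular water with no binding (Kp -> 1)."""
    return ep.OrganSpec(
        name=name, volume_l=volume_l, blood_flow_l_per_h=flow,
        f_ew=1.0, f_iw=0.0, f_nl=0.0, f_np=0.0, ap_mg_per_g=0.0,
        albumin_ratio=0.0, lipoprotein_ratio=0.0,
    )


def make_neutral_tracer(**overrides):
    """A freely diffusing neutral drug with no binding (one-compartment-like)."""
    defaults = dict(
        name="tracer",
        molecular_weight=100.0,
        effective_molecular_weight=100.0,
        log_lipophilicity=10.0,   # drives cellular permeability very high
        pka=7.0,
        acid_base_type="neutral",
        solubility_mg_per_ml=1e6,
        fraction_unbound=1.0,
        blood_to_plasma_ratio=1.0,
        intestinal_permeability_cm_per_min=0.004166666666666667,  # ka 0.5/h
        dissolution_t50_min=120.0,
        dissolution_shape=1.0,
        enzyme_clint_ul_per_min_per_pmol={"CYP3A4": 1.0},
    )
    defaults.update(overrides)
    return ep.DrugParameters(**defaults)


def make_degenerate_individual(central_volume_l=40.0):
    """All organs vanishingly small except venous blood: the whole body
    collapses to one well-mixed compartment with liver elimination."""
    ref = ep.build_reference_adult()
    organs = {}
    for name, organ in ref.organs.items():
        vol = central_volume_l if name == "venous blood" else 1e-4
        flow = 0.0 if name in ep.physiology.BLOOD_POOLS else 5000.0
        organs[name] = dataclasses.replace(
            make_water_organ(name, vol, flow), name=name
        )
    organs["lung"] = dataclasses.replace(
        organs["lung"],
        blood_flow_l_per_h=sum(
            o.blood_flow_l_per_h for n, o in organs.items()
            if n != "lung" and n not in ep.physiology.BLOOD_POOLS
        ),
    )
    ref.organs = organs
    # single enzyme sized for 2 L/h of intrinsic clearance
    # (1 uL/min/pmol specific clearance; uL/min -> L/h is 6e-5)
    ref.enzyme_abundance_umol = {"CYP3A4": 2.0 / (1.0 * 1e6 * 6e-5)}
    ref.enzyme_activity = {"CYP3A4": 1.0}
    return ref
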