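"""Whole-body model: structure, simulation and conservation properties."""

import numpy as np
import pytest

from translearn import constants
from translearn.pbpk import (
    ConfigurationError,
    DoseEvent,
    DrugParams,
    Physiology,
    ProcessKinetics,
    ValidationError,
    build_model,
    default_physiology,
    mass_balance,
    partition_coefficient,
    physiology_from_anthropometrics,
    simulate,
)
from translearn.pbpk.model import I_LIVER, I_TERMINAL, N_SLOTS


def _inert(name="inert", mw=100.0):
    return DrugParams(name=name, fraction_unbound=1.0, lipophilicity=-12.0,
                      molecular_weight=mw)


class TestPhysiology:
    def test_bmi_is_derived_from_weight_and_height(self):
        phys = physiology_from_anthropometrics(body_weight=81.0, body_height=1.80)
        assert phys.bmi == pytest.approx(81.0 / 1.80**2, abs=1e-9)

    def test_flow_bookkeeping_must_balance(self, mean_physiology):
        flows = dict(mean_physiology.organ_flows)
        flows["cardiac_output"] *= 1.5
        with pytest.raises(ValidationError, match="cardiac-output"):
            Physiology(
                age=35, body_weight=73, body_height=1.74,
                organ_volumes=mean_physiology.organ_volumes,
                organ_flows=flows, hematocrit=0.45, expression={},
            )

    def test_nonpositive_volume_rejected(self, mean_physiology):
        vols = dict(mean_physiology.organ_volumes)
        vols["liver"] = 0.0
        with pytest.raises(ValidationError, match="liver"):
            Physiology(
                age=35, body_weight=73, body_height=1.74, organ_volumes=vols,
                organ_flows=mean_physiology.organ_flows, hematocrit=0.45, expression={},
            )

    def test_allometry_scales_volumes_linearly_and_flows_sublinearly(self):
        small = physiology_from_anthropometrics(body_weight=50)
        big = physiology_from_anthropometrics(body_weight=150)
        ratio = 150 / 50
        assert big.organ_volumes["liver"] / small.organ_volumes["liver"] == pytest.approx(ratio)
        q = big.organ_flows["cardiac_output"] / small.organ_flows["cardiac_output"]
        assert q == pytest.approx(ratio**0.75)


class TestBuildModel:
    def test_midazolam_pair_has_three_active_processes(self, midazolam_pair, mean_physiology):
        model = build_model(mean_physiology, *midazolam_pair)
        assert model.active_process_names == {"CYP3A4", "UGT1A4", "ABCB1"}

    def test_torsemide_endothelial_scaling(self, torsemide_pair, mean_physiology):
        parent, metabolite = torsemide_pair
        assert parent.endothelial_permeability_scale["liver"] == 0.1
        assert all(
            v == 0.001
            for k, v in parent.endothelial_permeability_scale.items()
            if k != "liver"
        )
        model = build_model(mean_physiology, parent, metabolite)
        # compiled barrier: liver 0.1, kidney/rest 0.001; the mucosal gut
        # wall stays on the luminal side of the endothelium
        organs = {name: i for i, name in enumerate(
            ("gut_lumen", "gut_wall", "liver", "kidney", "arterial_plasma",
             "venous_plasma", "rest"))}
        assert model.scale[0, organs["liver"]] == 0.1
        assert model.scale[0, organs["kidney"]] == 0.001
        assert model.scale[0, organs["rest"]] == 0.001
        assert model.scale[0, organs["gut_wall"]] == 1.0

    def test_missing_expression_raises_configuration_error(self, mean_physiology):
        drug = DrugParams(
            name="x", fraction_unbound=0.5, lipophilicity=1.0, molecular_weight=100,
            intestinal_permeability=1e-3,
            processes=(ProcessKinetics("CYP9Z9", "metabolism", "x", None, 1.0, 1.0),),
        )
        with pytest.raises(ConfigurationError, match="CYP9Z9"):
            build_model(mean_physiology, drug, _inert())

    def test_partition_coefficient_monotone_in_lipophilicity(self):
        lo = DrugParams(name="a", fraction_unbound=0.1, lipophilicity=1.0,
                        molecular_weight=100)
        hi = DrugParams(name="b", fraction_unbound=0.1, lipophilicity=3.0,
                        molecular_weight=100)
        for organ in ("liver", "rest", "gut_wall", "kidney"):
            assert partition_coefficient(hi, organ) > partition_coefficient(lo, organ)
        assert partition_coefficient(hi, "venous_plasma") == 1.0


class TestSimulate:
    def test_zero_dose_gives_identically_zero_concentrations(
        self, midazolam_pair, mean_physiology, study_times
    ):
        model = build_model(mean_physiology, *midazolam_pair)
        profiles = simulate(model, [DoseEvent("midazolam", 0.0)], study_times)
        for p in profiles:
            assert np.all(p.concentrations == 0.0)

    def test_mean_model_peaks_at_interior_time(self, midazolam_pair, mean_physiology):
        model = build_model(mean_physiology, *midazolam_pair)
        times = np.linspace(0.05, 8.0, 160)
        result = model.solve([DoseEvent("midazolam", 1.0)], times)
        conc = result.venous_concentration("midazolam")
        tmax = times[np.argmax(conc)]
        assert 0.5 <= tmax <= 1.5  # absorption-calibration window
        assert conc[0] < conc.max() and conc[-1] < conc.max()
        assert np.all(conc >= 0)

    def test_pure_distribution_drug_conserves_amount_without_elimination(
        self, mean_physiology, study_times
    ):
        drug = DrugParams(name="d", fraction_unbound=0.5, lipophilicity=2.0,
                          molecular_weight=200.0, intestinal_permeability=5e-3)
        model = build_model(mean_physiology, drug, _inert())
        result = model.solve([DoseEvent("d", 1.0)], study_times)
        ledger = mass_balance(model, result)
        assert ledger["closed"]
        # no elimination pathway: urine and terminal ledgers stay empty
        assert np.all(ledger["urine"]["d"] == 0.0)
        assert np.all(ledger["terminal_metabolism"]["d"] == 0.0)

    def test_one_compartment_degenerate_configuration_matches_closed_form(self):
        """Fast-exchange, unit-partition configuration reduces exactly to the
        one-compartment model with first-order absorption."""
        volumes = dict(constants.REFERENCE_ORGAN_VOLUMES_L)
        flows = {k: v * 1e6 for k, v in constants.REFERENCE_PLASMA_FLOWS_L_PER_MIN.items()}
        phys = Physiology(age=35, body_weight=73, body_height=1.74,
                          organ_volumes=volumes, organ_flows=flows,
                          hematocrit=0.45, expression={})
        cl = 0.1  # l/min
        drug = DrugParams(name="probe", fraction_unbound=1.0, lipophilicity=-12.0,
                          molecular_weight=100.0, intestinal_permeability=1.0,
                          renal_clearance_specific=cl / 73.0)
        model = build_model(phys, drug, _inert())
        times = np.linspace(0.25, 8.0, 32)
        result = model.solve([DoseEvent("probe", 1.0)], times)
        obs = result.venous_concentration("probe")
        v_tot = sum(volumes[o] for o in volumes if o != "gut_lumen")
        dose_umol = 1.0 * 1000 / 100.0
        ka = 1.0 * constants.EFFECTIVE_AREA_CONSTANT_PER_CM
        ke = cl / v_tot
        t_min = times * 60.0
        expected = (dose_umol * ka / (v_tot * (ka - ke))
                    * (np.exp(-ke * t_min) - np.exp(-ka * t_min)))
        assert np.max(np.abs(obs - expected) / expected) < 1e-6

    def test_mid_run_dose_event_keeps_ledger_closed(self, midazolam_pair, mean_physiology):
        model = build_model(mean_physiology, *midazolam_pair)
        doses = [DoseEvent("midazolam", 1.0, time=0.0), DoseEvent("midazolam", 0.5, time=2.0)]
        result = model.solve(doses, np.linspace(0.5, 8, 16))
        ledger = mass_balance(model, result)
        assert ledger["closed"]
        # the 2 h dose raises the amount in the system by its molar amount
        i_before = np.searchsorted(result.times_h, 2.0) - 1
        assert ledger["dosed"][-1] > ledger["dosed"][i_before]


class TestMassBalance:
    def test_midazolam_ledger_closes_to_molar_dose(
        self, midazolam_pair, mean_physiology, study_times
    ):
        model = build_model(mean_physiology, *midazolam_pair)
        result = model.solve([DoseEvent("midazolam", 1.0)], study_times)
        ledger = mass_balance(model, result)
        assert ledger["closed"]
        assert ledger["dosed"][-1] == pytest.approx(1.0 * 1000 / 325.77)
        # glucuronidation drains the metabolite into the terminal ledger
        assert ledger["terminal_metabolism"]["OH-midazolam"][-1] > 0

    def test_zero_dose_ledger_identically_zero(self, torsemide_pair, mean_physiology,
                                               study_times):
        model = build_model(mean_physiology, *torsemide_pair)
        result = model.solve([DoseEvent("torsemide", 0.0)], study_times)
        ledger = mass_balance(model, result)
        assert np.all(ledger["total_in_system"] == 0.0)
        assert ledger["closed"]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_ledger_closes_for_randomized_parameters(
        self, torsemide_pair, midazolam_pair, seed, study_times
    ):
        rng = np.random.default_rng(seed)
        pairs = [midazolam_pair, torsemide_pair]
        for _ in range(10):
            parent, metabolite = pairs[rng.integers(2)]
            for proc in parent.processes:
                parent = parent.with_kcat(proc.protein, proc.kcat * rng.lognormal(0, 0.5))
            phys = physiology_from_anthropometrics(
                body_weight=float(rng.uniform(50, 200)),
                body_height=float(rng.uniform(1.55, 1.95)),
                liver_volume_factor=float(rng.lognormal(0, 0.2)),
            )
            model = build_model(phys, parent, metabolite)
            dose = float(rng.uniform(0.1, 5.0))
            result = model.solve([DoseEvent(parent.name, dose)], study_times)
            assert mass_balance(model, result)["closed"]


class TestKineticProperties:
    def test_metabolite_formation_linear_below_km(self, midazolam_pair, mean_physiology):
        """At substrate ≪ Km the formation rate is kcat·E/Km per unit unbound
        concentration (first-order regime), within 5% below Km/100."""
        parent, metabolite = midazolam_pair
        model = build_model(mean_physiology, parent, metabolite)
        proc = next(p for p in parent.processes if p.protein == "CYP3A4")
        fu, km = parent.fraction_unbound, proc.km
        v_liv = model.volumes[I_LIVER]
        kp_liv = model.kp[0, I_LIVER]
        expr = mean_physiology.expression[("CYP3A4", "liver")]
        for cu in (km / 1000, km / 200, km / 100):
            amount = cu * v_liv * kp_liv / fu  # amount giving unbound conc cu
            y = np.zeros(model.n_state)
            y[I_LIVER] = amount
            dy = model.rhs(0.0, y)
            formation = dy[N_SLOTS + I_LIVER]  # metabolite gains in liver
            linear = proc.kcat * expr / km * cu
            assert formation == pytest.approx(linear, rel=0.05)

    def test_halving_elimination_kcat_increases_auc(self, midazolam_pair, mean_physiology):
        parent, metabolite = midazolam_pair
        times = np.linspace(0.25, 8, 40)

        def parent_auc(p):
            model = build_model(mean_physiology, p, metabolite)
            res = model.solve([DoseEvent("midazolam", 1.0)], times)
            return np.trapezoid(res.venous_concentration("midazolam"), times)

        base = parent_auc(parent)
        halved = parent_auc(parent.with_kcat("CYP3A4", 0.05))
        assert halved > base

    def test_rhs_quasi_positive_from_nonnegative_state(self, torsemide_pair,
                                                       mean_physiology):
        model = build_model(mean_physiology, *torsemide_pair)
        rng = np.random.default_rng(3)
        for _ in range(50):
            y = rng.uniform(0, 1, model.n_state)
            zero_idx = rng.choice(model.n_state, size=5, replace=False)
            y[zero_idx] = 0.0
            dy = model.rhs(0.0, y)
            assert np.all(dy[zero_idx] >= -1e-12)


class TestDoseAndProfileValidation:
    def test_negative_dose_rejected(self):
        with pytest.raises(ValidationError):
            DoseEvent("midazolam", -1.0)

    def test_unknown_compound_dose_rejected(self, midazolam_pair, mean_physiology,
                                            study_times):
        model = build_model(mean_physiology, *midazolam_pair)
        with pytest.raises(ValidationError, match="unknown compound"):
            model.solve([DoseEvent("caffeine", 1.0)], study_times)

    def test_fraction_unbound_must_be_fraction(self):
        with pytest.raises(ValidationError):
            DrugParams(name="x", fraction_unbound=3.0, lipophilicity=1.0,
                       molecular_weight=100)
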