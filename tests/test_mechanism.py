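"""Mechanistic signal model: transport, binding, modification, digitonin."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scamflux import ConditionSpec, ConfigurationError, MechanismParams
from scamflux.simulate import signal_components, signal_model


def _app(conc=2.0, **kw):
    return ConditionSpec(substrate="APP+", substrate_conc_uM=conc, **kw)


class TestTransportSpecificity:
    def test_fluoxetine_blocks_95_percent_of_app_signal(self, mech):
        # the blockable fraction is concentration-independent by construction
        for conc in (2.0, 64.0):
            total, _ = signal_model(_app(conc), mech)
            blocked, _ = signal_model(_app(conc).blocked_partner(), mech)
            assert (total - blocked) / total == pytest.approx(0.95, abs=0.005)

    def test_fluoxetine_blocks_84_percent_of_asp_signal(self, mech):
        cond = ConditionSpec(substrate="ASP+", substrate_conc_uM=10.0)
        i1, m1 = signal_model(cond, mech)
        i0, m0 = signal_model(cond.blocked_partner(), mech)
        blockable = ((i1 + m1) - (i0 + m0)) / (i1 + m1)
        assert blockable == pytest.approx(0.84, abs=0.005)

    def test_transport_requires_both_na_and_cl(self, mech):
        for medium in ("NMDG-gluconate", "NMDG-Cl", "Na-isethionate"):
            comp = signal_components(_app(ion_medium=medium), mech)
            assert comp.interior_specific == 0.0
            assert comp.interior_nonspecific > 0.0
        assert signal_components(_app(ion_medium="NaCl"), mech).interior_specific > 0

    def test_app_has_no_membrane_component(self, mech):
        comp = signal_components(_app(), mech)
        assert comp.membrane_mean == 0.0


class TestModificationKinetics:
    def test_zero_concentration_leaves_everything_unmodified(self, mech):
        cond = _app(mutant="Y107C/C109A")
        assert mech.unmodified_fraction(cond) == 1.0

    def test_half_maximal_concentration_halves_activity(self, mech):
        k = mech.k_base[("Y107C/C109A", "MTSET")]
        c50 = math.log(2) / (k * 900.0)
        cond = _app(mutant="Y107C/C109A", mts_reagent="MTSET", mts_conc_M=c50, mts_time_s=900.0)
        assert mech.unmodified_fraction(cond) == pytest.approx(0.5, rel=1e-12)

    def test_interior_signal_strictly_decreasing_in_reagent_concentration(self, mech):
        concs = np.logspace(-7, -3, 12)
        sig = [
            signal_components(
                _app(mutant="Y107C/C109A", mts_reagent="MTSET", mts_conc_M=c, mts_time_s=900.0),
                mech,
            ).interior_specific
            for c in concs
        ]
        assert all(a > b for a, b in zip(sig, sig[1:]))

    def test_background_construct_insensitive_to_reagent(self, mech):
        sig = [
            signal_components(
                _app(mutant="C109A", mts_reagent="MTSET", mts_conc_M=c, mts_time_s=900.0), mech
            ).interior_specific
            for c in (1e-6, 1e-3)
        ]
        assert sig[0] == sig[1]

    def test_ligand_folds_scale_rate_constant(self, mech):
        base = mech.k_eff(_app(mutant="Y107C/C109A", mts_reagent="MTSET",
                               mts_conc_M=1e-5, mts_time_s=900.0))
        fluox = mech.k_eff(
            _app(mutant="Y107C/C109A", mts_reagent="MTSET", mts_conc_M=1e-5,
                 mts_time_s=900.0, ligand="fluoxetine", ligand_conc_uM=10.0)
        )
        assert fluox / base == pytest.approx(2.0)

    def test_mtsea_needs_digitonin_for_cytoplasmic_cysteine(self, mech):
        intact = ConditionSpec(
            substrate="ASP+", substrate_conc_uM=10.0, mutant="S277C/X5C",
            mts_reagent="MTSEA", mts_conc_M=5e-3, mts_time_s=300.0,
        )
        assert mech.unmodified_fraction(intact) == 1.0
        permeabilized = intact.with_(digitonin_ug_ml=25.0)
        assert mech.unmodified_fraction(permeabilized) < 0.01

    def test_mtset_cannot_reach_cytoplasmic_cysteine(self, mech):
        cond = ConditionSpec(
            substrate="ASP+", substrate_conc_uM=10.0, mutant="S277C/X5C",
            mts_reagent="MTSET", mts_conc_M=5e-3, mts_time_s=300.0, digitonin_ug_ml=25.0,
        )
        assert mech.unmodified_fraction(cond) == 1.0

    def test_partial_digitonin_caps_modifiable_fraction(self, mech):
        assert mech.access_completeness(10.0) == pytest.approx(0.4)
        assert mech.access_completeness(25.0) == 1.0
        assert mech.access_completeness(100.0) == 1.0
        cond = ConditionSpec(
            substrate="ASP+", substrate_conc_uM=10.0, mutant="S277C/X5C",
            mts_reagent="MTSEA", mts_conc_M=1.0, mts_time_s=300.0, digitonin_ug_ml=10.0,
        )
        # saturating reagent still leaves the inaccessible fraction active
        assert mech.unmodified_fraction(cond) == pytest.approx(0.6)


class TestDigitonin:
    def test_uptake_lost_but_binding_retained_at_reference_dose(self, mech):
        app0 = signal_components(_app(), mech).interior_specific
        app25 = signal_components(_app(digitonin_ug_ml=25.0), mech).interior_specific
        assert app25 / app0 < 0.05

        asp = ConditionSpec(substrate="ASP+", substrate_conc_uM=10.0)
        m0 = signal_components(asp, mech).membrane_specific
        m25 = signal_components(asp.with_(digitonin_ug_ml=25.0), mech).membrane_specific
        assert m25 / m0 > 0.6

    def test_total_asp_fluorescence_retained_above_60_percent(self, mech):
        asp = ConditionSpec(substrate="ASP+", substrate_conc_uM=10.0)
        i0, m0 = signal_model(asp, mech)
        i1, m1 = signal_model(asp.with_(digitonin_ug_ml=25.0), mech)
        assert (i1 + m1) / (i0 + m0) > 0.6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    # stay inside the representable exp() range so strict monotonicity holds
    conc=st.floats(1e-7, 1e-4),
    time=st.floats(10.0, 3600.0),
)
def test_unmodified_fraction_bounded_and_monotone(conc, time):
    mech = MechanismParams()
    cond = _app(mutant="S404C/C109A", mts_reagent="MTSET", mts_conc_M=conc, mts_time_s=time)
    u = mech.unmodified_fraction(cond)
    assert 0.0 <= u <= 1.0
    u2 = mech.unmodified_fraction(cond.with_(mts_conc_M=conc * 2))
    assert u2 < u


@pytest.mark.parametrize(
    "kwargs",
    [
        {"substrate": "XYZ+"},
        {"ion_medium": "KCl"},
        {"ligand": "caffeine"},
        {"mts_reagent": "MTSET", "mts_conc_M": 0.0},
        {"mts_reagent": "none", "mts_conc_M": 1e-5},
        {"substrate_conc_uM": -1.0},
    ],
)
def test_invalid_conditions_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        ConditionSpec(**kwargs)


def test_invalid_mechanism_rejected():
    with pytest.raises(ConfigurationError):
        MechanismParams(nonspecific_uptake_frac=1.5)
    with pytest.raises(ConfigurationError):
        MechanismParams(Kd_bind_asp=0.0)


def test_condition_manifest_round_trip():
    cond = ConditionSpec(
        substrate="ASP+", substrate_conc_uM=10.0, mutant="S277C/X5C",
        mts_reagent="MTSEA", mts_conc_M=1e-4, mts_time_s=300.0,
        ligand="5-HT", ligand_conc_uM=10.0, digitonin_ug_ml=25.0, experiment_id=2,
    )
    row = cond.to_manifest_row("stack_0001.tif")
    assert ConditionSpec.from_manifest_row(row) == cond
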