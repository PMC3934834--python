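"""Depolymerization occupancy models, steady-state partition, seeded growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spireformin import (
    Conditions,
    DepolyBindingModel,
    SteadyStateParams,
    depolymerization_rate,
    kind_effect,
    seeded_growth_rate,
    steady_state_unassembled,
)

conc_strategy = st.floats(0.0, 1e4, allow_nan=False)


class TestDepolymerizationRate:
    def test_free_ends_unit_rate(self):
        assert depolymerization_rate(DepolyBindingModel(), {}) == 1.0

    def test_saturating_formin_halves_total_rate(self):
        """60% inhibition of the barbed 83.3% share = 50% total slowdown."""
        rate = depolymerization_rate(DepolyBindingModel(), {"formin": math.inf})
        assert rate == pytest.approx(0.5, abs=0.001)

    def test_saturating_formin_plus_spire_full_barbed_block(self):
        model = DepolyBindingModel()
        rate = depolymerization_rate(model, {"formin": math.inf, "spire": math.inf})
        assert rate == pytest.approx(1 - model.f_barbed, abs=1e-9)
        assert rate == pytest.approx(0.167, abs=0.001)

    def test_saturating_spire_alone(self):
        model = DepolyBindingModel()
        rate = depolymerization_rate(model, {"spire": math.inf})
        assert rate == pytest.approx(1 - model.f_barbed * 0.7, abs=1e-9)

    def test_kind_on_fh1dfh2_completes_the_cap(self):
        rate = depolymerization_rate(DepolyBindingModel(),
                                     {"formin": math.inf, "kind": math.inf})
        assert rate == pytest.approx(0.167, abs=0.001)

    def test_kind_on_fh2_restores_free_rate(self):
        rate = depolymerization_rate(DepolyBindingModel(),
                                     {"fh2": math.inf, "kind": math.inf})
        assert rate == pytest.approx(1.0, abs=1e-9)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            depolymerization_rate(DepolyBindingModel(), {"gelsolin": 10.0})

    def test_two_formin_types_rejected(self):
        with pytest.raises(ValueError):
            depolymerization_rate(DepolyBindingModel(), {"formin": 1.0, "fh2": 1.0})

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(c1=conc_strategy, c2=conc_strategy)
    def test_monotone_in_cap_species(self, c1, c2):
        """More of a capping species never speeds disassembly up."""
        lo, hi = sorted([c1, c2])
        model = DepolyBindingModel()
        for species in ("formin", "spire"):
            assert (depolymerization_rate(model, {species: hi})
                    <= depolymerization_rate(model, {species: lo}) + 1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(c1=conc_strategy, c2=conc_strategy)
    def test_monotone_in_uncap_species(self, c1, c2):
        """KIND stripping FH2 restores the free-end rate monotonically."""
        lo, hi = sorted([c1, c2])
        model = DepolyBindingModel()
        assert (depolymerization_rate(model, {"fh2": 100.0, "kind": hi})
                >= depolymerization_rate(model, {"fh2": 100.0, "kind": lo}) - 1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(f=conc_strategy, s=conc_strategy)
    def test_rate_bounded_for_cap_only_models(self, f, s):
        model = DepolyBindingModel()
        rate = depolymerization_rate(model, {"formin": f, "spire": s})
        assert 1 - model.f_barbed - 1e-12 <= rate <= 1 + 1e-12


class TestKindEffect:
    def test_zero_kind_no_modification(self):
        eff = kind_effect("FH1D_FH2", 0.0)
        assert eff["occupancy"] == 0.0
        assert eff["effective_inhibition"] == pytest.approx(0.6)

    def test_saturating_on_fh1dfh2_full_cap(self):
        assert kind_effect("FH1D_FH2", 1e12)["effective_inhibition"] == pytest.approx(1.0, abs=1e-6)

    def test_saturating_on_fh2_uncaps(self):
        eff = kind_effect("FH2", 1e12)
        assert eff["mode"] == "uncap"
        assert eff["effective_inhibition"] == pytest.approx(0.0, abs=1e-6)


class TestSteadyState:
    def test_no_profilin(self):
        p = SteadyStateParams(P_total=0.0, A_total=2.5)
        res = steady_state_unassembled(p, all_ends_capped=True)
        assert res["PA_ss_uM"] == 0.0
        assert res["F_actin_uM"] == pytest.approx(2.5 - p.A_cP)

    def test_capped_sequestration_exceeding_actin(self):
        """P=6, K_P=0.1, A_cP=0.6: closed form demands 5.14 uM PA > 2.5 uM actin,
        so F-actin collapses to zero and PA follows exact mass action."""
        p = SteadyStateParams(P_total=6.0, K_P=0.1, A_cP=0.6, A_total=2.5)
        closed_form = 6.0 * 0.6 / 0.7
        assert closed_form == pytest.approx(5.14, abs=0.01)
        res = steady_state_unassembled(p, all_ends_capped=True)
        assert res["depleted"] and res["F_actin_uM"] == 0.0
        assert res["PA_ss_uM"] == pytest.approx(2.4318, abs=1e-3)
        # mass action consistency: P_free * G_free / PA = K_P
        pa, g = res["PA_ss_uM"], res["G_free_uM"]
        assert (6.0 - pa) * g / pa == pytest.approx(0.1, rel=1e-6)

    def test_infinite_kp_no_binding(self):
        p = SteadyStateParams(P_total=6.0, K_P=1e9, A_cP=0.6, A_total=2.5)
        res = steady_state_unassembled(p, all_ends_capped=True)
        assert res["PA_ss_uM"] == pytest.approx(0.0, abs=1e-6)

    def test_mass_conservation_when_filaments_remain(self):
        p = SteadyStateParams(P_total=2.0, K_P=0.1, A_cP=0.6, A_total=2.5)
        res = steady_state_unassembled(p, all_ends_capped=True)
        assert res["F_actin_uM"] > 0
        total = res["PA_ss_uM"] + res["G_free_uM"] + res["F_actin_uM"]
        assert total == pytest.approx(2.5, rel=1e-12)

    def test_capped_vs_active_partition(self):
        """Capping raises the monomer pool: less F-actin than with active ends."""
        p = SteadyStateParams(P_total=2.0, K_P=0.1, A_cP=0.6, A_cB=0.1, A_total=2.5)
        capped = steady_state_unassembled(p, all_ends_capped=True)
        active = steady_state_unassembled(p, all_ends_capped=False)
        assert capped["F_actin_uM"] < active["F_actin_uM"]


class TestSeededGrowth:
    def test_free_ends_rate(self, rc):
        cond = Conditions(spire_uM=0, formin_uM=0, pa_uM=1.0)
        rate = seeded_growth_rate(rc, cond, ends_nM=0.6)
        assert rate == pytest.approx(0.6e-3 * 8.8)

    def test_saturating_spire_blocks_growth(self, rc):
        cond = Conditions(spire_uM=1e6, formin_uM=0, pa_uM=1.0)
        free = seeded_growth_rate(rc, Conditions(pa_uM=1.0), 0.6)
        assert seeded_growth_rate(rc, cond, 0.6) < 1e-6 * free

    def test_half_effect_of_spire_at_K_S(self, rc):
        """At [S] = K_S and no formin, half the ends are capped."""
        K_S_uM = rc.k_off_S / rc.k_on_S_free
        full = seeded_growth_rate(rc, Conditions(pa_uM=1.0), 0.6)
        half = seeded_growth_rate(rc, Conditions(spire_uM=K_S_uM, pa_uM=1.0), 0.6)
        assert half == pytest.approx(0.5 * full, rel=1e-9)

    def test_excess_formin_restores_fast_growth(self, rc):
        """93 nM Spire with a large formin excess: rate approaches the fully
        formin-bound limit ends x v_formin."""
        cond = Conditions(spire_uM=0.093, formin_uM=50.0, pa_uM=1.0)
        rate = seeded_growth_rate(rc, cond, 0.6)
        limit = 0.6e-3 * 63.0
        assert rate == pytest.approx(limit, rel=0.05)
        assert rate < limit

    def test_spire_dose_response_is_hyperbolic_with_K_S(self, rc):
        """At [F]=0 the seeded rate falls as 1/(1+[S]/K_S)."""
        K_S_uM = rc.k_off_S / rc.k_on_S_free
        full = seeded_growth_rate(rc, Conditions(pa_uM=1.0), 0.6)
        for s in (0.002, 0.01, 0.05):
            rate = seeded_growth_rate(rc, Conditions(spire_uM=s, pa_uM=1.0), 0.6)
            assert rate == pytest.approx(full / (1 + s / K_S_uM), rel=1e-9)
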