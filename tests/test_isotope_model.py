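"""Unit and property tests for the labeling-model core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glncycle import (
    FluxSet,
    FluxValidationError,
    LabelingStrategy,
    MassBalanceError,
    ModelVariant,
    PoolSizes,
    SmallPoolWarning,
    Strategy,
    UndefinedStateError,
    astroglial_glu_fe,
    default_fluxes,
    default_pools,
    default_protocol,
    rhs_acetate_c4,
    rhs_full_glc,
    rhs_glc2_c3,
    rhs_simplified_glc,
    simulate_turnover,
    validate_fluxes,
)


class TestValidateFluxes:
    def test_fills_mass_balances(self):
        fx = validate_fluxes(FluxSet(vcyc=0.32, n_vtca=0.6, a_vtca=0.1, vana=0.04))
        assert fx.vgln == pytest.approx(0.36)
        assert fx.vefflux == pytest.approx(0.04)

    def test_negative_flux_named_in_error(self):
        with pytest.raises(FluxValidationError, match="vcyc"):
            validate_fluxes(FluxSet(vcyc=-0.1, n_vtca=0.6, a_vtca=0.1))

    def test_astroglial_tca_must_carry_anaplerosis(self):
        with pytest.raises(MassBalanceError, match="a_vtca"):
            validate_fluxes(FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.05, vana=0.1))

    def test_inconsistent_explicit_balance_rejected(self):
        with pytest.raises(MassBalanceError):
            validate_fluxes(
                FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.1, vana=0.04, vgln=0.5)
            )


class TestPoolSizes:
    def test_nonpositive_pool_rejected(self):
        with pytest.raises(FluxValidationError):
            PoolSizes(n_glu=10.0, a_glu=0.0, a_gln=3.7)

    def test_large_astroglial_glutamate_warns(self):
        with pytest.warns(SmallPoolWarning):
            PoolSizes(n_glu=10.0, a_glu=2.0, a_gln=3.7)


class TestLabelingStrategy:
    def test_non_glucose_strategies_require_simplified_variant(self):
        with pytest.raises(FluxValidationError):
            LabelingStrategy(Strategy.ACETATE_C2, ModelVariant.FULL)
        with pytest.raises(FluxValidationError):
            LabelingStrategy(Strategy.GLC_C2_VIA_PC, ModelVariant.FULL)

    def test_observables_match_labeled_positions(self):
        assert LabelingStrategy(
            Strategy.GLC_C2_VIA_PC, ModelVariant.SIMPLIFIED
        ).observables == ("nGlu3", "aGln3")
        assert LabelingStrategy().observables == ("nGlu4", "aGln4")


class TestAstroglialGluFe:
    def test_tracks_neuronal_glutamate_without_astroglial_tca(self):
        fx = validate_fluxes(FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.0))
        assert astroglial_glu_fe(fx, fe_lac=0.9, fe_nglu4=0.4) == pytest.approx(0.4)

    def test_tracks_lactate_without_cycling(self):
        fx = validate_fluxes(FluxSet(vcyc=0.0, n_vtca=0.6, a_vtca=0.2))
        assert astroglial_glu_fe(fx, fe_lac=0.5, fe_nglu4=0.9) == pytest.approx(0.5)

    def test_flux_weighted_mixture(self):
        fx = validate_fluxes(FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.1))
        # (0.1*0.5 + 0.3*0.4) / 0.4 = 0.425, hand evaluation of the closed form
        assert astroglial_glu_fe(fx, 0.5, 0.4) == pytest.approx(0.425)

    def test_zero_throughput_is_undefined(self):
        fx = validate_fluxes(FluxSet(vcyc=0.0, n_vtca=0.6, a_vtca=0.0))
        with pytest.raises(UndefinedStateError):
            astroglial_glu_fe(fx, 0.5, 0.4)


@pytest.fixture
def bench_fluxes():
    return validate_fluxes(
        FluxSet(vcyc=0.32, n_vtca=0.6, a_vtca=0.1, vana=0.04, vdil_gln=0.14)
    )


class TestRightHandSides:
    def test_unlabeled_fixed_point_full(self, bench_fluxes, pools):
        d = rhs_full_glc({"aGln4": 0.0, "nGlu4": 0.0}, bench_fluxes, pools, 0.0)
        assert d == {"aGln4": 0.0, "nGlu4": 0.0}

    def test_uniform_enrichment_fixed_point(self, pools):
        # vdil_gln = 0 and vefflux = vana = 0: fully equilibrated label is stationary
        fx = validate_fluxes(FluxSet(vcyc=0.32, n_vtca=0.6, a_vtca=0.1))
        f = 0.4
        state = {"aGln4": f * pools.a_gln, "nGlu4": f * pools.n_glu}
        d = rhs_full_glc(state, fx, pools, fe_lac=f)
        assert d["aGln4"] == pytest.approx(0.0, abs=1e-14)
        assert d["nGlu4"] == pytest.approx(0.0, abs=1e-14)

    def test_initial_neuronal_labeling_rate(self, bench_fluxes, pools):
        # all labels zero, fe_lac = 0.5: only the neuronal TCA feed term is active
        d = rhs_full_glc({"aGln4": 0.0, "nGlu4": 0.0}, bench_fluxes, pools, 0.5)
        assert d["nGlu4"] == pytest.approx(0.6 * 0.5)
        # glutamine is fed through the algebraic astroglial glutamate pool
        assert d["aGln4"] == pytest.approx(0.36 * (0.1 * 0.5) / 0.42)

    def test_missing_pool_is_contract_error(self, bench_fluxes, pools):
        with pytest.raises(KeyError):
            rhs_full_glc({"aGln4": 0.0}, bench_fluxes, pools, 0.5)

    def test_simplified_exchange_balance(self, pools):
        fx = validate_fluxes(FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.1))
        f = 0.3
        state = {"aGln4": f * pools.a_gln, "nGlu4": f * pools.n_glu}
        d = rhs_simplified_glc(state, fx, pools, fe_lac=f)
        assert d["aGln4"] == pytest.approx(0.0, abs=1e-14)

    def test_simplified_hand_sum(self):
        fx = validate_fluxes(
            FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.1, vdil_gln=0.14)
        )
        pools = PoolSizes(n_glu=10.0, a_glu=0.4, a_gln=4.0)
        state = {"nGlu4": 0.5 * 10.0, "aGln4": 0.2 * 4.0}
        d = rhs_simplified_glc(state, fx, pools, fe_lac=0.0)
        # 0.3*0.5 - 0.3*0.2 - 0.14*0.2
        assert d["aGln4"] == pytest.approx(0.062)

    def test_c3_route_unlabeled_fixed_point(self, bench_fluxes, pools):
        d = rhs_glc2_c3({"aGln3": 0.0, "nGlu3": 0.0}, bench_fluxes, pools, 0.0)
        assert d == {"aGln3": 0.0, "nGlu3": 0.0}

    def test_c3_route_anaplerotic_feed(self, bench_fluxes, pools):
        d = rhs_glc2_c3({"aGln3": 0.0, "nGlu3": 0.0}, bench_fluxes, pools, 0.5)
        assert d["aGln3"] == pytest.approx(0.04 * 0.5)
        assert d["nGlu3"] == 0.0

    def test_c3_steady_state_satisfies_closed_forms(self, bench_fluxes, pools):
        # pick glutamate C3 fe, derive the stationary glutamine C3 fe from the
        # neuronal balance, then check both derivatives vanish under the
        # lactate C2 enrichment implied by the astroglial balance
        fe_nglu3 = 0.05
        fe_agln3 = fe_nglu3 * (
            1.0 + 0.5 * bench_fluxes.n_vtca / bench_fluxes.vcyc
        )
        fe_lac2 = (
            bench_fluxes.vcyc * (fe_agln3 - fe_nglu3)
            + bench_fluxes.vdil_gln * fe_agln3
        ) / bench_fluxes.vana
        state = {"aGln3": fe_agln3 * pools.a_gln, "nGlu3": fe_nglu3 * pools.n_glu}
        d = rhs_glc2_c3(state, bench_fluxes, pools, fe_lac2)
        assert d["nGlu3"] == pytest.approx(0.0, abs=1e-15)
        assert d["aGln3"] == pytest.approx(0.0, abs=1e-15)

    def test_acetate_cycle_term_vanishes_at_equal_enrichment(self, bench_fluxes, pools):
        f = 0.2
        d = rhs_acetate_c4(
            {"nGlu4": f * pools.n_glu}, bench_fluxes, pools, fe_gln_feed=f
        )
        assert d["nGlu4"] == pytest.approx(-bench_fluxes.n_vtca * f)

    def test_acetate_hand_sum(self, pools):
        fx = validate_fluxes(FluxSet(vcyc=0.3, n_vtca=0.6, a_vtca=0.1))
        d = rhs_acetate_c4({"nGlu4": 0.0}, fx, pools, fe_gln_feed=0.2)
        assert d["nGlu4"] == pytest.approx(0.06)

    def test_acetate_mode_a_requires_forcing_curve(self, bench_fluxes, pools):
        with pytest.raises(UndefinedStateError):
            rhs_acetate_c4({"nGlu4": 0.0}, bench_fluxes, pools)

    def test_acetate_mode_b_dynamic_glutamine(self, bench_fluxes, pools):
        d = rhs_acetate_c4(
            {"nGlu4": 0.0, "aGln4": 0.0}, bench_fluxes, pools,
            mode="B", fe_acetyl=0.5,
        )
        assert d["aGln4"] == pytest.approx(bench_fluxes.a_vtca * 0.5)


class TestTrajectoryProperties:
    def test_enrichments_bounded_in_unit_interval(self, full_glc, fluxes, pools):
        prot = default_protocol(n_points_per_curve=200, duration=2000.0)
        curves = simulate_turnover(full_glc, fluxes, pools, prot)
        fe_glu = curves.values["nGlu4"] / pools.n_glu
        fe_gln = curves.values["aGln4"] / pools.a_gln
        for fe in (fe_glu, fe_gln):
            assert np.all(fe >= -1e-12) and np.all(fe <= 1.0 + 1e-12)

    def test_glutamate_c4_enrichment_exceeds_glutamine_c4(
        self, full_glc, fluxes, pools
    ):
        # with a positive glutamine dilution flux the product (glutamine C4)
        # stays strictly below its precursor (glutamate C4) at all t > 0
        prot = default_protocol(n_points_per_curve=100, duration=1000.0)
        curves = simulate_turnover(full_glc, fluxes, pools, prot)
        fe_glu = curves.values["nGlu4"][1:] / pools.n_glu
        fe_gln = curves.values["aGln4"][1:] / pools.a_gln
        assert np.all(fe_gln < fe_glu)

    def test_full_model_reduces_to_simplified(
        self, full_glc, simplified_glc, pools
    ):
        # with no astroglial TCA feed and no anaplerosis/efflux the full
        # equations collapse onto the simplified ones
        fx = validate_fluxes(
            FluxSet(vcyc=0.32, n_vtca=0.6, a_vtca=0.0, vana=0.0,
                    vdil_gln=0.14, vdil_lac=0.05)
        )
        prot = default_protocol(n_points_per_curve=64)
        full = simulate_turnover(full_glc, fx, pools, prot)
        simp = simulate_turnover(simplified_glc, fx, pools, prot)
        for obs in ("nGlu4", "aGln4"):
            assert np.max(np.abs(full.values[obs] - simp.values[obs])) < 1e-6

    @settings(max_examples=20, deadline=None)
    @given(
        vcyc=st.floats(0.05, 1.0),
        n_vtca=st.floats(0.1, 2.0),
        vdil=st.floats(0.0, 0.5),
        plateau=st.floats(0.0, 1.0),
    )
    def test_enrichment_bounds_hold_across_flux_space(
        self, vcyc, n_vtca, vdil, plateau
    ):
        fx = validate_fluxes(
            FluxSet(vcyc=vcyc, n_vtca=n_vtca, a_vtca=0.1, vana=0.04,
                    vdil_gln=vdil)
        )
        pools = default_pools()
        strat = LabelingStrategy(Strategy.GLC_C1, ModelVariant.FULL)
        prot = default_protocol(
            n_points_per_curve=50, duration=3000.0,
        )
        prot = default_protocol(
            n_points_per_curve=50, duration=3000.0,
            input_spec=prot.input_spec.__class__(shape="step", plateau_fe=plateau),
        )
        curves = simulate_turnover(strat, fx, pools, prot)
        fe_glu = curves.values["nGlu4"] / pools.n_glu
        fe_gln = curves.values["aGln4"] / pools.a_gln
        assert np.all(fe_glu >= -1e-10) and np.all(fe_glu <= 1.0 + 1e-10)
        assert np.all(fe_gln >= -1e-10) and np.all(fe_gln <= 1.0 + 1e-10)
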