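"""Closed-form conductance models: limits, symmetries, oracle agreement."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condcath import (
    ElectrodeConfig,
    SourceStrength,
    TissueModel,
    annulus_conductance_wei_style,
    lead_compartment_conductance,
    lead_currents,
    lead_total_conductance,
    lead_voltage,
    numeric_current,
    numeric_voltage,
    plate_blood_conductance,
    plate_total_conductance,
    total_conductance,
    wei_conductance,
    wei_total_conductance,
)
from condcath.field_core import plate_model_field, two_charge_field

SOURCE = SourceStrength(V0=1.0)


def oracle_wei(cfg, sigma, R):
    fld = two_charge_field(SOURCE.q(cfg), cfg.d_m)
    i = numeric_current(fld, sigma, cfg.r0, R)
    v = numeric_voltage(fld, -cfg.L / 2, cfg.L / 2)
    return abs(i / v)

def oracle_plate(cfg, sigma, R):
    i = numeric_current(plate_model_field(cfg, SOURCE, R), sigma, cfg.r0, R)
    v = 2 * numeric_voltage(plate_model_field(cfg, SOURCE, R, radial_offset=0.0), 0.0, cfg.L / 2)
    return abs(i / v)

def oracle_lead(cfg, sigma, R):
    q = SOURCE.q(cfg)
    i_d = numeric_current(two_charge_field(q, cfg.d_m, cfg.r0_m), sigma, cfg.r0, R)
    i_l = numeric_current(two_charge_field(q, cfg.L_m, cfg.r0_m), sigma, cfg.r0, R)
    v = numeric_voltage(two_charge_field(q, cfg.d_m), -cfg.L / 2, cfg.L / 2)
    return math.sqrt(i_d * i_l) / abs(v)


class TestWei:
    def test_zero_cavity(self, cfg):
        assert wei_conductance(cfg.r0, cfg, 0.7) == 0.0

    def test_below_electrode_radius_raises(self, cfg):
        with pytest.raises(ValueError):
            wei_conductance(0.5, cfg, 0.7)

    def test_infinite_cavity_limit(self, cfg):
        """Bounded above by the R -> inf limit of the mid-plane integral."""
        sigma = 0.7
        d, L, r0 = cfg.d_m, cfg.L_m, cfg.r0_m
        limit = math.pi * sigma * d * (d * d - L * L) / (2 * L) / math.sqrt(d * d + 4 * r0 * r0)
        assert wei_conductance(500.0, cfg, sigma) < limit
        assert annulus_conductance_wei_style(cfg.r0, math.inf, cfg, sigma) == pytest.approx(
            limit, rel=1e-14
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        r1=st.floats(1.0, 70.0),
        r2=st.floats(1.0, 70.0),
    )
    def test_strictly_increasing_in_radius(self, r1, r2):
        cfg = ElectrodeConfig(r0=1.0, L=20.0, d=40.0)
        lo, hi = sorted((r1, r2))
        if hi - lo < 1e-6:
            return
        assert wei_conductance(hi, cfg, 0.7) > wei_conductance(lo, cfg, 0.7)

    def test_matches_oracle(self, cfg):
        assert wei_conductance(20.0, cfg, 0.7) == pytest.approx(
            oracle_wei(cfg, 0.7, 20.0), rel=1e-6
        )


class TestWeiAnnulus:
    def test_empty_annulus_is_zero(self, cfg):
        assert annulus_conductance_wei_style(20.0, 20.0, cfg, 0.17) == 0.0

    def test_inverted_bounds_raise(self, cfg):
        with pytest.raises(ValueError):
            annulus_conductance_wei_style(30.0, 20.0, cfg, 0.17)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.floats(1.0, 60.0),
        b=st.floats(1.0, 60.0),
        c=st.floats(1.0, 60.0),
    )
    def test_telescoping_additivity(self, a, b, c):
        """annulus(a,b) + annulus(b,c) == annulus(a,c) for a <= b <= c."""
        cfg = ElectrodeConfig(r0=1.0, L=20.0, d=40.0)
        a, b, c = sorted((a, b, c))
        lhs = annulus_conductance_wei_style(a, b, cfg, 0.17) + annulus_conductance_wei_style(
            b, c, cfg, 0.17
        )
        rhs = annulus_conductance_wei_style(a, c, cfg, 0.17)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-18)

    def test_matches_oracle_on_muscle_annulus(self, cfg):
        fld = two_charge_field(SOURCE.q(cfg), cfg.d_m)
        i = numeric_current(fld, 0.17, 20.0, 30.0)
        v = numeric_voltage(fld, -cfg.L / 2, cfg.L / 2)
        assert annulus_conductance_wei_style(20.0, 30.0, cfg, 0.17) == pytest.approx(
            abs(i / v), rel=1e-6
        )


class TestPlate:
    def test_zero_cavity(self, cfg):
        assert plate_blood_conductance(cfg.r0, cfg, 0.7) == 0.0

    def test_below_electrode_radius_raises(self, cfg):
        with pytest.raises(ValueError):
            plate_blood_conductance(0.2, cfg, 0.7)

    def test_matches_oracle(self, cfg):
        assert plate_blood_conductance(15.0, cfg, 0.7) == pytest.approx(
            oracle_plate(cfg, 0.7, 15.0), rel=1e-6
        )

    def test_monotone_increasing_within_validity(self, cfg):
        radii = [cfg.r0 + 0.1 + i * (cfg.L - cfg.r0 - 0.2) / 200 for i in range(201)]
        values = [plate_blood_conductance(r, cfg, 0.7) for r in radii]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_validity_flag_beyond_L(self, cfg, phantom_tissue):
        assert plate_total_conductance(15.0, cfg, phantom_tissue).validity_flags == ()
        flags = plate_total_conductance(25.0, cfg, phantom_tissue).validity_flags
        assert any("validity" in f for f in flags)

    def test_total_is_sum_of_independent_parts(self, cfg, phantom_tissue):
        bd = plate_total_conductance(15.0, cfg, phantom_tissue)
        b, r_ba = phantom_tissue.wall_thickness, phantom_tissue.outer_radius(cfg)
        assert bd.G_blood == plate_blood_conductance(15.0, cfg, 0.7)
        assert bd.G_muscle == annulus_conductance_wei_style(15.0, 15.0 + b, cfg, 0.3)
        assert bd.G_background == annulus_conductance_wei_style(15.0 + b, r_ba, cfg, 0.2)
        assert bd.G_total == bd.G_blood + bd.G_muscle + bd.G_background

    def test_insulating_surround_leaves_blood_only(self, cfg, saline):
        bd = plate_total_conductance(15.0, cfg, saline)
        assert bd.G_muscle == 0.0 and bd.G_background == 0.0
        assert bd.G_total == bd.G_blood

    def test_zero_wall_thickness_removes_muscle_term(self, cfg):
        tissue = TissueModel(sigma_bl=0.7, sigma_m=0.3, sigma_ba=0.2, wall_thickness=0.0)
        assert plate_total_conductance(15.0, cfg, tissue).G_muscle == 0.0


class TestLead:
    def test_currents_vanish_at_zero_cavity(self, cfg):
        i_d, i_l = lead_currents(cfg.r0, cfg, 0.7)
        assert i_d == 0.0 and i_l == 0.0

    def test_currents_match_oracle(self, cfg):
        q = SOURCE.q(cfg)
        i_d, i_l = lead_currents(20.0, cfg, 0.7)
        i_d_o = numeric_current(two_charge_field(q, cfg.d_m, cfg.r0_m), 0.7, 1.0, 20.0)
        i_l_o = numeric_current(two_charge_field(q, cfg.L_m, cfg.r0_m), 0.7, 1.0, 20.0)
        assert i_d == pytest.approx(i_d_o, rel=1e-9)
        assert i_l == pytest.approx(i_l_o, rel=1e-9)

    def test_inverted_annulus_raises(self, cfg):
        with pytest.raises(ValueError):
            lead_currents(20.0, cfg, 0.7, rho_in=30.0, rho_out=20.0)

    def test_compartment_geometric_mean_degenerates(self):
        assert lead_compartment_conductance(-2.0, -2.0, 4.0) == pytest.approx(0.5)
        assert lead_compartment_conductance(0.0, -3.0, 4.0) == 0.0

    def test_opposite_sign_currents_rejected(self):
        with pytest.raises(ValueError):
            lead_compartment_conductance(1.0, -1.0, 4.0)

    def test_compartment_invariant_under_role_swap(self, cfg):
        i_d, i_l = lead_currents(20.0, cfg, 0.7)
        v = lead_voltage(cfg)
        assert lead_compartment_conductance(i_d, i_l, v) == lead_compartment_conductance(
            i_l, i_d, v
        )

    def test_blood_term_equals_direct_reciprocity_construction(self, cfg, saline):
        """The breakdown's blood term is sqrt(I_d*I_L)/V_all evaluated directly."""
        i_d, i_l = lead_currents(20.0, cfg, saline.sigma_bl)
        expected = math.sqrt(i_d * i_l) / lead_voltage(cfg)
        assert lead_total_conductance(20.0, cfg, saline).G_blood == pytest.approx(
            expected, rel=1e-14
        )

    def test_matches_oracle(self, cfg):
        assert lead_total_conductance(20.0, cfg, TissueModel(sigma_bl=0.7)).G_blood == (
            pytest.approx(oracle_lead(cfg, 0.7, 20.0), rel=1e-6)
        )

    def test_strictly_increasing_total(self, cfg, phantom_tissue):
        radii = [2.0 + i * (80.0 - 2.0) / 300 for i in range(301)]
        values = [lead_total_conductance(r, cfg, phantom_tissue).G_total for r in radii]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_total_additivity_exact(self, cfg, phantom_tissue):
        bd = lead_total_conductance(30.0, cfg, phantom_tissue)
        assert bd.G_total - bd.G_blood - bd.G_muscle - bd.G_background == 0.0
        assert bd.G_muscle > 0 and bd.G_background > 0


class TestTissueModel:
    def test_negative_conductivity_rejected(self):
        with pytest.raises(ValueError):
            TissueModel(sigma_bl=-0.1)

    def test_default_background_extent_is_five_spacings(self, cfg):
        assert TissueModel(sigma_bl=0.7).outer_radius(cfg) == 5 * cfg.d

    def test_unbounded_background_uses_closed_form_limit(self, cfg):
        bounded = TissueModel(sigma_bl=0.7, sigma_ba=0.2, background_outer_radius=50000.0)
        unbounded = TissueModel(sigma_bl=0.7, sigma_ba=0.2, background_outer_radius=math.inf)
        g_b = wei_total_conductance(20.0, cfg, bounded).G_background
        g_u = wei_total_conductance(20.0, cfg, unbounded).G_background
        assert g_u > g_b
        assert g_u == pytest.approx(g_b, rel=1e-3)


class TestCrossModelOrdering:
    def test_wei_inversion_overestimates_lead_generated_radius(self, cfg, phantom_tissue):
        """For a conductance produced by the lead model with conductive
        surroundings, the insulating Wei model needs a strictly larger radius
        to explain it (radius overestimation)."""
        for r_true in (13.3, 20.0, 30.0):
            g = lead_total_conductance(r_true, cfg, phantom_tissue).G_total
            assert wei_conductance(r_true, cfg, phantom_tissue.sigma_bl) < g


class TestDispatch:
    def test_unknown_acm_rejected(self, cfg, saline):
        with pytest.raises(ValueError):
            total_conductance("baan", 20.0, cfg, saline)

    @pytest.mark.parametrize("acm", ["wei", "plate", "lead"])
    def test_zero_cavity_blood_conductance(self, cfg, phantom_tissue, acm):
        assert total_conductance(acm, cfg.r0, cfg, phantom_tissue).G_blood == 0.0
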