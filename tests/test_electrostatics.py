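"""Screened-Coulomb model against longhand constant arithmetic."""

import math

import numpy as np
import pytest

from npcharge.electrostatics import (
    NPCModel,
    barrier,
    local_npc_charge,
    pair_energy,
    phosphorylation_shift,
    pore_volume,
    predict_particle,
    predict_particles,
    translocation_enthalpy,
)
from npcharge.io import ComplexManifest, ProteinRecord

# Longhand CODATA constants, independent of scipy.constants.
E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m
KB = 1.380649e-23  # J/K


def oracle_pair_energy(q1, q2, lam_nm, eps, temp_k):
    joules = q1 * q2 * E_CHARGE**2 / (4 * math.pi * EPS0 * eps * lam_nm * 1e-9)
    return joules / (KB * temp_k)


class TestPoreGeometry:
    def test_default_yeast_pore_volume(self):
        v = pore_volume(NPCModel())
        assert v == pytest.approx(math.pi * 19**2 * 37, rel=1e-12)
        assert v == pytest.approx(41962, abs=1.0)

    def test_unit_volume_cylinder(self):
        assert pore_volume(NPCModel(radius_nm=1.0, height_nm=1.0 / math.pi)) == (
            pytest.approx(1.0)
        )

    def test_doubling_radius_quadruples_volume(self):
        v1 = pore_volume(NPCModel(radius_nm=10.0))
        v2 = pore_volume(NPCModel(radius_nm=20.0))
        assert v2 == pytest.approx(4 * v1)


class TestLocalNPCCharge:
    def test_hand_evaluated_hemisphere_expectation(self):
        # 104 nucleoporins of median +10 e in the default pore:
        # 104 * 10 * ((2/3)*pi / (pi*19^2*37)) = 0.0519 e.
        model = NPCModel(median_nup_charge_e=10.0)
        assert local_npc_charge(model) == pytest.approx(0.0519, abs=1e-4)

    def test_zero_median_charge(self):
        assert local_npc_charge(NPCModel(median_nup_charge_e=0.0)) == 0.0

    def test_doubling_copies_doubles_charge(self):
        q8 = local_npc_charge(NPCModel(copies_per_species=8))
        q16 = local_npc_charge(NPCModel(copies_per_species=16))
        assert q16 == pytest.approx(2 * q8)

    def test_explicit_charge_list_uses_median(self):
        model = NPCModel(median_nup_charge_e=None, nup_charges_e=(5.0, 10.0, 30.0))
        expected = local_npc_charge(NPCModel(median_nup_charge_e=10.0))
        assert local_npc_charge(model) == pytest.approx(expected)

    def test_direct_q_npc_short_circuits(self):
        model = NPCModel(q_npc_e=0.05)
        assert local_npc_charge(model) == 0.05

    def test_missing_charges_error(self):
        with pytest.raises(ValueError, match="median"):
            local_npc_charge(NPCModel(median_nup_charge_e=None))


class TestPairEnergy:
    def test_unit_charges_in_water_at_one_nanometre(self):
        # e^2 / (4 pi eps0 * 80 * 1 nm) at 298.15 K.
        assert pair_energy(1.0, 1.0, 1.0, 80.0, 298.15) == pytest.approx(0.700, abs=0.005)

    def test_matches_longhand_oracle(self, rng):
        for _ in range(50):
            q1, q2 = rng.uniform(-60, 60, size=2)
            lam = rng.uniform(0.3, 3.0)
            eps = rng.uniform(2.0, 100.0)
            temp = rng.uniform(270.0, 320.0)
            assert pair_energy(q1, q2, lam, eps, temp) == pytest.approx(
                oracle_pair_energy(q1, q2, lam, eps, temp), rel=1e-9
            )

    def test_zero_charge_gives_zero(self):
        assert pair_energy(0.0, 7.0) == 0.0

    def test_inverse_screening_length_scaling_and_symmetry(self):
        e1 = pair_energy(3.0, -2.0, 1.0)
        assert pair_energy(3.0, -2.0, 0.5) == pytest.approx(2 * e1, rel=1e-12)
        assert pair_energy(-2.0, 3.0, 1.0) == pytest.approx(e1, rel=1e-12)

    def test_inverse_dielectric_scaling(self):
        assert pair_energy(1.0, 1.0, 1.0, 40.0) == pytest.approx(
            2 * pair_energy(1.0, 1.0, 1.0, 80.0), rel=1e-12
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(1.0, 1.0, -1.0)
        with pytest.raises(ValueError):
            pair_energy(1.0, 1.0, 1.0, 80.0, 0.0)


class TestTranslocationEnthalpy:
    def test_median_receptor_charge_gains_several_kbt(self):
        # A -50 e particle in the default pore gains ~2.5 kBT.
        assert translocation_enthalpy(-50.0, NPCModel()) == pytest.approx(-2.5, abs=0.3)

    def test_neutral_particle_feels_nothing(self):
        assert translocation_enthalpy(0.0, NPCModel()) == 0.0

    def test_linearity_in_particle_charge(self):
        model = NPCModel()
        base = translocation_enthalpy(1.0, model)
        for q in (-50.0, -3.5, 0.25, 12.0):
            assert translocation_enthalpy(q, model) == pytest.approx(q * base, rel=1e-12)

    def test_attraction_iff_opposite_signs(self):
        model = NPCModel()  # positive Q_NPC
        assert translocation_enthalpy(-10.0, model) < 0
        assert translocation_enthalpy(+10.0, model) > 0

    def test_per_unit_charge_step_is_about_005_kbt(self):
        model = NPCModel()
        for q in (-30.0, 0.0, 42.0):
            step = abs(
                translocation_enthalpy(q - 1.0, model) - translocation_enthalpy(q, model)
            )
            assert step == pytest.approx(0.05, abs=0.01)


class TestBarrierAndPhosphorylation:
    def test_flat_barrier_when_enthalpy_matches_entropy(self):
        assert barrier(-2.5, -2.5) == 0.0

    def test_pure_entropic_barrier(self):
        assert barrier(0.0, -3.0) == 3.0

    def test_additivity(self):
        assert barrier(-1.2, 0.7) + barrier(0.5, 0.0) == pytest.approx(
            barrier(-0.7, 0.7)
        )

    def test_single_site_shift(self):
        assert phosphorylation_shift(1, NPCModel()) == pytest.approx(-0.05, abs=0.01)

    def test_zero_sites_no_shift(self):
        assert phosphorylation_shift(0, NPCModel()) == 0.0

    def test_ten_sites_scale_linearly(self):
        model = NPCModel()
        assert phosphorylation_shift(10, model) == pytest.approx(
            10 * phosphorylation_shift(1, model), rel=1e-12
        )

    def test_negative_sites_rejected(self):
        with pytest.raises(ValueError):
            phosphorylation_shift(-1, NPCModel())


class TestPredictParticle:
    def test_lysine_excess_protein_faces_a_barrier(self):
        rec = ProteinRecord("basic", "K" * 50 + "A" * 50)
        pred = predict_particle(rec)
        assert pred.q_ntr_e > 0
        assert pred.delta_h_kbt > 0

    def test_complex_charge_is_sum_of_member_charges(self):
        a = ProteinRecord("a", "D" * 30 + "G" * 10)
        b = ProteinRecord("b", "K" * 20 + "G" * 10)
        cplx = ComplexManifest("ab", ((a, 1), (b, 1)))
        pa, pb, pc = (predict_particle(s) for s in (a, b, cplx))
        assert pc.q_ntr_e == pytest.approx(pa.q_ntr_e + pb.q_ntr_e, abs=1e-12)
        assert pc.delta_h_kbt == pytest.approx(pa.delta_h_kbt + pb.delta_h_kbt, abs=1e-12)

    def test_receptor_binding_flips_the_barrier_sign(self):
        # A basic cargo alone faces a barrier; bound to two acidic
        # receptor-like chains the complex charge (and hence the sign of
        # the enthalpy) flips -- the linker-histone scenario.
        cargo = ProteinRecord("cargo", "K" * 60 + "A" * 120)
        r1 = ProteinRecord("r1", "D" * 60 + "L" * 240)
        r2 = ProteinRecord("r2", "E" * 60 + "L" * 240)
        cplx = ComplexManifest("ternary", ((cargo, 1), (r1, 1), (r2, 1)))
        assert predict_particle(cargo).delta_h_kbt > 0
        assert predict_particle(cplx).delta_h_kbt < 0

    def test_supplied_entropic_cost_fills_in_barrier(self):
        rec = ProteinRecord("x", "DDDDKKGG")
        pred = predict_particle(rec, t_delta_s_kbt=-2.0)
        assert pred.delta_g_kbt == pytest.approx(pred.delta_h_kbt + 2.0)

    def test_table_prediction_matches_scalar_api(self):
        recs = [ProteinRecord("a", "DDKKGG"), ProteinRecord("b", "KKKAAA")]
        table = predict_particles(recs)
        for rec in recs:
            pred = predict_particle(rec)
            assert table.loc[rec.id, "delta_h_kbt"] == pytest.approx(pred.delta_h_kbt)


class TestNPCModelConfig:
    def test_roundtrip_from_yaml(self, tmp_path):
        p = tmp_path / "npc.yaml"
        p.write_text("radius_nm: 25\ncopies_per_species: 16\nq_npc_e: 0.07\n")
        model = NPCModel.from_config(p)
        assert model.radius_nm == 25
        assert model.copies_per_species == 16
        assert local_npc_charge(model) == 0.07

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "npc.yaml"
        p.write_text("pore_radius: 25\n")
        with pytest.raises(ValueError, match="pore_radius"):
            NPCModel.from_config(p)

    def test_summary_reports_coupling(self):
        text = NPCModel().summary()
        assert "Q_NPC" in text and "k_B T" in text
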