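"""QSSA reduction (apparent Michaelis-Menten binding) and cell-to-body
linking constants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellpkpd.cell import pretreatment_steady_state, simulate_in_vitro
from cellpkpd.params import drug_from_affinity
from cellpkpd.reduction import (
    LinkResult,
    ReducedCellParameters,
    compute_link,
    effective_bmax,
    effective_km,
    reduced_cell_parameters,
    reduced_free_concentration,
    reduced_rhs,
    simulate_reduced,
)
from cellpkpd.units import SF_UNIT


class TestEffectiveBmax:
    def test_value_for_fixture_rates(self, cell_invitro, drug_invitro):
        # SF_unit * 130 per min / (0.005/60 per min) = 2.59e-9 nmol/cell
        assert effective_bmax(cell_invitro, drug_invitro) == pytest.approx(
            2.5914e-9, rel=1e-4
        )

    def test_linear_in_synthesis_rate(self, cell_invitro, drug_invitro):
        doubled = dataclasses.replace(cell_invitro, k_synR=2 * cell_invitro.k_synR)
        assert effective_bmax(doubled, drug_invitro) == pytest.approx(
            2 * effective_bmax(cell_invitro, drug_invitro)
        )

    def test_independent_of_binding_kinetics(self, cell_invitro, drug_invitro):
        for k_offC in (0.0, 0.1, 10.0):
            altered = dataclasses.replace(drug_invitro, k_offC=k_offC)
            assert effective_bmax(cell_invitro, altered) == effective_bmax(
                cell_invitro, drug_invitro
            )

    def test_zero_internalization_is_unbounded(self, cell_invitro, drug_invitro):
        no_internalization = dataclasses.replace(drug_invitro, k_degRC=0.0)
        with pytest.raises(ValueError, match="unbounded"):
            effective_bmax(cell_invitro, no_internalization)


class TestEffectiveKm:
    def test_value_for_monkey_adjusted_fixture(self, cell_monkey, drug_invitro, env):
        # unscaled in vitro affinity of 7 nM gives ~7.1 nM in the monkey
        assert effective_km(cell_monkey, drug_invitro, env) == pytest.approx(
            7.076, rel=1e-3
        )

    def test_collapse_without_dissociation_and_ligand(self, cell_monkey, env):
        from cellpkpd.params import LigandEnvironment

        drug = drug_from_affinity(0.0, k_onC=0.072, k_degRC=0.005 / 60)
        km = effective_km(cell_monkey, drug, LigandEnvironment(L=0.0))
        c = cell_monkey
        expected = c.k_degRi * c.k_degR / (
            (c.k_degRi + c.k_recyRi) * drug.k_onC
        )
        assert km == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing_in_dissociation_rate(
        self, cell_monkey, drug_invitro, env
    ):
        k_offs = [0.0, 0.1, 0.5, 2.0]
        kms = [
            effective_km(
                cell_monkey,
                dataclasses.replace(drug_invitro, k_offC=k),
                env,
            )
            for k in k_offs
        ]
        assert np.all(np.diff(kms) > 0)


class TestReducedFreeConcentration:
    def test_zero_total_gives_zero_free(self):
        reduced = ReducedCellParameters(B_max_cell=2.6e-9, K_M_cell=7.0)
        assert reduced_free_concentration(0.0, reduced, 4e-13) == 0.0

    def test_vanishing_capacity_gives_free_equals_total(self):
        reduced = ReducedCellParameters(B_max_cell=1e-30, K_M_cell=7.0)
        assert reduced_free_concentration(123.0, reduced, 4e-13) == pytest.approx(
            123.0, rel=1e-9
        )

    @settings(deadline=None, max_examples=100)
    @given(
        C_tot=st.floats(min_value=1e-3, max_value=1e5),
        B_max=st.floats(min_value=1e-12, max_value=1e-7),
        K_M=st.floats(min_value=1e-2, max_value=1e3),
        V_ex=st.floats(min_value=1e-14, max_value=1e-10),
    )
    def test_mass_closure_for_random_parameters(self, C_tot, B_max, K_M, V_ex):
        """Free + bound/volume reconstructs the total concentration."""
        reduced = ReducedCellParameters(B_max_cell=B_max, K_M_cell=K_M)
        C_ex = reduced_free_concentration(C_tot, reduced, V_ex)
        assert 0.0 <= C_ex <= C_tot * (1 + 1e-12)
        A_RS = B_max * C_ex / (K_M + C_ex)
        assert C_ex + A_RS / V_ex == pytest.approx(C_tot, rel=1e-10)


class TestReducedRhs:
    def test_zero_at_zero_concentration(self, cell_monkey, drug_invitro, env):
        reduced = reduced_cell_parameters(cell_monkey, drug_invitro, env)
        assert reduced_rhs(0.0, reduced, drug_invitro, cell_monkey.V_ex) == 0.0

    def test_saturation_limit_is_zero_order(self, cell_monkey, drug_invitro, env):
        reduced = reduced_cell_parameters(cell_monkey, drug_invitro, env)
        V_ex = cell_monkey.V_ex
        limit = -drug_invitro.k_degRC * reduced.B_max_cell / V_ex
        huge = 1e9  # nM, far above K_M and capacity
        assert reduced_rhs(huge, reduced, drug_invitro, V_ex) == pytest.approx(
            limit, rel=1e-3
        )

    def test_depletion_matches_full_model_after_transient(
        self, cell_monkey, drug_invitro, env
    ):
        """Reduced depletion tracks the full trafficking model within 2%."""
        ss = pretreatment_steady_state(cell_monkey, env)
        C_tot0 = 50.0
        horizon = 20000.0
        full = simulate_in_vitro(
            ss, C_tot0, cell_monkey, drug_invitro, env, horizon=horizon
        )
        red = simulate_reduced(C_tot0, cell_monkey, drug_invitro, env, horizon)
        C_tot_full = full["C_ex"] + SF_UNIT * full["RC"] / cell_monkey.V_ex
        after = full.t > 500.0  # past the initial binding transient
        rel = np.abs(red["C_tot"][after] - C_tot_full[after]) / np.maximum(
            C_tot_full[after], 1e-6 * C_tot0
        )
        assert rel.max() < 0.02

    def test_discrepancy_shrinks_with_time_scale_separation(
        self, cell_monkey, env
    ):
        """Jointly speeding up binding (k_onC, k_offC x10, x100) drives the
        full model toward the reduced one, monotonically."""
        ss = pretreatment_steady_state(cell_monkey, env)
        C_tot0 = 50.0
        horizon = 20000.0
        discrepancies = []
        for scale in (1.0, 10.0, 100.0):
            # slow-binding baseline so the binding time scale is limiting
            drug = drug_from_affinity(
                7e-9, k_onC=7.2e-5 * scale, k_degRC=0.005 / 60
            )
            full = simulate_in_vitro(ss, C_tot0, cell_monkey, drug, env, horizon)
            red = simulate_reduced(C_tot0, cell_monkey, drug, env, horizon)
            C_tot_full = full["C_ex"] + SF_UNIT * full["RC"] / cell_monkey.V_ex
            discrepancies.append(
                np.max(np.abs(red["C_tot"] - C_tot_full)) / C_tot0
            )
        assert discrepancies[0] > discrepancies[1] > discrepancies[2]


class TestComputeLink:
    def test_number_of_relevant_cells(self, link):
        assert link.N_cell == pytest.approx(5.2e9, rel=0.005)

    def test_in_vitro_in_vivo_scaling_factor(self, link):
        assert link.SF_iviv == pytest.approx(2.1, abs=0.05)
        assert link.SF_iviv_inverse == pytest.approx(1 / link.SF_iviv)

    def test_capacity_closure(self, link, pk):
        assert link.N_cell * link.B_max_cell == pytest.approx(
            pk.B_max_PK, rel=1e-9
        )

    def test_forced_km_equality_gives_unit_factor(
        self, cell_monkey, drug_invitro, env, pk
    ):
        km_cell = effective_km(cell_monkey, drug_invitro, env)
        pk_equal = dataclasses.replace(pk, K_M_PK=km_cell)
        link = compute_link(pk_equal, cell_monkey, drug_invitro, env)
        assert link.SF_iviv == pytest.approx(1.0, rel=1e-12)

    def test_zero_synthesis_rejected(self, cell_monkey, drug_invitro, env, pk):
        dead = dataclasses.replace(cell_monkey, k_synR=0.0)
        with pytest.raises(ValueError, match="k_synR"):
            compute_link(pk, dead, drug_invitro, env)

    def test_json_round_trip(self, link):
        restored = LinkResult.from_json(link.to_json())
        assert restored == link
        assert restored.provenance == link.provenance
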