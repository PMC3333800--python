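"""Scenario runners and CLI: dose-response, affinity sweep, tumor
specificity, linking report."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from cellpkpd.cli import main as cli_main
from cellpkpd.experiments import (
    ANTIBODIES,
    SweepSpec,
    run_affinity_sweep,
    run_dose_response,
    run_linking_report,
    run_tumor_comparison,
)
from cellpkpd.metrics import receptor_saturation, residual_activity
from cellpkpd.reduction import LinkResult


class TestLinkingReport:
    def test_reported_constants(self):
        link, report = run_linking_report()
        assert link.N_cell == pytest.approx(5.2e9, rel=0.005)
        assert link.SF_iviv == pytest.approx(2.1, abs=0.05)
        assert "N_cell" in report and "SF_iviv" in report

    def test_report_round_trips_through_json(self):
        link, _ = run_linking_report()
        assert LinkResult.from_json(link.to_json()) == link


@pytest.fixture(scope="module")
def dose_response_summary():
    _, summary = run_dose_response((0.0, 2.0, 20.0))
    return summary


class TestDoseResponse:
    def test_zero_dose_control_has_no_saturation(self, dose_response_summary):
        row = dose_response_summary.set_index("dose_mg_per_kg").loc[0.0]
        assert row["max_saturation_pct"] == 0.0

    def test_low_dose_saturation_is_partial(self, dose_response_summary):
        row = dose_response_summary.set_index("dose_mg_per_kg").loc[2.0]
        assert row["max_saturation_pct"] == pytest.approx(60.0, abs=5.0)

    def test_effect_grows_with_dose(self, dose_response_summary):
        by_dose = dose_response_summary.set_index("dose_mg_per_kg")
        low, high = by_dose.loc[2.0], by_dose.loc[20.0]
        assert high["integral_of_inhibition"] > low["integral_of_inhibition"]
        assert high["duration_day"] > low["duration_day"]
        assert high["max_saturation_pct"] > low["max_saturation_pct"]

    def test_saturation_underestimates_inhibition_late(self, dose_trajectories):
        """At late times after a high dose, receptor saturation is smaller
        than the fractional loss of activated receptors."""
        traj = dose_trajectories[20.0]
        sat = receptor_saturation(traj["R"], traj["RL"], traj["RC"])
        resid = residual_activity(traj["RL"], traj.metadata["RL_star"])
        late = traj.t_days > 40.0
        assert np.all(sat[late] < 1.0 - resid[late])


@pytest.fixture(scope="module")
def sweep_table():
    spec = SweepSpec(
        K_D_grid=(1e-7, 1e-6),
        include_antibodies=True,
        k_degRC_multipliers=(1.0, 10.0),
        doses=(2.0, 20.0),
    )
    return run_affinity_sweep(spec)


class TestAffinitySweep:
    def test_no_point_failed(self, sweep_table):
        assert (sweep_table["error"] == "").all()

    @pytest.mark.parametrize("dose", [2.0, 20.0])
    def test_effect_plateau_across_marketed_antibodies(self, sweep_table, dose):
        """Despite a 140-fold affinity range, the integral of inhibition of
        the five antibodies varies by less than 15% (regression guard)."""
        sub = sweep_table[
            (sweep_table["antibody"].isin(ANTIBODIES))
            & (sweep_table["k_degRC_multiplier"] == 1.0)
            & (sweep_table["dose_mg_per_kg"] == dose)
        ]
        assert len(sub) == 5
        assert sub["E"].max() / sub["E"].min() < 1.15

    @pytest.mark.parametrize("dose", [2.0, 20.0])
    def test_low_affinity_weakens_the_effect(self, sweep_table, dose):
        sub = sweep_table[
            (sweep_table["k_degRC_multiplier"] == 1.0)
            & (sweep_table["dose_mg_per_kg"] == dose)
        ].set_index("antibody")
        assert sub.loc["KD=1e-06", "E"] < sub.loc["zalutumumab", "E"]

    def test_downregulation_helps_medium_affinity_antibodies(self, sweep_table):
        sub = sweep_table[
            (sweep_table["antibody"] == "KD=1e-07")
            & (sweep_table["dose_mg_per_kg"] == 20.0)
        ].set_index("k_degRC_multiplier")
        assert sub.loc[10.0, "E"] > sub.loc[1.0, "E"]

    def test_failed_points_are_recorded_not_raised(self):
        spec = SweepSpec(
            K_D_grid=(1e-9,), include_antibodies=False,
            k_degRC_multipliers=(1.0,),
            doses=(-2.0,),  # invalid bolus -> per-point error
        )
        table = run_affinity_sweep(spec)
        assert len(table) == 1
        assert table["error"].iloc[0] != ""

    def test_empty_grids_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec(K_D_grid=(), include_antibodies=False)


@pytest.fixture(scope="module")
def tumor_table():
    return run_tumor_comparison(doses=(2.0, 20.0))


class TestTumorComparison:
    def test_inhibition_is_stronger_on_tumor_cells(self, tumor_table):
        assert (tumor_table["S_E"] >= 1.0).all()
        assert (tumor_table["S_p"] >= 1.0 - 1e-9).all()
        assert (tumor_table["S_d"] >= 1.0 - 1e-9).all()

    @pytest.mark.parametrize("dose", [2.0, 20.0])
    def test_internalization_variant_outlasts_synthesis_variant(
        self, tumor_table, dose
    ):
        """Slower internalization prolongs inhibition far more than higher
        synthesis, so S_E and S_d rank the two alterations."""
        sub = tumor_table[tumor_table["dose_mg_per_kg"] == dose].set_index(
            "tumor_variant"
        )
        assert (
            sub.loc["decreased_internalization", "S_E"]
            > sub.loc["increased_synthesis", "S_E"]
        )
        assert (
            sub.loc["decreased_internalization", "S_d"]
            > sub.loc["increased_synthesis", "S_d"]
        )

    def test_pretreatment_activation_is_elevated_tenfold(self, tumor_table):
        ratio = tumor_table["RL_star_tumor"] / tumor_table["RL_star_normal"]
        assert ((ratio > 9.0) & (ratio < 11.5)).all()


class TestCli:
    def test_link_command_writes_json(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["link", "--out", str(tmp_path)]
        )
        assert result.exit_code == 0, result.output
        data = json.loads((tmp_path / "link.json").read_text())
        assert data["N_cell"] == pytest.approx(5.2e9, rel=0.005)

    def test_dose_response_command_writes_tables(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["dose-response", "--doses", "2", "--horizon", "20",
             "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "dose_response_summary.csv").exists()
        assert (tmp_path / "trajectory_2mgkg.csv").exists()
        assert (tmp_path / "run_metadata.json").exists()

    def test_simulate_command_reports_mass_balance(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["simulate", "--dose", "20", "--horizon", "30",
             "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        meta = json.loads((tmp_path / "run_metadata.json").read_text())
        assert meta["mass_balance_error"] < 1e-6
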