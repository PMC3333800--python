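"""Shared fixtures: one parameter load and a few session-scoped simulations
reused across test modules to keep the suite fast."""

import pytest

from cellpkpd import (
    DoseScenario,
    apply_species_adjustment,
    compute_link,
    load_environment,
    load_parameters,
    simulate_cell_level_pkpd,
)
from cellpkpd.experiments import build_model


@pytest.fixture(scope="session")
def fixture_params():
    cell, drug, pk = load_parameters("zalutumumab_monkey")
    return cell, drug, pk


@pytest.fixture(scope="session")
def env():
    return load_environment("zalutumumab_monkey")


@pytest.fixture(scope="session")
def cell_invitro(fixture_params):
    return fixture_params[0]


@pytest.fixture(scope="session")
def drug_invitro(fixture_params):
    """Fixture antibody with the unscaled in vitro affinity."""
    return fixture_params[1]


@pytest.fixture(scope="session")
def pk(fixture_params):
    return fixture_params[2]


@pytest.fixture(scope="session")
def cell_monkey(cell_invitro):
    return apply_species_adjustment(cell_invitro, "cynomolgus")


@pytest.fixture(scope="session")
def link(pk, cell_monkey, drug_invitro, env):
    return compute_link(pk, cell_monkey, drug_invitro, env)


@pytest.fixture(scope="session")
def bundle():
    """Default in vivo model: monkey-adjusted cell, affinity scaled by
    SF_iviv."""
    return build_model("zalutumumab_monkey")


@pytest.fixture(scope="session")
def dose_trajectories(bundle):
    """Combined-model runs for the three study doses (100-day horizon)."""
    out = {}
    for dose in (2.0, 20.0, 40.0):
        out[dose] = simulate_cell_level_pkpd(
            bundle.pk, bundle.cell, bundle.drug, bundle.link, bundle.env,
            DoseScenario(dose=dose),
        )
    return out


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
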