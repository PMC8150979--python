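"""Shared fixtures and the end-to-end reconstruction helper."""

import pytest

from gemsmith.fba import solve_fba
from gemsmith.model_core import MetabolicModel
from gemsmith.reconstruction import (
    add_reactions_from,
    draft_from_template,
    filter_orthologs,
    gap_fill,
    transfer_nongene_reactions,
)
from gemsmith.synthetic import ToyConfig, ToyEcosystem, make_ecosystem, toy_medium


@pytest.fixture(scope="session")
def eco() -> ToyEcosystem:
    return make_ecosystem(seed=0)


@pytest.fixture(scope="session")
def template(eco) -> MetabolicModel:
    return eco.template


@pytest.fixture(scope="session")
def medium() -> dict[str, float]:
    return toy_medium()


def run_pipeline(eco: ToyEcosystem) -> MetabolicModel:
    """Homology filtering -> draft -> transfer -> gap-fill, as a user would."""
    orthologs = filter_orthologs(eco.forward_hits, eco.reverse_hits)
    draft = draft_from_template(eco.template, orthologs)
    draft = transfer_nongene_reactions(eco.template, draft)
    added = gap_fill(
        draft, eco.template, draft.objective_reaction_id, toy_medium()
    )
    return add_reactions_from(draft, eco.template, added)


@pytest.fixture(scope="session")
def reconstructed(eco) -> MetabolicModel:
    model = run_pipeline(eco)
    assert solve_fba(model, medium=toy_medium()).optimal
    return model
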