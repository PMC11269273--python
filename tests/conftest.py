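import pytest
from hypothesis import settings

from phagerank.simulate import (
    CampaignSpec,
    generate_campaign,
    pick_planted_binders,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_campaign():
    """A small ground-truthed campaign shared across tests.

    200 library sequences, 3 planted binders at 10x per round, 2,000
    reads per round, 5% anchor SNVs, 2% frameshifts, fixed seed.
    """
    spec = CampaignSpec(
        n_library_sequences=200,
        reads_per_round=2000,
        planted_binders=pick_planted_binders(7, 3, 10.0),
        anchor_mutation_rate=0.05,
        frameshift_rate=0.02,
        seed=1,
    )
    return spec, generate_campaign(spec)


@pytest.fixture(scope="session")
def clean_campaign():
    """Corruption-free campaign: extraction must be lossless."""
    spec = CampaignSpec(
        n_library_sequences=100,
        reads_per_round=1000,
        planted_binders=pick_planted_binders(3, 2, 8.0),
        seed=5,
    )
    return spec, generate_campaign(spec)
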