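import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")

from vespaquant.abundance import aggregate_families, relative_abundance  # noqa: E402
from vespaquant.densitometry import proportions_from_areas  # noqa: E402
from vespaquant.spectral_filter import (  # noqa: E402
    apply_quality_filters,
    flag_contaminants,
)
from vespaquant.synthetic import default_truth, simulate  # noqa: E402


def recover_family_composition(ds):
    """Run the quantification path on a synthetic dataset in memory:
    contaminant flagging, quality filters, toxin restriction, analytic
    band-area proportions, band-weighted abundance, family aggregation."""
    hits = flag_contaminants(ds.hits, prefixes=("CRAP_", "DECOY_"))
    kept = apply_quality_filters(hits)
    toxin = [h for h in kept if ds.annotations[h.accession].is_toxin]
    proportions = proportions_from_areas(ds.band_areas)
    protein = relative_abundance(toxin, proportions)
    return aggregate_families(protein, ds.annotations)


@pytest.fixture(scope="session")
def truth():
    return default_truth(seed=7)


@pytest.fixture(scope="session")
def dataset(truth):
    return simulate(truth)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return simulate(default_truth(noise_sd_log=0.0, seed=3))
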