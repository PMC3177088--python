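import numpy as np
import pytest
from hypothesis import settings

from cysmap.pipeline import SurveyParams, run_survey
from cysmap.synthetic_data import GeneratorParams, generate_proteome

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A 30-protein bundle with every feature switched on (divergence,
    secreted proteins, metal motifs, odd cysteines)."""
    return generate_proteome(
        GeneratorParams(n_proteins=30, true_f=0.5, divergence=0.10, seed=42)
    )


@pytest.fixture(scope="session")
def exact_bundle():
    """Noise-free bundle: divergence 0, no secreted/metal/odd extras, so the
    pipeline estimate must equal the planted fraction exactly."""
    return generate_proteome(
        GeneratorParams(
            n_proteins=25,
            true_f=0.6,
            divergence=0.0,
            secreted_fraction=0.0,
            metal_motif_fraction=0.0,
            odd_cys_fraction=0.0,
            seed=43,
        )
    )


@pytest.fixture(scope="session")
def exact_survey(exact_bundle):
    # nothing secreted is planted, so the secretion filter stays off:
    # the estimate must then reproduce the planted fraction exactly
    from cysmap.filters import FilterParams

    return run_survey(
        exact_bundle.proteome,
        exact_bundle.structures,
        exact_bundle.library,
        SurveyParams(filter_params=FilterParams(signal_filter_mode="off")),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
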