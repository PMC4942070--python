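import warnings

import pytest

from abdesign import DesignSpec, ToxScenario, enumerate_pathways


def quiet_design(A, B, C, D, E, deescalate=False) -> DesignSpec:
    """Build a DesignSpec suppressing the legal-but-odd-parameter warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DesignSpec(A, B, C, D, E, deescalate)


def quiet_scenario(probs) -> ToxScenario:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ToxScenario(probs)


# The four worked examples: (design, true DLT probabilities per dose).
EXAMPLES = {
    "I": (DesignSpec(3, 3, 1, 1, 1, False), (0.05, 0.10, 0.33, 0.60)),
    "II": (DesignSpec(3, 3, 1, 1, 1, False), (0.04, 0.08, 0.16, 0.32, 0.64, 0.80)),
    "III": (DesignSpec(3, 3, 1, 1, 1, True), (0.06, 0.15, 0.29, 0.31, 0.33, 0.35)),
    "IV": (DesignSpec(2, 4, 1, 1, 2, True), (0.06, 0.20, 0.30, 0.40, 0.45)),
}


@pytest.fixture(scope="session")
def example_pathways():
    """Enumerated PathwaySets for the four worked examples, keyed by name."""
    return {
        name: enumerate_pathways(design, ToxScenario(probs))
        for name, (design, probs) in EXAMPLES.items()
    }


@pytest.fixture
def design_33():
    return EXAMPLES["I"][0]


@pytest.fixture
def design_33_deesc():
    return EXAMPLES["III"][0]


@pytest.fixture
def design_24_deesc():
    return EXAMPLES["IV"][0]
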