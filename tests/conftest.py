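import pytest

from gh13csr import SyntheticConfig, generate_family, generate_truth_msa
from gh13csr.synthetic_data import reference_annotation, truth_fingerprints


@pytest.fixture(scope="session")
def small_family():
    """A clean 12-member GH13_24-like family (no noise in the CSRs)."""
    config = SyntheticConfig(
        subfamily="GH13_24",
        n_sequences=12,
        substitution_rate=0.05,
        chloride_triad="RNR",
        sbs_plant=((2, 1, "W"), (4, 2, "Y")),
        seed=42,
    )
    records, truths = generate_family(config)
    return config, records, truths


@pytest.fixture(scope="session")
def truth_alignment(small_family):
    _, records, truths = small_family
    msa = generate_truth_msa(records, truths)
    return msa, reference_annotation(truths[0]), truths


@pytest.fixture(scope="session")
def small_fingerprints(small_family):
    _, _, truths = small_family
    return truth_fingerprints(truths)
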