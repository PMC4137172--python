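import pytest

from surfaceome.core_io import IdentificationRecord
from surfaceome.synthetic_data import (
    GeneratorConfig,
    generate_annotation_inputs,
    generate_quantification_inputs,
)


def make_identification(
    protein_id="Dred_0001",
    experiment="protoplast",
    condition="fermentation",
    replicate="R1",
    n_peptides=3,
    protein_fdr=0.005,
    spectral_count=10,
):
    return IdentificationRecord(
        protein_id=protein_id,
        experiment=experiment,
        condition=condition,
        replicate=replicate,
        n_peptides=n_peptides,
        protein_fdr=protein_fdr,
        spectral_count=spectral_count,
    )


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """One moderately sized noisy benchmark shared across tests."""
    config = GeneratorConfig(n_proteins=600, seed=19)
    inputs = generate_annotation_inputs(config)
    matrix, ratios = generate_quantification_inputs(config, inputs.truth)
    return config, inputs, matrix, ratios
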