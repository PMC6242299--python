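import pytest

import vmerv


@pytest.fixture(scope="session")
def default_config():
    return vmerv.SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One full synthetic study at the default configuration, shared across tests."""
    fragments, genes, truth = vmerv.generate_annotation(default_config)
    trackset = vmerv.generate_methylation_tracks(truth, default_config)
    return {
        "config": default_config,
        "fragments": fragments,
        "genes": genes,
        "truth": truth,
        "trackset": trackset,
    }


@pytest.fixture(scope="session")
def sim_summaries(sim_bundle):
    elements = vmerv.truth_to_elements(sim_bundle["truth"])
    return vmerv.summarize_ltr_methylation(elements, sim_bundle["trackset"])


def single_element_config(meth_class, structure="solo_LTR", seed=0, coverage=30.0, **kwargs):
    """Config with exactly one IAP element of the given methylation class."""
    return vmerv.SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length_bp=300_000,
        element_counts={("IAP", structure, meth_class): 1},
        coverage=coverage,
        n_genes=5,
        **kwargs,
    )
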