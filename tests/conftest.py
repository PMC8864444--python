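import pandas as pd
import pytest

from metascreen import normalize, simulate


def make_annotations(truth, organism_fraction=1.0):
    """Annotation table marking the first fraction of ions as organism compounds."""
    ions = truth.ion_ids
    n_org = int(round(organism_fraction * len(ions)))
    return pd.DataFrame(
        {
            "ion_id": ions,
            "compound_id": [f"C{i:05d}" for i in range(len(ions))],
            "is_organism_compound": [i < n_org for i in range(len(ions))],
        }
    )


@pytest.fixture(scope="session")
def small_params():
    return simulate.SimulationParams(
        n_genes=8, n_drugs=30, n_ions=80, n_planted=4, timepoints=(1.5,), seed=7
    )


@pytest.fixture(scope="session")
def truth(small_params):
    return simulate.generate_truth(small_params)


@pytest.fixture(scope="session")
def oe_screen(truth, small_params):
    return simulate.simulate_oe_screen(truth, small_params)


@pytest.fixture(scope="session")
def drug_screen(truth, small_params):
    return simulate.simulate_drug_screen(truth, small_params)


@pytest.fixture(scope="session")
def annotations(truth):
    return make_annotations(truth)


@pytest.fixture(scope="session")
def profiles(truth, small_params, oe_screen, drug_screen, annotations):
    # the outlier gate has its own tests; here every condition must survive
    # so downstream counting and planted-pair lookups are exact
    from metascreen import PipelineConfig

    cfg = PipelineConfig(mad_multiplier=float("inf"))
    oe_prof, _ = normalize.normalize_screen(oe_screen, annotations, cfg,
                                            scheme="control")
    drug_prof, _ = normalize.normalize_screen(drug_screen, annotations, cfg,
                                              scheme="plate")
    return oe_prof, drug_prof
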