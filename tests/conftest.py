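import warnings

import pytest

from txcrowd.config import TruthConfig
from txcrowd.organs import OrganLexicon
from txcrowd import synthetic

# statsmodels emits convergence chatter on small refits; failures surface as
# EstimationError, not warnings
warnings.filterwarnings("ignore", message="Maximum Likelihood optimization")


@pytest.fixture(scope="session")
def lexicon():
    return OrganLexicon.default()


@pytest.fixture(scope="session")
def small_config():
    """A small corpus with every exclusion rule exercised."""
    return TruthConfig(
        seed=11,
        n_campaigns=600,
        n_states=8,
        cities_per_state=4,
        frac_non_us=0.03,
        frac_invalid=0.02,
        frac_no_transplant=0.03,
        frac_outlier=0.001,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    """Gazetteer, name table, campaigns + truth, panel for the small config."""
    gaz = synthetic.generate_gazetteer(small_config)
    names = synthetic.generate_name_table(small_config, gaz)
    records, truth = synthetic.generate_campaigns(small_config, gaz, names)
    panel = synthetic.generate_state_panel(small_config)
    return {"config": small_config, "gazetteer": gaz, "names": names,
            "records": records, "truth": truth, "panel": panel}
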