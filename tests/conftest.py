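import numpy as np
import pytest

import ascotval as av


@pytest.fixture(scope="session")
def jp():
    return av.jp_tariff()


@pytest.fixture(scope="session")
def uk():
    return av.uk_tariff()


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared across tests (60 respondents)."""
    truth = av.SyntheticTruth.default(seed=42)
    bws_design, tto_design, bws, tto = av.simulate_study(truth, n_respondents=60)
    return {
        "truth": truth,
        "bws_design": bws_design,
        "tto_design": tto_design,
        "bws": bws,
        "tto": tto,
    }


@pytest.fixture(scope="session")
def small_choice_long(small_study):
    return av.responses_to_long(small_study["bws"])
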