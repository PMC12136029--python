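import numpy as np
import pytest

from metaniche import (
    make_quota_chain_model,
    project_niche,
    toy1_spec,
)

#: TOY1 reactions of interest: nutrient uptakes, carbon fixation, biomass.
TOY1_ROI = ["EX_N", "EX_P", "CFIX", "BIO"]

#: The reference environment: N ample, P exactly at quota, carbon in excess.
ENV_REFERENCE = {"EX_N": 2.0, "EX_P": 0.2, "CFIX": 12.0}

#: Nitrogen-limited environment.
ENV_N_LIMITED = {"EX_N": 0.5, "EX_P": 1.0, "CFIX": 100.0}


@pytest.fixture(scope="session")
def toy1():
    return make_quota_chain_model(toy1_spec())


@pytest.fixture(scope="session")
def toy1_niche(toy1):
    return project_niche(toy1, TOY1_ROI)


def random_bioavailability(rng, reactions, hi=2.0):
    return {r: float(rng.uniform(0.0, hi)) for r in reactions}
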