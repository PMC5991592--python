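import numpy as np
import pytest

from rbcedit.screen import AttributionConfig
from rbcedit.sequence import GuideRNA


@pytest.fixture(scope="session")
def guide() -> GuideRNA:
    return GuideRNA(name="g1", protospacer="ACGTACGTACGTACGTACGT", target_gene="KEL")


@pytest.fixture(scope="session")
def cfg() -> AttributionConfig:
    return AttributionConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20_18)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
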