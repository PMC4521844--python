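import numpy as np
import pytest

from smydkit.classification import AnchorSet, ClassLabel
from smydkit.synthetic_data import SynthConfig, generate_family
from smydkit.zinc_finger import RelaxPolicy, ZnPattern


@pytest.fixture(scope="session")
def pattern() -> ZnPattern:
    return ZnPattern.default()


@pytest.fixture(scope="session")
def relax() -> RelaxPolicy:
    return RelaxPolicy()


@pytest.fixture(scope="session")
def small_family():
    """One synthetic family at moderate divergence, shared across tests."""
    return generate_family(SynthConfig(seed=11, divergence=0.3, core_length=600))


def anchors_from_truth(truth, per_subgroup=False) -> AnchorSet:
    return AnchorSet(
        anchors={
            sid: ClassLabel(cls, sub)
            for sid, (cls, sub) in truth.anchor_ids(per_subgroup).items()
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
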