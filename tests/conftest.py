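import numpy as np
import pytest

from collagenphylo.simulate import SimulationConfig, simulate_dataset

AAS = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="session")
def bundle8():
    """Default-condition 8-taxon synthetic study bundle."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_alignment(rng, taxa, n_columns, x_prob=0.0):
    from collagenphylo.assembly import AminoAcidAlignment

    rows = {}
    for t in taxa:
        chars = rng.choice(list(AAS), size=n_columns)
        if x_prob > 0:
            mask = rng.random(n_columns) < x_prob
            chars = np.where(mask, "X", chars)
        rows[t] = "".join(chars)
    return AminoAcidAlignment(taxa=list(taxa), rows=rows)
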