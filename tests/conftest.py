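import numpy as np
import pytest

import saliencybench as sb


@pytest.fixture(scope="session")
def default_scenario():
    """The default synthetic study (20 images, 6 algorithms), seed 1."""
    return sb.gen_scenario(seed=1)


@pytest.fixture(scope="session")
def default_maps(default_scenario):
    sc = default_scenario
    return {aid: sc.maps_by_image(aid) for aid in sc.ensembles}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_auc(pos_values, neg_values):
    """Exhaustive pairwise-comparison oracle: wins + half-ties over pairs."""
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    wins = ties = 0
    for p in pos:
        wins += int((p > neg).sum())
        ties += int((p == neg).sum())
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
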