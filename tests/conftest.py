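import numpy as np
import pytest

import motifnet as mn
from motifnet.synthetic import generate_promoters


@pytest.fixture(scope="session")
def unmasked_promoters():
    """10 fully-free promoters, 2500 bp upstream / 200 bp downstream."""
    return generate_promoters(10, 2500, 200, 0.0, seed=1)


@pytest.fixture(scope="session")
def ccaat_pwm():
    return mn.PWM.from_consensus("CCAAT")


@pytest.fixture()
def two_promoter_set():
    """Two promoters, M=4 / N=0, promoter B masked at positions -4 and -3.

    The hand-computed background over these is K=8, E(d)=13/8, V(d)=35/8-(13/8)^2.
    """
    ps = generate_promoters(2, 4, 0, 0.0, seed=3)
    free = ps.free_mask.copy()
    free[1, 0] = False  # position -4
    free[1, 1] = False  # position -3
    return mn.PromoterSet(list(ps.gene_ids), list(ps.sequences), free, 4, 0)


def make_promoter(seq: str, upstream: int, downstream: int, gene="gX", mask=None):
    """Single-promoter set from an explicit sequence (optionally masked columns)."""
    free = np.ones((1, len(seq)), dtype=bool)
    if mask is not None:
        free[0, list(mask)] = False
    return mn.PromoterSet([gene], [seq.upper()], free, upstream, downstream)
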