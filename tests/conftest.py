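import numpy as np
import pytest

from dcmd.mixture import ComponentSet, FittedMixture, GammaComponent
from dcmd.otu_table import OTUTable, Resolutions


@pytest.fixture
def tiny_table() -> OTUTable:
    counts = np.array(
        [
            [0, 2, 5],
            [1, 0, 8],
            [3, 1, 0],
            [0, 4, 2],
        ]
    )
    return OTUTable(
        counts=counts,
        sample_ids=["s1", "s2", "s3", "s4"],
        otu_ids=["o1", "o2", "o3"],
        labels=np.array(["a", "a", "b", "b"]),
    )


@pytest.fixture
def unit_resolutions():
    def make(n):
        return Resolutions(t=np.ones(n), nbar=1000.0)

    return make


def make_mixture(weights, gammas, C=8, has_zero=True, has_high=True) -> FittedMixture:
    """Hand-built fitted mixture for distribution/distance tests."""
    comp = ComponentSet(
        gammas=tuple(GammaComponent(a, b) for a, b in gammas),
        C=C,
        has_zero_mass=has_zero,
        has_high_mass=has_high,
    )
    w = np.asarray(weights, dtype=float)
    return FittedMixture(
        components=comp,
        w=w,
        model_probs=np.array([1.0]),
        per_model_w=w[None, :],
    )
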