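import numpy as np
import pytest

from combopredict.sigio import (CompoundLibrary, DiseaseSignature,
                                GeneUniverse, RankedSignature)


@pytest.fixture
def universe5():
    return GeneUniverse(("g1", "g2", "g3", "g4", "g5"))


@pytest.fixture
def small_library(universe5):
    """Three compounds over five genes with hand-chosen z-scores."""
    z = {
        "cA": [1.0, 0.0, -1.0, 2.0, -2.0],
        "cB": [0.5, 2.0, -0.5, -1.0, 1.0],
        "cC": [-1.0, -1.0, 1.0, 1.0, 0.0],
    }
    sigs = {cid: RankedSignature(cid, universe5, np.array(v))
            for cid, v in z.items()}
    return CompoundLibrary(universe5, sigs)


@pytest.fixture
def disease_up_down():
    return DiseaseSignature("fxs", frozenset({"g1", "g2"}), frozenset({"g4"}))


def ks_bruteforce(positions, n):
    """Independent running-sum oracle for the KS enrichment statistic.

    Walks every step position j explicitly and tracks the two one-sided
    maximal deviations between the member-position empirical CDF and the
    uniform CDF; returns the signed larger one, exactly as the statistic
    is defined, without any vectorization shared with the implementation.
    """
    p = sorted(positions)
    t = len(p)
    a = max(j / t - p[j - 1] / n for j in range(1, t + 1))
    b = max(p[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b
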