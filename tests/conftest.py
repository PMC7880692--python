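import numpy as np
import pytest

from tcrdyn.io import RepertoireSample, TcrClone


def make_sample(counts, subject_id="S1", time_point="PS", chain="beta",
                v_gene="TRBV1", j_gene="TRBJ1", **meta):
    """Build a sample from {cdr3: abundance}; one V/J for all clones unless
    counts values are (v, j, abundance) triples."""
    clones = []
    for cdr3, val in counts.items():
        if isinstance(val, tuple):
            v, j, a = val
        else:
            v, j, a = v_gene, j_gene, val
        clones.append(TcrClone(chain=chain, v_gene=v, j_gene=j,
                               cdr3_aa=cdr3, abundance=a))
    return RepertoireSample.from_clones(clones, subject_id=subject_id,
                                        time_point=time_point, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_sample():
    return make_sample({"CASSAF": 10, "CASSBF": 5, "CASSCF": 1})
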