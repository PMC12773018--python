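import os

# single-threaded BLAS: the suite is tuned for one CPU and oversubscribed
# thread pools only add sys-time overhead
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest

from pepdev.core import Modality, PeptideRecord, PropertyDataset, get_task


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_aa_sequences(rng, n, lo=8, hi=20):
    from pepdev.core import AA_ALPHABET

    letters = np.array(list(AA_ALPHABET))
    return [
        "".join(letters[rng.integers(0, 20, size=rng.integers(lo, hi + 1))])
        for _ in range(n)
    ]


@pytest.fixture
def small_binary_dataset():
    recs = [
        PeptideRecord(id=f"r{i}", modality=Modality.AA, payload=p, labels={"hemolysis": y})
        for i, (p, y) in enumerate(
            [("GLFDIVKKVV", 1.0), ("ACDEFGHIKL", 1.0), ("PPPPGGGGSS", 0.0)]
        )
    ]
    return PropertyDataset(task=get_task("hemolysis"), records=recs)
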