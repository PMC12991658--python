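import numpy as np
import pytest

import finestab as fs

# Worked-example probability vectors: pooled + two subpopulation slices over
# five SNPs named A1..A5 (C = 1 potential set).
WORKED_POOLED = [0.45, 0.43, 0.02, 0.10, 0.00]
WORKED_SLICE_1 = [0.00, 0.40, 0.10, 0.25, 0.25]
WORKED_SLICE_2 = [0.20, 0.60, 0.00, 0.10, 0.10]
WORKED_IDS = ["A1", "A2", "A3", "A4", "A5"]


def dense_vector(values, kind="pics"):
    values = np.asarray(values, dtype=float)
    return fs.PosteriorVector(
        support=np.arange(values.size),
        probs=values,
        lead_index=int(np.argmax(values)),
        kind=kind,
        n_variants=values.size,
    )


@pytest.fixture
def worked_example():
    return {
        "pooled": [dense_vector(WORKED_POOLED)],
        "slices": {
            "E1": [dense_vector(WORKED_SLICE_1)],
            "E2": [dense_vector(WORKED_SLICE_2)],
        },
        "variant_ids": np.asarray(WORKED_IDS, dtype=object),
    }


@pytest.fixture
def small_locus():
    """A small synthetic locus with LD blocks and five labelled populations."""
    return fs.synth_genotypes(
        n_per_pop=(40, 40, 40, 40, 40),
        n_variants=40,
        ld_block_size=8,
        ld_rho=0.8,
        seed=11,
    )


@pytest.fixture
def cohort_locus():
    """A locus at the default cohort size (N = 445, five populations)."""
    return fs.synth_genotypes(n_variants=60, seed=23)
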