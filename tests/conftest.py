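import logging

import numpy as np
import pandas as pd
import pytest

import subtypekit as sk
from subtypekit import synthetic
from subtypekit.types import PLATFORM_TABLE

logging.getLogger("subtypekit").setLevel(logging.ERROR)


def make_expression(values, gene_ids=None, sample_ids=None,
                    platform="microarray"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    scale, units = PLATFORM_TABLE[platform]
    return sk.ExpressionMatrix(
        data=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        scale=scale, units=units, platform=platform,
    )


def make_clinical(er, pr=None, her2=None, tn=None, sample_ids=None):
    n = len(er)
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    table = pd.DataFrame(
        {
            "er": er,
            "pr": pr if pr is not None else ["unknown"] * n,
            "her2": her2 if her2 is not None else ["unknown"] * n,
            "tn": tn if tn is not None else [False] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return sk.ClinicalTable(table)


@pytest.fixture(scope="session")
def registry():
    return sk.load_registry()


@pytest.fixture(scope="session")
def toy_models():
    return sk.make_toy_models(seed=1, noise_sd=0.3)


@pytest.fixture(scope="session")
def mega_cohort(toy_models):
    return synthetic.make_mega_cohort(toy_models, size=1500, noise_sd=0.3,
                                      seed=1)


@pytest.fixture(scope="session")
def balanced_cohort(toy_models):
    spec = sk.SimSpec(seed=7, noise_sd=0.2, n=200)
    return sk.simulate_cohort(spec, toy_models.centroid)
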