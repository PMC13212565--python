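"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from limnoscope import synthetic


@pytest.fixture(scope="session")
def study_bundle():
    """The four study lineages at desk scale: 20 genomes each, gene counts
    scaled from a 200-gene reference. Shared across recovery and contrast
    tests; generation is deterministic under the fixed seed."""
    config = synthetic.study_config(seed=11, n_genomes=20, genes_reference=200)
    return synthetic.simulate(config)


@pytest.fixture(scope="session")
def study_truth(study_bundle):
    """Ground-truth LineageSpec per lineage name."""
    return {spec.name: spec for spec in study_bundle.config.lineages}


@pytest.fixture()
def toy_tree() -> dendropy.Tree:
    """((A:0.1,B:0.2):0.3,C:0.4); - the worked PD example."""
    return dendropy.Tree.get(
        data="((A:0.1,B:0.2):0.3,C:0.4);",
        schema="newick",
        preserve_underscores=True,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
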