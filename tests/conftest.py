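"""Shared fixtures: one default synthetic cohort reused across test modules."""

import numpy as np
import pytest

from lncortho.locate import AnchorSet
from lncortho.simulate import (DEFAULT_TREE, EvolutionRates, PhyloTree,
                               SyntheticLocusSpec, simulate_cohort)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def default_cohort():
    """Root locus + leaves evolved along the default tree (seed 1)."""
    spec = SyntheticLocusSpec()
    tree = PhyloTree(DEFAULT_TREE)
    root, truth, leaves = simulate_cohort(spec, tree, EvolutionRates(), seed=1)
    return {"spec": spec, "tree": tree, "root": root, "truth": truth,
            "leaves": leaves}


@pytest.fixture(scope="session")
def default_anchors(default_cohort):
    return {key: AnchorSet.from_truth(default_cohort["root"],
                                      default_cohort["truth"], key)
            for key in ("divergent", "conserved")}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
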