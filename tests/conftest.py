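import warnings

import numpy as np
import pytest

from pymocca import (
    IupacMotif,
    LabelledSequence,
    MarkovModel,
    MoccaClassifier,
    PlantingPlan,
    make_planted_cre_set,
)

PRE_MOTIFS = [IupacMotif("GAF", "GAGAG"), IupacMotif("PHO", "GCCAT")]


@pytest.fixture(scope="session")
def uniform_bg():
    return MarkovModel.uniform(0)


@pytest.fixture(scope="session")
def pre_motifs():
    return PRE_MOTIFS


def planted_dataset(
    seed: int,
    n_per_class: int = 30,
    length: int = 2000,
    counts=None,
    cluster_width: int = 500,
):
    """Three-class planted-combinatorics dataset: CREs with clustered motif
    occurrences, dummy-CREs with the same counts uniformly placed, and pure
    background."""
    counts = counts or {"GAF": 5, "PHO": 5}
    plans = {
        "cre": PlantingPlan(counts, "clustered", cluster_width),
        "dummy-cre": PlantingPlan(counts, "uniform"),
        "dummy-genomic": None,
    }
    return make_planted_cre_set(
        MarkovModel.uniform(0), PRE_MOTIFS, plans, n_per_class, length, seed
    )


@pytest.fixture(scope="session")
def small_planted():
    seqs, truth = planted_dataset(seed=11, n_per_class=25)
    return seqs, truth


@pytest.fixture(scope="session")
def fitted_mocca(small_planted):
    """A small fitted RF-MOCCA used by scoring and core-CRE tests."""
    seqs, _ = small_planted
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return MoccaClassifier(
            motifs=PRE_MOTIFS,
            base="rf",
            positive_label="cre",
            n_trees=60,
            random_state=7,
        ).fit(seqs)
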