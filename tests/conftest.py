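import numpy as np
import pytest

from ilsom.datatypes import (
    KIND_METABOLITE,
    KIND_TRANSCRIPT,
    Pattern,
    ProfileDataset,
)
from ilsom import som as som_mod, synthetic
from ilsom.preprocess import augment_inverted


def make_dataset(values, kinds=None, genotypes=None, entity_ids=None, augment=True):
    """Build a small dataset from a (n_entities, P) array of profiles."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    kinds = kinds or [KIND_TRANSCRIPT] * n
    genotypes = genotypes or [f"IL_{i + 1}" for i in range(p)]
    entity_ids = entity_ids or [f"e{i + 1}" for i in range(n)]
    patterns = [
        Pattern(entity_id=e, kind=k, values=v)
        for e, k, v in zip(entity_ids, kinds, values)
    ]
    dataset = ProfileDataset(genotypes=genotypes, patterns=patterns)
    return augment_inverted(dataset) if augment else dataset


@pytest.fixture(scope="session")
def trained():
    """A small trained synthetic map shared by analysis/viz tests."""
    spec = synthetic.SynthSpec(
        p=21, n_transcripts=60, n_metabolites=16, g=4, seed=11,
        missing_rate=0.03,
    )
    dataset, truth = synthetic.generate_dataset(spec)
    som, assignment = som_mod.train_batch(
        dataset, som_mod.SomConfig(rows=8, cols=8, n_epochs=30, seed=11)
    )
    return dataset, truth, som, assignment
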