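import numpy as np
import pytest

from hcpl import pipeline, synth


@pytest.fixture(scope="session")
def small_manifest():
    """A small but full-featured dataset shared by structural tests."""
    return synth.generate_dataset(synth.SynthConfig(n_images=12, rng_seed=7))


@pytest.fixture(scope="session")
def small_table(small_manifest):
    return pipeline.build_cell_table(small_manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def reference_runs():
    """Reference benchmark manifests (200 images x 12 cells, C=6,
    imbalanced, union weak labels) with cell tables and image splits,
    for seeds 0-2. Shared by the end-to-end tests."""
    runs = {}
    for seed in (0, 1, 2):
        manifest = synth.generate_dataset(synth.reference_config(seed=seed))
        table = pipeline.build_cell_table(manifest)
        train_ids, val_ids = pipeline.split_images(manifest, 0.25, seed=seed)
        runs[seed] = dict(manifest=manifest, table=table,
                          train_ids=train_ids, val_ids=val_ids)
    return runs
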