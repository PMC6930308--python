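import numpy as np
import pytest

import nirleaf as nl


@pytest.fixture(scope="session")
def small_gen_config():
    """Reduced dried design for fast structural tests: 6 classes x 10 leaves
    (5 trees), 2 replicates, 8 cm^-1 steps."""
    return nl.GeneratorConfig(
        sample_type="dried",
        n_trees_per_class=5,
        n_leaves_per_class=10,
        n_replicates=2,
        axis_step=8.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_spectra(small_gen_config):
    return nl.generate(small_gen_config)


@pytest.fixture(scope="session")
def small_leaves(small_gen_config):
    return nl.average_replicates(nl.generate(small_gen_config))


@pytest.fixture(scope="session")
def dried_default_run(tmp_path_factory):
    """One full default dried study run (seed 1), shared across tests."""
    out = tmp_path_factory.mktemp("dried_run")
    config = nl.PipelineConfig(sample_type="dried", seed=1,
                               out_dir=str(out), write_spectra_csv=False)
    return nl.run_all(config)


@pytest.fixture(scope="session")
def separable_spectra():
    """Two far-apart classes: trivially separable fixture for PLS-DA."""
    rng = np.random.default_rng(0)
    n_per, p = 12, 30
    axis = np.arange(p, dtype=float)[::-1]
    base = rng.normal(0, 0.05, size=(2 * n_per, p))
    base[:n_per, :10] += 5.0
    base[n_per:, 10:20] += 5.0
    return nl.SpectraSet(
        values=base,
        axis=axis,
        labels=np.array(["A"] * n_per + ["B"] * n_per),
        sample_id=np.array([f"s{i}" for i in range(2 * n_per)]),
        sample_type="dried",
        kind="derivative",
    )
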