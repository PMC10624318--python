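import numpy as np
import pytest

from callopt import dataset, synthetic


@pytest.fixture(scope="session")
def table():
    return dataset.load_packaged_table()


@pytest.fixture(scope="session")
def replicates(table):
    """One reconstruction of the 231 vessels at a fixed seed."""
    return synthetic.reconstruct_replicates(table, n_reps=7, explants_per_vessel=4, seed=1)


@pytest.fixture(scope="session")
def dense_surface():
    """Noiseless Gaussian surface sampled on a dense 4-D grid, with truth."""
    spec = synthetic.SurfaceSpec(
        optimum=(1.3, 1.0, 1.4, 1.7),
        peak_cfr=95.0,
        peak_cfw=1.8,
        widths=(0.8, 0.8, 0.8, 0.8),
        noise_sd_cfr=0.0,
        noise_sd_cfw=0.0,
    )
    axes = np.linspace(0.0, 2.0, 7)
    design = np.array(np.meshgrid(*[axes] * 4)).reshape(4, -1).T
    reps, _ = synthetic.simulate_surface(spec, design, n_reps=1, seed=0)
    return reps, spec
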