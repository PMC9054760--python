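import numpy as np
import pytest

from mfskit import synthetic


@pytest.fixture(scope="session")
def bundle_and_map():
    spec = synthetic.BundleSpec(seed=11)
    return synthetic.build_two_state_bundle(spec)


@pytest.fixture(scope="session")
def state_ensembles():
    """20 noisy outward-facing and 20 inward-facing bundles (sigma 0.3 A)."""
    of_spec = synthetic.BundleSpec(state_param=0.0, seed=21)
    if_spec = synthetic.BundleSpec(state_param=1.0, seed=22)
    ofs = synthetic.generate_state_ensemble(of_spec, 20, 0.3)
    ifs = synthetic.generate_state_ensemble(if_spec, 20, 0.3)
    _, cmap = synthetic.build_two_state_bundle(of_spec)
    return ofs, ifs, cmap


@pytest.fixture(scope="session")
def fitted_space(state_ensembles):
    from mfskit import confspace

    ofs, ifs, cmap = state_ensembles
    labels = ["OF"] * len(ofs) + ["IF"] * len(ifs)
    return confspace.fit_space_from_structures(ofs + ifs, labels, cmap), cmap


@pytest.fixture(scope="session")
def two_gaussian_samples():
    """5000 draws from a 0.7/0.3 mixture of well-separated isotropic
    Gaussians (sigma 0.5, means (0,0) and (5,5))."""
    rng = np.random.default_rng(42)
    n = 5000
    pick = rng.random(n) < 0.7
    a = rng.normal([0.0, 0.0], 0.5, (n, 2))
    b = rng.normal([5.0, 5.0], 0.5, (n, 2))
    return np.where(pick[:, None], a, b), pick
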