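import numpy as np
import pytest

import knotfiber as kf


@pytest.fixture(scope="session")
def params_047():
    return kf.ModelParams.from_ratio(n_beads=25, dl_ratio=0.47)


@pytest.fixture(scope="session")
def ens_047_20k(params_047):
    """Workhorse classified + writhe-annotated ensemble at D/L = 0.47."""
    ens = kf.sample_ensemble(params_047, 20_000, seed=1)
    kf.classify_ensemble(ens, seed=2)
    kf.annotate_writhe(ens)
    return ens


@pytest.fixture(scope="session")
def ens_small(params_047):
    """Small unannotated ensemble for cheap structural tests."""
    return kf.sample_ensemble(params_047, 500, seed=7)


@pytest.fixture(scope="session")
def fixture_curves():
    kinds = {k: (80 if k == "figure_eight" else 60)
             for k in kf.FIXTURE_KNOTS}
    return {k: kf.make_fixture(k, n_vertices=n) for k, n in kinds.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
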