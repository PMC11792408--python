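import numpy as np
import pytest

from tlsscape.phenotyping import assign_phenotypes, load_registry
from tlsscape.simulate import TissueSimConfig, simulate_slide


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def small_tissue_config():
    """A compact slide: 3×3 mm window, 1 mm tumour, one TLS per zone."""
    return TissueSimConfig(
        seed=7,
        slide_extent_um=(3000.0, 3000.0),
        tumour_radius_um=1000.0,
        im_band_halfwidth_um=500.0,
        n_tls={"TC": 1, "IM": 1, "N": 1},
        tls_diameter_um=(250.0, 350.0),
    )


@pytest.fixture(scope="session")
def slide_dataset(small_tissue_config, registry):
    """One simulated slide with phenotype memberships assigned."""
    ds = simulate_slide(small_tissue_config, slide_id="S1", patient_id="P1")
    ds.memberships = assign_phenotypes(ds.cells, registry)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
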