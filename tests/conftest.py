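import numpy as np
import pytest

from dtialps import (
    compute_alps,
    default_gradient_table,
    default_phantom_spec,
    derive_maps,
    fit_tensor_loglinear,
    generate_phantom_dwi,
)


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


@pytest.fixture(scope="session")
def phantom_pipeline(gtab):
    """Noise-free phantom at g=0.5 run through fit -> maps -> ALPS."""
    spec = default_phantom_spec(g=0.5, noise_sigma=0.0)
    dwi, truth, rois = generate_phantom_dwi(spec, gtab)
    field = fit_tensor_loglinear(dwi, gtab)
    maps = derive_maps(field)
    result = compute_alps(maps, rois)
    return {"spec": spec, "dwi": dwi, "truth": truth, "rois": rois,
            "field": field, "maps": maps, "result": result}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
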