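import dataclasses

import pytest

from nfmri.phantom import PhantomSpec, build_phantom

# Two-slice phantom with proportionally scaled infarct/no-flow targets: the
# per-slice geometry is identical to the full-size reperfused phantom, so
# segmentation behaviour carries over at a third of the cost.
SMALL_NF_CURVE = {2.0: 2.57, 10.0: 2.54, 15.0: 2.51, 20.0: 2.07, 25.0: 1.73,
                  30.0: 1.40, 35.0: 1.07, 40.0: 0.83, 45.0: 0.61}


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec.reperfused(
        n_slices=2,
        target_mi_volume_ml=5.7,
        nf_volume_ml_by_time=dict(SMALL_NF_CURVE),
    )


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def quiet_truth(small_spec):
    """Same geometry, noiseless renders."""
    spec = dataclasses.replace(small_spec, noise_model="none")
    return build_phantom(spec)
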