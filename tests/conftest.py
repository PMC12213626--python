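import pytest

from retoct import segmentation as seg_mod
from retoct.phantom import DegenerationModel, PhantomParams, make_profile, render_bscan


@pytest.fixture(scope="session")
def model():
    return DegenerationModel.default()


@pytest.fixture(scope="session")
def day0_noise_free(model):
    params = PhantomParams(speckle_shape=None)
    bscan, truth = render_bscan(make_profile(params, model, 0.0), params, seed=1)
    return bscan, truth


@pytest.fixture(scope="session")
def day0_speckled(model):
    params = PhantomParams()
    bscan, truth = render_bscan(make_profile(params, model, 0.0), params, seed=7)
    return bscan, truth


@pytest.fixture(scope="session")
def day0_segmentation(day0_noise_free):
    bscan, _ = day0_noise_free
    return seg_mod.segment(bscan, "normal")


def boundary_errors(seg, truth):
    """Per-boundary error arrays over jointly valid A-scans."""
    both = seg.valid_mask & truth.valid_mask
    return seg.boundaries[:, both] - truth.boundaries[:, both]
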