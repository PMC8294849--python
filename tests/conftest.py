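import numpy as np
import pytest

from mitonet import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_morph():
    """Small random reconstruction used across morphometry tests."""
    return synthetic.gen_morphology(n_branch_axon=3, n_branch_dend=2,
                                    segment_len=12.0, seed=11)


@pytest.fixture(scope="session")
def mito_scene():
    """Matched (morphology, mito stack, volume mask) triple on one grid."""
    from mitonet import morphometry

    morph = synthetic.gen_morphology(2, 2, segment_len=10.0, seed=21)
    stack, truth = synthetic.gen_mito_stack(morph, n_mito=40, voxel_size=0.5,
                                            psf_sigma=0.3, seed=21)
    mask = morphometry.fill_volume_mask(morph, 0.5, origin=stack.origin,
                                        shape=stack.shape)
    return morph, stack, truth, mask
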