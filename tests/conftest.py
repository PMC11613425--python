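import numpy as np
import pytest

from multicca import MultiViewDataset, SyntheticConfig, generate_multiview


@pytest.fixture(scope="session")
def planted_dataset():
    """Mid-size 4-view dataset with the default planted structure."""
    cfg = SyntheticConfig(n_subjects=2000, seed=11)
    return generate_multiview(cfg)


@pytest.fixture(scope="session")
def planted_dataset_no_shift():
    """Same design with the group effect switched off (clean latents)."""
    cfg = SyntheticConfig(n_subjects=2000, group_effect=(0, 0, 0, 0), seed=11)
    return generate_multiview(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_noise_dataset(n=400, dims=(8, 8, 5), seed=0) -> MultiViewDataset:
    """Views with no shared structure (fidelity 0)."""
    cfg = SyntheticConfig(n_subjects=n, view_dims=dims, n_components=2,
                          latent_fidelity=0.0, group_effect=(0, 0),
                          cognition_effect=0.0, seed=seed)
    return generate_multiview(cfg)[0]
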