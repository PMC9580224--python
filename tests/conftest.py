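import numpy as np
import pytest

from perceptstrain.approach2 import TrainingSet
from perceptstrain.kernels import GridGeometry, Jacobian
from perceptstrain.metric import tiled_distance
from perceptstrain.synthetic import ObserverModel, degrade, gen_images, simulate_ratings


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def image_pair(rng):
    """Random 8x8 pair in [0, 1] luminance."""
    return rng.random((8, 8)), rng.random((8, 8))


@pytest.fixture(scope="session")
def sparse_tile_jacobian():
    """Identity plus short-range couplings at multiples of 0.1 (8x8 tile)."""
    geom = GridGeometry(8, 8)
    d = geom.pairwise_distances()
    P = np.eye(64)
    P[np.isclose(d, 1.0)] = 0.3
    P[np.isclose(d, 2.0)] = -0.2
    np.fill_diagonal(P, 1.0)
    return Jacobian(P, geom)


def degraded_training_set(distance_fn, n_refs=25, size=(16, 16), seed=11,
                          link="affine", noise_sd=0.0, obs_seed=3):
    """Reference images x four quality tiers, rated by a simulated observer."""
    imgs = gen_images(n_refs, size=size, correlation_scale=1.5, seed=seed)
    pairs, refs, cats = [], [], []
    for i, im in enumerate(imgs):
        for q in (30, 20, 10, 5):
            pairs.append((im, degrade(im, q)))
            refs.append(f"r{i:03d}")
            cats.append(f"c{i % 2}")
    model = ObserverModel(distance_fn=distance_fn, link=link,
                          rater_noise_sd=noise_sd, seed=obs_seed)
    ratings = simulate_ratings(pairs, model)
    dmos = ratings.groupby("image_id", sort=False)["dmos"].mean().to_numpy()
    return TrainingSet(pairs, dmos, categories=cats, reference_ids=refs)


@pytest.fixture(scope="session")
def tile_training_set(sparse_tile_jacobian):
    """100 pairs whose DMOS comes from the sparse ground-truth tile Jacobian."""
    return degraded_training_set(
        lambda a, b: tiled_distance(a, b, sparse_tile_jacobian)
    )
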