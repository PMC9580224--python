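"""Shared builders for sweep/fit recovery experiments."""

import numpy as np

from perceptstrain.approach2 import TrainingSet
from perceptstrain.kernels import DOGParams, GaussianParams, build_stencil
from perceptstrain.metric import convolutional_distance
from perceptstrain.synthetic import ObserverModel, degrade, gen_images, simulate_ratings


def kernel_training_set(rng_seed=5, n_refs=16, size=(32, 32), sigma=None,
                        dog=None, obs_seed=9):
    """Images x quality tiers rated by an observer with a known kernel.

    Exactly one of ``sigma`` (Gaussian) or ``dog`` ((center, surround,
    alpha)) selects the ground-truth connectivity; the observer link is the
    noiseless affine-in-d^2 map, so the generating kernel achieves (near)
    perfect correlation and parameter recovery is identifiable.
    """
    kernel = GaussianParams(sigma) if sigma is not None else DOGParams(*dog)
    stencil = build_stencil(kernel)
    imgs = gen_images(n_refs, size=size, correlation_scale=1.5, seed=rng_seed)
    pairs, refs, cats = [], [], []
    for i, im in enumerate(imgs):
        for q in (30, 20, 10, 5):
            pairs.append((im, degrade(im, q)))
            refs.append(f"r{i:03d}")
            cats.append(f"c{i % 2}")
    model = ObserverModel(
        distance_fn=lambda a, b: convolutional_distance(a, b, stencil),
        link="affine", seed=obs_seed,
    )
    ratings = simulate_ratings(pairs, model)
    dmos = ratings.groupby("image_id", sort=False)["dmos"].mean().to_numpy()
    return TrainingSet(pairs, dmos, categories=cats, reference_ids=refs)
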