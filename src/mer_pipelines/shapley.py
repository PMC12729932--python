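"""Shapley additive feature attributions by permutation sampling.

Attributions explain a scalar model output f(x) relative to a single
reference vector (here: the training-fold feature mean).  For a random
permutation of the features, each feature's marginal contribution is the
change in f when that feature's value is switched from the reference to
the explained point, given the features before it in the permutation have
already been switched; the Shapley value is the average contribution over
permutations.  Contributions telescope, so for every sampled permutation
the attributions sum exactly to f(x) - f(reference) (the additivity
property), and for a linear f the estimator is exact with any number of
permutations.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["shapley_values"]


def shapley_values(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    reference: np.ndarray,
    n_permutations: int = 12,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Permutation-sampling Shapley attributions.

    Parameters
    ----------
    predict
        Maps an (n, p) array to n scalar outputs (probability of the
        positive class or a decision value).
    X
        Points to explain, shape (n, p).
    reference
        Baseline feature vector, shape (p,).
    n_permutations
        Sampled feature orderings; the estimator is exact for linear
        models with any value >= 1.
    rng
        Seed or generator for the permutation draws.

    Returns
    -------
    ndarray of shape (n, p): per-point, per-feature attributions.
    """
    X = np.asarray(X, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if X.ndim != 2 or reference.shape != (X.shape[1],):
        raise ValueError("X must be (n, p) and reference (p,)")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    n, p = X.shape
    rng = np.random.default_rng(rng)
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        # states[s] = points with the first s features (in perm order)
        # switched from the reference to their explained values
        cur = np.repeat(reference[None, :], n, axis=0)
        states = np.empty((p + 1, n, p))
        states[0] = cur
        for s, j in enumerate(perm, start=1):
            cur[:, j] = X[:, j]
            states[s] = cur
        f = np.asarray(predict(states.reshape(-1, p)), dtype=float).reshape(p + 1, n)
        contrib = f[1:] - f[:-1]  # (p, n), in perm order
        phi[:, perm] += contrib.T
    return phi / n_permutations
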