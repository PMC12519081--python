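"""Shared test utilities: independent oracles and random-matrix factories."""

from __future__ import annotations

import numpy as np

from hoinfo.gaussian import CovarianceModel


def random_pd_cov(rng: np.random.Generator, k: int,
                  names: list[str] | None = None) -> CovarianceModel:
    """A well-conditioned random positive-definite covariance model."""
    a = rng.standard_normal((k, k + 3))
    sigma = a @ a.T / (k + 3) + 0.2 * np.eye(k)
    if names is None:
        names = [f"v{i}" for i in range(k)]
    return CovarianceModel(sigma, names, n_samples=1000)


def ari_pair_oracle(a, b) -> float:
    """Adjusted Rand index by brute-force enumeration of all item pairs.

    Counts pairs co-clustered in both partitions (n11) and the marginal
    co-clustered pair counts, then applies the permutation-model
    adjustment: (index - expected) / (max - expected).
    """
    a = list(a)
    b = list(b)
    n = len(a)
    n11 = same_a = same_b = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            same_a += sa
            same_b += sb
            n11 += sa and sb
    expected = same_a * same_b / total
    maximum = 0.5 * (same_a + same_b)
    if maximum == expected:  # both partitions trivial (all-same or all-diff)
        return 1.0 if same_a == same_b else 0.0
    return (n11 - expected) / (maximum - expected)


def block_se(values: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean of per-block estimates."""
    blocks = np.array_split(values, n_blocks)
    means = np.array([np.mean(b) for b in blocks])
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
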