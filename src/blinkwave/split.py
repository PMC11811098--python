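"""Seeded train/validation/test splitting with largest-remainder rounding."""

from __future__ import annotations

import numpy as np

__all__ = ["split_sizes", "three_way_split"]


def split_sizes(n: int, ratio: tuple[int, int, int] = (8, 1, 1)) -> tuple[int, int, int]:
    """Partition ``n`` items by ``ratio`` using largest-remainder rounding.

    Guarantees the sizes sum to ``n``; all three sets are non-empty whenever
    each ratio share amounts to at least one item (e.g. n >= 10 at 8:1:1).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    total = sum(ratio)
    exact = [n * r / total for r in ratio]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # largest remainder first
    for i in range(rem):
        base[order[i]] += 1
    return tuple(base)  # type: ignore[return-value]


def three_way_split(
    n: int,
    ratio: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shuffled index arrays (train, val, test) of largest-remainder sizes."""
    n_tr, n_va, n_te = split_sizes(n, ratio)
    perm = rng.permutation(n)
    return perm[:n_tr], perm[n_tr : n_tr + n_va], perm[n_tr + n_va :]
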