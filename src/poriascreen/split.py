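"""Train/test selection: deterministic Kennard-Stone and seeded random holdout."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from poriascreen._seeds import stream


@dataclass
class SplitResult:
    """Disjoint train/test index lists covering 0..n-1."""

    train_ids: list[int]
    test_ids: list[int]
    fraction: float
    method: str

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    @property
    def n(self) -> int:
        return len(self.train_ids) + len(self.test_ids)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def kennard_stone_split(X: np.ndarray, train_fraction: float) -> SplitResult:
    """Max-min Euclidean (Kennard-Stone) selection of a representative train set.

    Start from the two mutually farthest records; repeatedly add the record
    whose minimum distance to the selected set is largest; stop at
    round-half-up(n * train_fraction). All ties break to the lowest original
    index, so the selection is fully deterministic. 100 records at fraction
    2/3 give the conventional 67 train / 33 test partition.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 records")
    if not (0 < train_fraction <= 1):
        raise ValueError("train_fraction must be in (0, 1]")
    k = n if train_fraction == 1.0 else _round_half_up(n * train_fraction)
    k = max(2, min(k, n))

    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    np.maximum(d2, 0, out=d2)

    # seed pair: maximum pairwise distance, lowest (i, j) on ties
    flat = np.round(d2, 12)  # guard float jitter in tie comparison
    best = np.unravel_index(np.argmax(flat), flat.shape)  # argmax -> lowest flat idx
    i0, j0 = int(min(best)), int(max(best))
    selected = [i0, j0]
    mind = np.minimum(d2[i0], d2[j0])
    mind[selected] = -np.inf
    while len(selected) < k:
        nxt = int(np.argmax(np.round(mind, 12)))  # argmax takes lowest index on ties
        selected.append(nxt)
        mind = np.minimum(mind, d2[nxt])
        mind[nxt] = -np.inf
    train = selected[:k]
    test = [i for i in range(n) if i not in set(train)]
    return SplitResult(train, test, train_fraction, "kennard_stone")


def random_holdout(n: int, holdout_fraction: float, seed: int) -> SplitResult:
    """Seeded uniform holdout without replacement.

    ``test_ids`` receives round-half-up(n * holdout_fraction) records; the
    remainder trains. 200 samples at 10% give the conventional 20-sample
    external-verification set.
    """
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must be in (0, 1)")
    h = _round_half_up(n * holdout_fraction)
    if h == 0 or h == n:
        raise ValueError(f"holdout of {h} from {n} leaves an empty partition")
    rng = stream(seed, "random-holdout")
    test = sorted(int(i) for i in rng.choice(n, size=h, replace=False))
    train = [i for i in range(n) if i not in set(test)]
    return SplitResult(train, test, 1 - holdout_fraction, "random")
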