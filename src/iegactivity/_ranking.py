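"""Shared rank-and-bin helpers used by module scoring, HVG selection and
background-interval construction."""

from __future__ import annotations

import numpy as np
import pandas as pd


def split_near_equal(n: int, k: int) -> list[int]:
    """Sizes of ``k`` near-equal contiguous chunks of ``n`` items.

    Earlier chunks absorb the remainder: ``split_near_equal(7, 3) == [3, 2, 2]``.
    """
    if k < 1:
        raise ValueError("number of chunks must be >= 1")
    if k > n:
        raise ValueError(f"cannot split {n} items into {k} non-empty chunks")
    base, rem = divmod(n, k)
    return [base + 1 if i < rem else base for i in range(k)]


def rank_order(values: pd.Series) -> list[str]:
    """Item labels sorted by ascending value, ties broken lexicographically by label."""
    df = pd.DataFrame({"v": values.to_numpy(), "g": values.index.astype(str)})
    df = df.sort_values(["v", "g"], kind="mergesort")
    return df["g"].tolist()


def rank_bins(values: pd.Series, n_bins: int) -> pd.Series:
    """Assign each item to one of ``n_bins`` rank intervals of near-equal size.

    Items are ranked ascending by value (lexicographic tie-break) and the rank
    range is cut into contiguous intervals; earlier intervals absorb the
    remainder. Returns bin index (0-based) per item label.
    """
    order = rank_order(values)
    sizes = split_near_equal(len(order), n_bins)
    bins = np.repeat(np.arange(n_bins), sizes)
    return pd.Series(bins, index=order, name="bin")
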