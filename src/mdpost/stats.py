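"""Block-average error estimation for correlated time series.

Uncertainties of means over MD-like (autocorrelated) series are estimated by
splitting the series into contiguous blocks and using the spread of the block
means.  This is the single error estimator shared by the contact, energy and
NOE analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BlockAverageResult", "block_average", "DEFAULT_N_BLOCKS"]

#: default number of blocks; the blocking choice is recorded in every report
DEFAULT_N_BLOCKS = 5


@dataclass(frozen=True)
class BlockAverageResult:
    mean: float
    error: float
    n_blocks: int
    block_means: np.ndarray


def block_average(series, n_blocks: int = DEFAULT_N_BLOCKS) -> BlockAverageResult:
    """Mean and block-average standard error of a series.

    The series is split into ``n_blocks`` contiguous near-equal blocks (any
    remainder is spread over the leading blocks).  The error is the sample
    standard deviation of the block means divided by sqrt(n_blocks).

    Raises ``ValueError`` if the series is shorter than ``n_blocks`` or
    ``n_blocks`` < 2.
    """
    x = np.asarray(series, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if x.size < n_blocks:
        raise ValueError(f"series of length {x.size} cannot be split into {n_blocks} blocks")
    blocks = np.array_split(x, n_blocks)  # remainder goes to leading blocks
    bm = np.array([b.mean() for b in blocks])
    err = float(bm.std(ddof=1) / np.sqrt(n_blocks))
    return BlockAverageResult(mean=float(x.mean()), error=err, n_blocks=n_blocks, block_means=bm)
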