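"""Finite-population sample-size computation and random grid selection.

The validation fieldwork audits a simple random sample of grid cells.
The sample size follows the classical finite-population-corrected
(Cochran) formula for estimating a proportion: with population size N,
expected proportion p, absolute margin of error e and two-sided normal
quantile z for the confidence level,

    n = ceil( N z^2 p(1-p) / ( e^2 (N-1) + z^2 p(1-p) ) ),

capped at N.  At p = 0.5, e = 0.05 and 95% confidence this yields 301
cells out of a 1375-cell frame (and 385 in the infinite-population
limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geo_grid import GridSet


@dataclass(frozen=True)
class SampleSizeSpec:
    N: int
    p: float
    e: float
    conf: float
    z: float
    n: int


def sample_size_finite(N: int, p: float = 0.5, e: float = 0.05, conf: float = 0.95) -> SampleSizeSpec:
    """Sample size for a proportion under simple random sampling without
    replacement from a finite frame of N units; ceil-rounded, capped at N."""
    if N < 1:
        raise ValueError("population size N must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError("expected proportion p must lie in (0, 1)")
    if not 0.0 < e < 1.0:
        raise ValueError("margin of error e must lie in (0, 1)")
    if not 0.0 < conf < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    z = float(stats.norm.ppf(0.5 + conf / 2.0))
    zpq = z * z * p * (1.0 - p)
    n = math.ceil(N * zpq / (e * e * (N - 1) + zpq))
    n = min(max(n, 1), N)
    return SampleSizeSpec(N=N, p=p, e=e, conf=conf, z=z, n=n)


def draw_sample(grid: GridSet, n: int, seed: int) -> list[str]:
    """Simple random sample of n cell ids without replacement, seeded."""
    ids = grid.cell_ids()
    if not 1 <= n <= len(ids):
        raise ValueError(f"sample size {n} outside [1, {len(ids)}]")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return [ids[i] for i in sorted(chosen)]
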