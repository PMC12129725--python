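"""Bayesian group contrasts via highest-density intervals.

Groups are fitted independently, so their posterior draws are exchangeable;
a seeded pairing of draws yields the posterior of the group difference,
summarized by its 95% HDI.  A difference is called significant when the
interval excludes zero.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchy import PosteriorDraws
from .models import InvalidDataError

__all__ = ["HdiComparison", "hdi", "group_difference", "contrast_table"]


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    if not np.all(np.isfinite(x)):
        raise InvalidDataError("draws must be finite")
    n = x.size
    if not (0.0 < mass < 1.0):
        raise InvalidDataError(f"mass must be in (0,1), got {mass}")
    if n < max(2, int(np.ceil(1.0 / (1.0 - mass)))):
        raise InvalidDataError(f"too few draws ({n}) to resolve a {mass:.0%} interval")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass(frozen=True)
class HdiComparison:
    """HDI contrast of one parameter between two groups (A - B)."""

    parameter: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    lower95: float
    upper95: float
    significant: bool

    def __post_init__(self) -> None:
        assert self.lower95 <= self.upper95


def _side_permutation(draws: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Permutation derived from the draws' own fingerprint, so that the
    pairing of a side does not depend on which argument slot it occupies
    (this makes group_difference(A, B) exactly -group_difference(B, A))."""
    tag = zlib.crc32(np.ascontiguousarray(draws).tobytes()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), tag]))
    perm = rng.permutation(draws.size)
    if draws.size > n:
        perm = perm[:n]
    return perm


def group_difference(
    draws_a: PosteriorDraws,
    draws_b: PosteriorDraws,
    parameter: str,
    seed: int = 0,
    mass: float = 0.95,
) -> HdiComparison:
    """HDI of the between-group difference of a population parameter.

    The difference is taken on the constrained scale between the two
    groups' population-mean draws after a seeded shuffle of each side
    (independent fits make any pairing exchangeable; seeding makes it
    reproducible).  Unequal draw counts are handled by subsampling the
    larger side.
    """
    a = draws_a.population_mean_draws(parameter)
    b = draws_b.population_mean_draws(parameter)
    if a.size < 100 or b.size < 100:
        raise InvalidDataError("need >= 100 draws per group")
    n = min(a.size, b.size)
    pa = _side_permutation(a, n, seed)
    pb = _side_permutation(b, n, seed)
    diff = a[pa] - b[pb]
    lo, hi = hdi(diff, mass)
    sig = not (lo <= 0.0 <= hi)

    def _msd(d: PosteriorDraws, pop: np.ndarray) -> tuple[float, float]:
        if parameter in d.param_names:
            return float(pop.mean()), float(d.population_sd_draws(parameter).mean())
        return float(pop.mean()), float("nan")

    ma, sa = _msd(draws_a, a)
    mb, sb = _msd(draws_b, b)
    return HdiComparison(parameter, ma, sa, mb, sb, lo, hi, sig)


def contrast_table(comparisons: list[HdiComparison]) -> pd.DataFrame:
    """Contrast table mirroring the group-comparison layout: per-group
    mean (SD), lower/upper 95% HDI of the difference, significance mark."""
    return pd.DataFrame({
        "parameter": [c.parameter for c in comparisons],
        "group_a_mean": [c.mean_a for c in comparisons],
        "group_a_sd": [c.sd_a for c in comparisons],
        "group_b_mean": [c.mean_b for c in comparisons],
        "group_b_sd": [c.sd_b for c in comparisons],
        "lower95_hdi": [c.lower95 for c in comparisons],
        "upper95_hdi": [c.upper95 for c in comparisons],
        "significant": ["*" if c.significant else "" for c in comparisons],
    })
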