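"""Out-of-sample predictive model comparison.

Models are scored by the expected log pointwise predictive density (ELPD)
estimated with Pareto-smoothed importance sampling leave-one-out
cross-validation (PSIS-LOO); LOOIC = -2 * ELPD.  Pairs of models are
compared by the ELPD difference, its standard error computed from the
pointwise-difference vector, and the "sigma effect" (difference / SE), a
heuristic for the significance of the difference.  The pointwise unit is
the trial, pooled across the subjects of a group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import InvalidDataError

__all__ = ["LooResult", "ComparisonRow", "psis_loo", "compare", "sigma_effect", "comparison_table"]


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO score for one model on one set of points."""

    elpd_loo: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray
    p_loo: float
    high_k_warning: bool
    model_id: int | None = None

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def n_points(self) -> int:
        return int(self.pointwise_elpd.shape[0])


def psis_loo(
    pointwise_loglik: np.ndarray,
    chain: np.ndarray | None = None,
    model_id: int | None = None,
) -> LooResult:
    """PSIS-LOO from a (draws x points) pointwise log-likelihood matrix.

    Importance ratios are Pareto-smoothed (generalized-Pareto tail fit on
    the largest ratios); points with shape diagnostic k > 0.7 are unreliable
    and flagged when they exceed 10% of points.
    """
    import arviz as az

    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise InvalidDataError("pointwise_loglik must be draws x points")
    if not np.all(np.isfinite(ll)):
        raise InvalidDataError("pointwise log-likelihood contains non-finite values")
    if ll.shape[0] < 100:
        raise InvalidDataError(f"need >= 100 draws for PSIS-LOO, got {ll.shape[0]}")

    if chain is None:
        arr = ll[None]                                   # (1, draws, points)
    else:
        chain = np.asarray(chain)
        ids = np.unique(chain)
        per = min(int((chain == c).sum()) for c in ids)
        arr = np.stack([ll[chain == c][:per] for c in ids])
    idata = az.from_dict(
        posterior={"dummy": np.zeros(arr.shape[:2])},
        log_likelihood={"obs": arr},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    k = np.asarray(res.pareto_k.values, dtype=float)
    loo_i = np.asarray(res.loo_i.values, dtype=float)
    # a point whose log-likelihood is constant across draws has zero weight
    # variance: its LOO density is that constant and its tail is trivial
    const = ll.max(axis=0) - ll.min(axis=0) < 1e-12
    if const.any():
        loo_i = np.where(const, ll.mean(axis=0), loo_i)
        k = np.where(const, 0.0, k)
    frac_high = float(np.mean(k > 0.7))
    return LooResult(
        elpd_loo=float(np.sum(loo_i)),
        pointwise_elpd=loo_i,
        pareto_k=k,
        p_loo=float(res.p_loo),
        high_k_warning=frac_high > 0.10,
        model_id=model_id,
    )


def sigma_effect(elpd_diff: float, se_diff: float) -> float:
    """ELPD difference divided by its standard error (NaN for the best model)."""
    if se_diff == 0.0:
        return float("nan")
    return elpd_diff / se_diff


@dataclass(frozen=True)
class ComparisonRow:
    """One model's line in the comparison table (best model first)."""

    model_id: int | None
    elpd_loo: float
    elpd_diff: float
    se_diff: float
    sigma: float
    looic: float
    is_best: bool


def compare(loo_results: list[LooResult]) -> list[ComparisonRow]:
    """Rank models by ELPD and compute pairwise differences vs the best.

    The SE of each difference comes from the pointwise-difference vector:
    se = sqrt(n * var(d_i)).  All models must be scored on identical points
    in identical order.  Output is sorted by LOOIC ascending and invariant
    to the input ordering.
    """
    if not loo_results:
        return []
    n = loo_results[0].n_points
    for r in loo_results:
        if r.n_points != n:
            raise InvalidDataError(
                f"models scored on different point counts: {r.n_points} vs {n}")
    order = sorted(range(len(loo_results)),
                   key=lambda i: (-loo_results[i].elpd_loo,
                                  loo_results[i].model_id if loo_results[i].model_id is not None else i))
    best = loo_results[order[0]]
    rows = []
    for i in order:
        r = loo_results[i]
        if r is best:
            rows.append(ComparisonRow(r.model_id, r.elpd_loo, 0.0, 0.0, float("nan"),
                                      r.looic, True))
            continue
        d = r.pointwise_elpd - best.pointwise_elpd
        diff = float(d.sum())
        se = float(np.sqrt(n * np.var(d, ddof=1)))
        rows.append(ComparisonRow(r.model_id, r.elpd_loo, diff, se,
                                  sigma_effect(diff, se), r.looic, False))
    return rows


def comparison_table(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison table with the study's column layout; the best model's
    sigma prints blank."""
    return pd.DataFrame({
        "model": [r.model_id for r in rows],
        "elpd_diff": [r.elpd_diff for r in rows],
        "se_diff": [r.se_diff for r in rows],
        "sigma_effect": ["" if r.is_best else r.sigma for r in rows],
        "looic": [r.looic for r in rows],
    })
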