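"""Design-based inference with jackknife replicate weights.

Standard errors come from a set of delete-one-group jackknife replicate
weights (JK1): the estimate is recomputed under each replicate weight
column and the spread of replicate estimates around the full-sample
estimate yields the variance, with coefficient (R−1)/R.  Scenario
differences are tested with two-sided t-tests on R−1 degrees of freedom,
pairing the scenarios on the shared replicate set (the default, since both
scenarios are computed on the same sample).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "ReplicateEstimates",
    "ScenarioComparison",
    "jackknife_se",
    "compare_scenarios",
    "weighted_proportion",
    "PropEstimate",
]


@dataclass(frozen=True)
class ReplicateEstimates:
    """A full-sample point estimate with its replicate-weight re-estimates."""

    estimate: float
    replicates: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "replicates", tuple(float(r) for r in self.replicates))
        if len(self.replicates) < 2:
            raise DataError("need at least 2 replicate estimates")
        if not all(np.isfinite(self.replicates)):
            raise DataError("replicate estimates must be finite")

    @property
    def R(self) -> int:
        return len(self.replicates)


def jackknife_se(rep: ReplicateEstimates) -> float:
    """JK1 standard error: sqrt( ((R−1)/R) · Σ_r (θ_r − θ̂)² )."""
    theta = np.asarray(rep.replicates)
    R = rep.R
    return float(np.sqrt((R - 1) / R * np.sum((theta - rep.estimate) ** 2)))


@dataclass(frozen=True)
class ScenarioComparison:
    difference: float
    se: float
    t: float
    p: float
    df: int


def compare_scenarios(
    current: ReplicateEstimates,
    modeled: ReplicateEstimates,
    *,
    paired: bool = True,
) -> ScenarioComparison:
    """Two-sided t-test of (modeled − current) on R−1 degrees of freedom.

    Paired (default): the jackknife is applied to the per-replicate
    differences, exploiting the correlation from the shared replicate-weight
    set.  Unpaired: the scenario SEs are combined as if independent.
    """
    if current.R != modeled.R:
        raise DataError(
            f"replicate counts differ: {current.R} vs {modeled.R}"
        )
    diff = modeled.estimate - current.estimate
    if paired:
        diffs = tuple(m - c for m, c in zip(modeled.replicates, current.replicates))
        se = jackknife_se(ReplicateEstimates(diff, diffs))
    else:
        se = float(np.hypot(jackknife_se(current), jackknife_se(modeled)))
    df = current.R - 1
    if se == 0.0:
        t = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return ScenarioComparison(difference=diff, se=se, t=float(t), p=p, df=df)


@dataclass(frozen=True)
class PropEstimate:
    percent: float
    se: float | None
    ci95: tuple[float, float] | None
    n_unweighted: int


def weighted_proportion(
    flags,
    weights,
    replicate_weights: np.ndarray | pd.DataFrame | None = None,
) -> PropEstimate:
    """Survey-weighted percentage with optional jackknife SE and 95% CI.

    ``flags``: boolean per person; ``weights``: positive analytic weights;
    ``replicate_weights``: optional (n × R) matrix.  The CI is the normal
    interval estimate ± 1.96·SE, clipped to [0, 100].
    """
    f = np.asarray(flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    if f.shape != w.shape:
        raise DataError("flags and weights must have the same length")
    if np.any(w <= 0):
        raise DataError("weights must be > 0")
    total = w.sum()
    if total <= 0:
        raise DataError("total weight is zero")
    pct = 100.0 * float(np.sum(w * f) / total)
    if replicate_weights is None:
        return PropEstimate(pct, None, None, int(len(f)))
    rw = np.asarray(replicate_weights, dtype=float)
    if rw.shape[0] != len(f):
        raise DataError("replicate weight matrix must have one row per person")
    col_tot = rw.sum(axis=0)
    if np.any(col_tot <= 0):
        raise DataError("each replicate weight column must have positive total")
    reps = 100.0 * (f @ rw) / col_tot
    se = jackknife_se(ReplicateEstimates(pct, tuple(reps)))
    lo = max(0.0, pct - 1.96 * se)
    hi = min(100.0, pct + 1.96 * se)
    return PropEstimate(pct, se, (lo, hi), int(len(f)))
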