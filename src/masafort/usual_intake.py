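"""Usual-intake estimation from one or two 24-hour recalls per person.

A single recall day is a noisy measurement of a person's usual (long-run
average) intake: observed day totals mix between-person variation (real
differences in usual intake) with within-person variation (day-to-day
fluctuation and reporting noise).  The percentage of a population whose
*usual* intake exceeds a cut-point is therefore not the percentage of
observed days above it; the within-person variance must be removed first.

The model here follows the classic measurement-error workflow for a single
daily-consumed nutrient:

1. choose a shifted power transformation (Box-Cox family including the log)
   that makes day intakes approximately normal, by minimizing the magnitude
   of the weighted skewness over a λ grid;
2. adjust transformed intakes for day-of-week and interview-mode effects by
   weighted least squares, re-centering to the reference level (weekday,
   in-person interview);
3. estimate the within-person variance from the half-differences of persons
   with two recall days, and the between-person variance from the variance
   of person means minus the within-person contribution;
4. scale each person's deviation from the weighted grand mean by the square
   root of the reliability ratio σ²_b / (σ²_b + σ²_w / dᵢ), so that the
   transformed-scale variance of the usual values equals σ²_b;
5. back-transform with a second-order bias adjustment for the nonlinear
   inverse transformation.

The usual-intake distribution is represented by the weighted empirical
distribution of the resulting per-person usual values, from which cut-point
exceedance percentages are read off directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, ModelError

__all__ = [
    "UsualIntakeModel",
    "ExceedanceEstimate",
    "fit_usual_intake",
    "update_intakes",
    "percent_above",
    "transform",
    "back_transform",
]

#: Default λ grid: −1 … 1 in steps of 0.05 (0 is the log transform).
DEFAULT_LAM_GRID = tuple(np.round(np.arange(-1.0, 1.0001, 0.05), 10))

#: Cells with fewer unweighted persons than this beyond the cut-point (but
#: more than zero) are flagged not-estimable: the empirical tail is too thin
#: for a stable estimate.
MIN_TAIL_PERSONS = 12


@dataclass
class ExceedanceEstimate:
    """Weighted percentage of usual intakes above a cut-point."""

    cutpoint_ug: float
    percent_above: float
    n_unweighted: int
    n_above_unweighted: int
    not_estimable: bool = False
    se: float | None = None
    ci95: tuple[float, float] | None = None


@dataclass
class UsualIntakeModel:
    """Fitted transformation, covariate effects and variance components.

    ``person_table`` has one row per person: ``person_id``, ``n_days``,
    ``mean_transformed`` (covariate-adjusted person mean on the transformed
    scale), ``shrink_factor`` (reliability ratio, in (0, 1], equal to 1 when
    the within-person variance is 0), ``usual_transformed`` and ``usual_ug``
    (back-transformed with bias adjustment).
    """

    lam: float
    shift: float
    scale: float
    covariate_effects: dict[str, float]
    sigma2_between: float
    sigma2_within: float
    grand_mean: float
    person_table: pd.DataFrame
    weights: pd.Series
    dow_levels: str = "weekend3"

    def summary_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "shift": self.shift,
            "scale": self.scale,
            "covariate_effects": dict(self.covariate_effects),
            "sigma2_between": self.sigma2_between,
            "sigma2_within": self.sigma2_within,
            "grand_mean_transformed": self.grand_mean,
            "n_persons": int(len(self.person_table)),
        }


def transform(y, lam: float, shift: float = 0.0, scale: float = 1.0):
    """Shifted, scaled power transform: t((y+shift)/scale); λ=0 is the log."""
    z = (np.asarray(y, dtype=float) + shift) / scale
    if np.any(z <= 0):
        raise DomainError("transform requires (y + shift)/scale > 0")
    if lam == 0.0:
        return np.log(z)
    return (z**lam - 1.0) / lam


def back_transform(model_or_lam, x, shift: float = 0.0, scale: float = 1.0):
    """Exact inverse of :func:`transform`.

    Accepts either a fitted :class:`UsualIntakeModel` or explicit
    (λ, shift, scale).  Raises for values outside the transform's range when
    λ ≠ 0 (where λ·x + 1 must be positive).
    """
    if isinstance(model_or_lam, UsualIntakeModel):
        lam, shift, scale = model_or_lam.lam, model_or_lam.shift, model_or_lam.scale
    else:
        lam = model_or_lam
    x = np.asarray(x, dtype=float)
    if lam == 0.0:
        z = np.exp(x)
    else:
        base = lam * x + 1.0
        if np.any(base <= 0):
            raise DomainError("value outside the range of the power transform")
        z = base ** (1.0 / lam)
    out = z * scale - shift
    return float(out) if out.ndim == 0 else out


def _back_transform_second_deriv(lam, x, scale):
    """d²/dx² of the inverse transform (used by the bias adjustment)."""
    x = np.asarray(x, dtype=float)
    if lam == 0.0:
        return scale * np.exp(x)
    base = lam * x + 1.0
    return scale * (1.0 - lam) * base ** (1.0 / lam - 2.0)


def _weighted_skewness(z, w):
    m = np.average(z, weights=w)
    v = np.average((z - m) ** 2, weights=w)
    if v <= 0:
        return 0.0
    return np.average((z - m) ** 3, weights=w) / v**1.5


def _design_matrix(days: pd.DataFrame, dow_levels: str) -> pd.DataFrame:
    """Covariate indicators; reference level is weekday / in-person."""
    dow = days["day_of_week"].astype(int)
    cols = {}
    if dow_levels == "weekend3":
        cols["dow_friday"] = (dow == 5).astype(float)
        cols["dow_weekend"] = (dow >= 6).astype(float)
    elif dow_levels == "full7":
        for d in range(2, 8):
            cols[f"dow_{d}"] = (dow == d).astype(float)
    else:
        raise DataError(f"unknown dow_levels {dow_levels!r}")
    cols["mode_telephone"] = (days["interview_mode"] == "telephone").astype(float)
    return pd.DataFrame(cols, index=days.index)


def _variance_components(adj: pd.DataFrame, w_person: pd.Series):
    """(sigma2_within, sigma2_between) from adjusted transformed day values.

    Within: twice the weighted mean squared half-difference over two-day
    persons.  Between: weighted variance of person means minus the
    within-person contribution σ²_w · mean(1/dᵢ), floored at 0.
    Returns (s2w, s2b, person_means, n_days); s2w is None when no person
    has two days.
    """
    g = adj.groupby("person_id")["z_adj"]
    means = g.mean()
    n_days = g.size()
    w = w_person.reindex(means.index).astype(float)

    two = n_days[n_days == 2].index
    if len(two) > 0:
        wide = adj[adj["person_id"].isin(two)].pivot_table(
            index="person_id", columns="day_index", values="z_adj"
        )
        half = (wide[1] - wide[2]) / 2.0
        w2 = w_person.reindex(half.index).astype(float)
        s2w = 2.0 * float(np.average(half.to_numpy() ** 2, weights=w2.to_numpy()))
    else:
        s2w = None

    return s2w, means, n_days, w


def _between_variance(means, n_days, w, s2w):
    n = len(means)
    mbar = np.average(means, weights=w)
    var_means = np.average((means - mbar) ** 2, weights=w)
    if n > 1:
        var_means *= n / (n - 1)
    inv_d = np.average(1.0 / n_days.to_numpy(), weights=w)
    return max(var_means - s2w * inv_d, 0.0), mbar


def _finish_person_table(means, n_days, w, s2w, s2b, mbar, lam, shift, scale):
    d = n_days.to_numpy(dtype=float)
    denom = s2b + s2w / d
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, s2b / np.where(denom > 0, denom, 1.0), 1.0)
    # degenerate data (both variances 0): every person sits at the grand mean
    f = np.where(s2w == 0.0, 1.0, f)
    x = mbar + np.sqrt(f) * (means.to_numpy() - mbar)
    usual = back_transform(lam, x, shift, scale)
    usual = usual + 0.5 * _back_transform_second_deriv(lam, x, scale) * s2w
    usual = np.maximum(np.asarray(usual, dtype=float), 0.0)
    return pd.DataFrame(
        {
            "person_id": means.index,
            "n_days": n_days.to_numpy(),
            "mean_transformed": means.to_numpy(),
            "shrink_factor": f,
            "usual_transformed": x,
            "usual_ug": usual,
        }
    ).reset_index(drop=True)


def _prepare_days(person_days: pd.DataFrame, value_col: str) -> pd.DataFrame:
    needed = {"person_id", "day_index", "day_of_week", "interview_mode", value_col}
    missing = needed - set(person_days.columns)
    if missing:
        raise DataError(f"person-day table missing columns: {sorted(missing)}")
    return person_days.reset_index(drop=True)


def fit_usual_intake(
    person_days: pd.DataFrame,
    weights: pd.Series,
    *,
    value_col: str = "total_fa_ug",
    dow_levels: str = "weekend3",
    lam_grid=DEFAULT_LAM_GRID,
    external_within_variance: float | None = None,
) -> UsualIntakeModel:
    """Fit the usual-intake measurement-error model.

    ``person_days``: one row per person-day with columns ``person_id``,
    ``day_index``, ``day_of_week`` (1=Monday … 7=Sunday), ``interview_mode``
    (``in_person``/``telephone``) and the intake column.  ``weights``: one
    analytic weight per person, indexed by person_id.

    A two-day subsample must exist unless ``external_within_variance``
    supplies the within-person variance (on the transformed scale) from
    elsewhere — e.g. borrowing the estimate from survey cycles with two
    recall days to cover a one-day-only cycle.
    """
    days = _prepare_days(person_days, value_col)
    y = days[value_col].to_numpy(dtype=float)
    if np.any(y < 0):
        raise DataError(f"{value_col} must be >= 0")
    w_person = weights.astype(float)
    w_row = days["person_id"].map(w_person).to_numpy(dtype=float)
    if np.any(~np.isfinite(w_row)) or np.any(w_row <= 0):
        raise DataError("every person-day needs a positive person weight")

    scale = float(np.average(y, weights=w_row))
    if scale <= 0:
        scale = 1.0
    shift = 0.0
    if np.any(y <= 0):
        shift = 1e-4 * scale - float(np.min(y))

    # 1. transformation: λ minimizing |weighted skewness|
    best = None
    for lam in lam_grid:
        z = transform(y, lam, shift, scale)
        if not np.all(np.isfinite(z)):
            continue
        sk = abs(_weighted_skewness(z, w_row))
        if not np.isfinite(sk):
            continue
        key = (sk, abs(lam), lam)
        if best is None or key < best[0]:
            best = (key, lam)
    if best is None:
        raise ModelError("no λ in the grid gave a finite skewness criterion")
    lam = float(best[1])
    z = transform(y, lam, shift, scale)

    # 2. covariate adjustment to the weekday / in-person reference
    X = _design_matrix(days, dow_levels)
    import statsmodels.api as sm

    exog = sm.add_constant(X, has_constant="add")
    res = sm.WLS(z, exog, weights=w_row).fit()
    beta = {k: float(v) for k, v in res.params.items() if k != "const"}
    z_adj = z - X.to_numpy() @ np.array([beta[c] for c in X.columns])

    adj = days[["person_id", "day_index"]].copy()
    adj["z_adj"] = z_adj

    # 3. variance components
    s2w_hat, means, n_days, w = _variance_components(adj, w_person)
    if external_within_variance is not None:
        if external_within_variance < 0:
            raise DataError("external_within_variance must be >= 0")
        s2w = float(external_within_variance)
    elif s2w_hat is not None:
        s2w = s2w_hat
    else:
        raise ModelError(
            "no two-day subsample and no external within-person variance supplied"
        )
    s2b, mbar = _between_variance(means, n_days, w, s2w)

    # 4-5. reliability scaling and back-transform
    table = _finish_person_table(means, n_days, w, s2w, s2b, mbar, lam, shift, scale)
    return UsualIntakeModel(
        lam=lam,
        shift=shift,
        scale=scale,
        covariate_effects=beta,
        sigma2_between=s2b,
        sigma2_within=s2w,
        grand_mean=mbar,
        person_table=table,
        weights=w_person.reindex(means.index),
        dow_levels=dow_levels,
    )


def update_intakes(
    model: UsualIntakeModel,
    person_days: pd.DataFrame,
    weights: pd.Series,
    *,
    value_col: str = "total_fa_ug",
    reestimate_variances: bool = True,
    min_twoday_persons: int = 10,
) -> UsualIntakeModel:
    """Re-derive person means (and optionally variances) for new day totals,
    keeping the fitted transformation and covariate effects fixed.

    With ``reestimate_variances=False`` the variance components and hence
    each person's shrink factor are carried over unchanged — the mode used
    for a modeled fortification scenario paired with its current-intake fit,
    which makes scenario comparisons monotone by construction (a scenario
    that raises every day total can only raise every usual value).
    """
    days = _prepare_days(person_days, value_col)
    y = days[value_col].to_numpy(dtype=float)
    w_person = weights.astype(float)
    z = transform(y, model.lam, model.shift, model.scale)
    X = _design_matrix(days, model.dow_levels)
    beta_vec = np.array([model.covariate_effects.get(c, 0.0) for c in X.columns])
    adj = days[["person_id", "day_index"]].copy()
    adj["z_adj"] = z - X.to_numpy() @ beta_vec

    s2w_hat, means, n_days, w = _variance_components(adj, w_person)
    if reestimate_variances:
        n_two = int((n_days == 2).sum())
        s2w = s2w_hat if (s2w_hat is not None and n_two >= min_twoday_persons) else model.sigma2_within
        s2b, mbar = _between_variance(means, n_days, w, s2w)
        if s2b == 0.0 and model.sigma2_between > 0 and len(means) < min_twoday_persons:
            s2b = model.sigma2_between
    else:
        s2w, s2b = model.sigma2_within, model.sigma2_between
        mbar = float(np.average(means, weights=w))
    table = _finish_person_table(
        means, n_days, w, s2w, s2b, mbar, model.lam, model.shift, model.scale
    )
    return UsualIntakeModel(
        lam=model.lam,
        shift=model.shift,
        scale=model.scale,
        covariate_effects=dict(model.covariate_effects),
        sigma2_between=s2b,
        sigma2_within=s2w,
        grand_mean=mbar,
        person_table=table,
        weights=w_person.reindex(means.index),
        dow_levels=model.dow_levels,
    )


def percent_above(
    model: UsualIntakeModel,
    cutpoint: float,
    weights: pd.Series | None = None,
    *,
    min_tail_persons: int = MIN_TAIL_PERSONS,
) -> ExceedanceEstimate:
    """Weighted % of the usual-intake distribution above a cut-point.

    ``weights`` overrides the model's person weights (e.g. a jackknife
    replicate column, indexed by person_id; zero replicate weights are
    allowed).  Estimates whose unweighted tail holds fewer than
    ``min_tail_persons`` persons (but at least one) are flagged
    not-estimable; an empty tail is a clean 0%.
    """
    if cutpoint <= 0:
        raise DomainError(f"cutpoint must be > 0, got {cutpoint}")
    tab = model.person_table
    w = (model.weights if weights is None else weights).reindex(tab["person_id"])
    w = w.to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise DataError("weights must be finite and >= 0")
    total = w.sum()
    if total <= 0:
        raise DataError("total weight is zero")
    above = tab["usual_ug"].to_numpy() > cutpoint
    pct = 100.0 * float(w[above].sum() / total)
    n_above = int(above.sum())
    return ExceedanceEstimate(
        cutpoint_ug=float(cutpoint),
        percent_above=pct,
        n_unweighted=int(len(tab)),
        n_above_unweighted=n_above,
        not_estimable=0 < n_above < min_tail_persons,
    )
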