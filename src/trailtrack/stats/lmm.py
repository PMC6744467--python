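"""Linear mixed models with crossed random intercepts and Tukey pairwise
comparisons of interval means.

Models are fitted with statsmodels ``MixedLM`` using one all-encompassing
group and a variance component per random factor, which realizes crossed
random intercepts (e.g. colony and date). Tukey-adjusted pairwise contrasts
use the studentized range distribution on the fixed-effect estimated
marginal means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from ..core_io import format_clock

__all__ = ["LmmResult", "fit_lmm", "interval_comparison", "bin_half_hour"]

HALF_HOUR_S = 1800.0


@dataclass
class LmmResult:
    """Fixed effects, random-effect variances, and optional pairwise table."""

    fixed_effects: pd.DataFrame  # index term; columns estimate, se, z, p
    fixed_cov: pd.DataFrame  # covariance of the fixed-effect estimates
    random_variances: dict[str, float]
    residual_variance: float
    n_obs: int
    converged: bool
    singular: bool
    pairwise: pd.DataFrame | None = None  # columns a, b, estimate, se, p_tukey
    group_means: pd.DataFrame | None = None
    formula: str = ""

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.loc[term, "se"])


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: str | list[str],
    random_groups: list[str],
) -> LmmResult:
    """Fit ``response ~ fixed`` with random intercepts per grouping factor.

    ``fixed`` is a term or list of terms joined by ``+`` (patsy syntax, so
    ``C(interval)`` is allowed). ``random_groups`` may be empty, in which
    case an OLS fit is returned in the same container. Singular fits
    (a variance component estimated at zero) are flagged, not dropped.
    """
    fixed_terms = [fixed] if isinstance(fixed, str) else list(fixed)
    formula = f"{response} ~ {' + '.join(fixed_terms)}"
    for col in random_groups:
        if col not in table.columns:
            raise ValueError(f"random grouping column {col!r} missing from table")
        if table[col].nunique() < 2:
            raise ValueError(f"random grouping column {col!r} needs >= 2 levels")

    if not random_groups:
        res = smf.ols(formula, data=table).fit()
        fe = pd.DataFrame(
            {"estimate": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues}
        )
        return LmmResult(
            fixed_effects=fe,
            fixed_cov=res.cov_params(),
            random_variances={},
            residual_variance=float(res.mse_resid),
            n_obs=int(res.nobs),
            converged=True,
            singular=False,
            formula=formula,
        )

    data = table.copy()
    data["_one"] = 1
    vc = {g: f"0 + C({g})" for g in random_groups}
    model = smf.mixedlm(formula, data=data, groups="_one", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "powell"])
    k_fe = model.k_fe
    names = list(model.exog_names)
    params = np.asarray(res.params)[:k_fe]
    bse = np.asarray(res.bse)[:k_fe]
    fe = pd.DataFrame(
        {
            "estimate": params,
            "se": bse,
            "z": np.asarray(res.tvalues)[:k_fe],
            "p": np.asarray(res.pvalues)[:k_fe],
        },
        index=names,
    )
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k_fe, :k_fe], index=names, columns=names)
    vcomp = {g: float(v) for g, v in zip(model.exog_vc.names, np.asarray(res.vcomp))}
    singular = bool(np.any(np.asarray(res.vcomp) < 1e-10))
    return LmmResult(
        fixed_effects=fe,
        fixed_cov=cov,
        random_variances=vcomp,
        residual_variance=float(res.scale),
        n_obs=int(res.nobs),
        converged=bool(res.converged),
        singular=singular,
        formula=formula,
    )


def bin_half_hour(clock_s: np.ndarray) -> np.ndarray:
    """Bin seconds-since-midnight into clock-aligned 30-minute interval labels.

    Times past midnight (>= 86400 s) keep increasing so a 19:30-00:00 night
    stays ordered; labels are the interval start clock, e.g. '19:30' or,
    past midnight, '24:00'.
    """
    clock_s = np.asarray(clock_s, dtype=float)
    starts = (np.floor(clock_s / HALF_HOUR_S) * HALF_HOUR_S).astype(int)
    return np.array([f"{s // 3600:02d}:{(s % 3600) // 60:02d}" for s in starts])


def _tukey_pairwise(means: pd.Series, cov: pd.DataFrame, df_resid: float) -> pd.DataFrame:
    """All pairwise contrasts with studentized-range adjusted p-values."""
    levels = list(means.index)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[a] - means[b])
            var = float(cov.loc[a, a] + cov.loc[b, b] - 2.0 * cov.loc[a, b])
            se = float(np.sqrt(max(var, 1e-300)))
            q = abs(diff) / se * np.sqrt(2.0)
            p = float(studentized_range.sf(q, k, df_resid))
            rows.append({"a": a, "b": b, "estimate": diff, "se": se, "p_tukey": p})
    return pd.DataFrame(rows)


def interval_comparison(
    records: pd.DataFrame,
    response: str = "AEI",
    clock_col: str = "start_clock",
    random_groups: list[str] | None = None,
    min_per_interval: int = 2,
) -> LmmResult:
    """Compare the response across clock-aligned 30-minute intervals.

    Bins each record by its clock time, fits ``response ~ C(interval)`` with
    the given random intercepts (default: whichever of colony/date columns
    exist), and attaches per-interval estimated marginal means plus all
    pairwise Tukey contrasts. Intervals with fewer than ``min_per_interval``
    records are dropped with a warning.
    """
    if random_groups is None:
        random_groups = [g for g in ("colony", "date") if g in records.columns
                         and records[g].nunique() >= 2]
    data = records.copy()
    data["interval"] = bin_half_hour(data[clock_col].to_numpy())
    sizes = data.groupby("interval").size()
    thin = sizes[sizes < min_per_interval].index
    if len(thin):
        warnings.warn(
            f"dropping intervals with < {min_per_interval} records: {list(thin)}",
            stacklevel=2,
        )
        data = data[~data["interval"].isin(thin)]
    levels = sorted(data["interval"].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 populated intervals to compare")

    result = fit_lmm(data, response, "C(interval)", random_groups)

    # estimated marginal means under treatment coding: intercept + level term
    terms = list(result.fixed_effects.index)
    design = np.zeros((len(levels), len(terms)))
    for row, lev in enumerate(levels):
        design[row, terms.index("Intercept")] = 1.0
        term = f"C(interval)[T.{lev}]"
        if term in terms:
            design[row, terms.index(term)] = 1.0
    est = design @ result.fixed_effects["estimate"].to_numpy()
    cov_means = pd.DataFrame(
        design @ result.fixed_cov.to_numpy() @ design.T, index=levels, columns=levels
    )
    means_s = pd.Series(est, index=levels)
    df_resid = max(result.n_obs - len(terms), 2)
    result.pairwise = _tukey_pairwise(means_s, cov_means, df_resid)
    result.group_means = pd.DataFrame(
        {
            "interval": levels,
            "mean": est,
            "n": [int(sizes[lev]) for lev in levels],
        }
    )
    return result
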