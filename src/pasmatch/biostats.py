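"""Supporting biostatistics: Fisher's exact test, noncentral-t/F power analysis,
relative qPCR quantification (2^-ddCt), four-parameter dose-response IC50
fitting, and correlation.

Power computations use the exact noncentral t and F distributions rather than
normal approximations, so they agree with dedicated power software even at
very small per-group sizes (df = 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, UndefinedStatisticError, ValidationError
from .io import ContingencyTable2x2

__all__ = [
    "PowerSpec",
    "IC50Fit",
    "fisher_exact_2x2",
    "power_two_sample_t",
    "power_one_way_anova",
    "power",
    "min_n_for_power",
    "ddct_fold_change",
    "fit_ic50",
    "correlation_r2",
]


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sidedness follows the conventional minimum-likelihood rule: the sum of
    probabilities of all tables (with the margins fixed) whose point
    probability does not exceed the observed table's.
    """
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


@dataclass(frozen=True)
class PowerSpec:
    """Specification of a power analysis.

    For ``two_sample_t``: ``effect_size`` is Cohen's d and ``n_per_group`` the
    per-group size.  For ``one_way_anova``: ``effect_size`` is Cohen's f,
    ``k_groups`` the number of groups and ``n_total`` the total sample size.
    """

    test: Literal["two_sample_t", "one_way_anova"]
    effect_size: float
    alpha: float = 0.05
    sides: int = 2
    n_per_group: int | None = None
    k_groups: int | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValidationError("effect size must be nonnegative")


def power_two_sample_t(d: float, n_per_group: int, alpha: float = 0.05, sides: int = 2) -> float:
    """Power of the two-sample t-test for standardized effect d (Cohen).

    The test statistic follows a noncentral t with df = 2n - 2 and
    noncentrality d * sqrt(n/2); power is the probability of exceeding the
    central-t critical value.
    """
    if n_per_group < 2:
        raise ValidationError("need at least 2 observations per group")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    if sides == 2:
        crit = stats.t.ppf(1 - alpha / 2, df)
        pw = stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp)
    elif sides == 1:
        crit = stats.t.ppf(1 - alpha, df)
        pw = stats.nct.sf(crit, df, ncp)
    else:
        raise ValidationError("sides must be 1 or 2")
    return float(pw)


def power_one_way_anova(f: float, k_groups: int, n_total: int, alpha: float = 0.05) -> float:
    """Power of the one-way fixed-effects ANOVA for Cohen's f.

    Under the alternative the F statistic is noncentral F with
    df = (k - 1, N - k) and noncentrality lambda = f^2 * N.
    """
    if k_groups < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    if n_total < k_groups + 1:
        raise ValidationError("total sample size must exceed the number of groups")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    df1, df2 = k_groups - 1, n_total - k_groups
    lam = f * f * n_total
    crit = stats.f.ppf(1 - alpha, df1, df2)
    if lam == 0:  # ncf degenerates to the central F at zero noncentrality
        return float(stats.f.sf(crit, df1, df2))
    return float(stats.ncf.sf(crit, df1, df2, lam))


def power(spec: PowerSpec) -> float:
    """Dispatch a PowerSpec to the matching power function."""
    if spec.test == "two_sample_t":
        if spec.n_per_group is None:
            raise ValidationError("two_sample_t requires n_per_group")
        return power_two_sample_t(spec.effect_size, spec.n_per_group, spec.alpha, spec.sides)
    if spec.test == "one_way_anova":
        if spec.k_groups is None or spec.n_total is None:
            raise ValidationError("one_way_anova requires k_groups and n_total")
        return power_one_way_anova(spec.effect_size, spec.k_groups, spec.n_total, spec.alpha)
    raise ValidationError(f"unknown test {spec.test!r}")


def min_n_for_power(
    f: float, k_groups: int, target_power: float = 0.80, alpha: float = 0.05, n_max: int = 10_000
) -> int:
    """Smallest total N at which a one-way ANOVA reaches the target power."""
    for n in range(k_groups + 1, n_max + 1):
        if power_one_way_anova(f, k_groups, n, alpha) >= target_power:
            return n
    raise ValidationError(f"target power not reached by N={n_max}")


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative qPCR expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    fold change = 2^-ddCt.
    """
    cts = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(math.isfinite(c) for c in cts):
        raise ValidationError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


@dataclass(frozen=True)
class IC50Fit:
    """Four-parameter log-logistic dose-response fit.

    ``ic50`` is the dose at half-maximal inhibition between the fitted top and
    bottom plateaus; NaN when the response is flat or increases with dose.
    """

    ic50: float
    top: float
    bottom: float
    hill: float
    r_squared: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.ic50)


def four_pl(dose: np.ndarray, bottom: float, top: float, ic50: float, hill: float) -> np.ndarray:
    """Viability = bottom + (top - bottom) / (1 + (dose/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def fit_ic50(doses: Sequence[float], viability: Sequence[float]) -> IC50Fit:
    """Least-squares 4PL fit of normalized viability against dose.

    ``doses`` may repeat (replicates).  Initial values come from the data
    extremes and the log-midpoint of the dose range.  Degenerate inputs (flat
    response, viability increasing with dose) yield a warning and NaN IC50.
    """
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    if doses.shape != y.shape:
        raise ValidationError("doses and viability must have equal length")
    if (doses <= 0).any():
        raise ValidationError("doses must be positive")
    if not np.isfinite(y).all():
        raise ValidationError("viabilities must be finite")
    unique = np.unique(doses)
    if unique.size < 4:
        raise ValidationError("IC50 fitting needs at least 4 distinct doses")

    means = pd.Series(y).groupby(pd.Series(doses)).mean()
    means = means.loc[np.sort(means.index)]
    span = means.max() - means.min()
    if span < 1e-3 * max(abs(means).max(), 1.0):
        warnings.warn("flat dose-response: IC50 undefined", stacklevel=2)
        return IC50Fit(math.nan, float(means.mean()), float(means.mean()), math.nan, 0.0)
    rho = stats.spearmanr(means.index.to_numpy(), means.to_numpy()).statistic
    if rho > 0:
        warnings.warn("viability increases with dose: IC50 undefined", stacklevel=2)
        return IC50Fit(math.nan, float(means.iloc[-1]), float(means.iloc[0]), math.nan, 0.0)

    top0 = float(means.iloc[0])
    bottom0 = float(means.iloc[-1])
    ic50_0 = float(np.exp((np.log(unique.min()) + np.log(unique.max())) / 2.0))
    p0 = [bottom0, top0, ic50_0, 1.0]
    bounds = ([-np.inf, -np.inf, unique.min() / 1e3, 1e-3], [np.inf, np.inf, unique.max() * 1e3, 100.0])
    try:
        popt, _ = optimize.curve_fit(four_pl, doses, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        resid = y - four_pl(doses, *p0)
        raise ConvergenceError(
            f"4PL fit did not converge (initial RSS={float(resid @ resid):.4g}): {exc}"
        ) from exc
    bottom, top, ic50, hill = (float(v) for v in popt)
    fitted = four_pl(doses, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IC50Fit(ic50=ic50, top=top, bottom=bottom, hill=hill, r_squared=r2)


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson correlation between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("correlation needs equally long vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
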