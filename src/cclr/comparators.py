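"""Odds-ratio comparator analyses.

The classical case-control alternatives the ccLR is benchmarked against:
the crude (cross-product) odds ratio with Fisher's exact p-value and
Haldane's correction for zero cells, logistic regression adjusted by age
(and country) with a likelihood-ratio-test p-value, and the ACMG/AMP PS4
decision rule (OR > 5.0, confidence interval excluding 1.0, p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .likelihood import CaseControlDataset

__all__ = [
    "ContingencySummary",
    "OrResult",
    "crude_or",
    "logistic_or",
    "ps4_criterion",
    "SEPARATION_ABS_COEF",
]

# |log OR| beyond this is treated as (quasi-)complete separation
SEPARATION_ABS_COEF = 15.0

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencySummary:
    """2x2 carrier-by-status counts."""

    carriers_cases: int
    noncarriers_cases: int
    carriers_controls: int
    noncarriers_controls: int

    def __post_init__(self):
        for name in (
            "carriers_cases",
            "noncarriers_cases",
            "carriers_controls",
            "noncarriers_controls",
        ):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @classmethod
    def from_dataset(cls, data: CaseControlDataset):
        f = data.frame
        cases = f["status"] == 1
        return cls(
            carriers_cases=int((cases & (f["carrier"] == 1)).sum()),
            noncarriers_cases=int((cases & (f["carrier"] == 0)).sum()),
            carriers_controls=int((~cases & (f["carrier"] == 1)).sum()),
            noncarriers_controls=int((~cases & (f["carrier"] == 0)).sum()),
        )

    def cells(self) -> np.ndarray:
        return np.array(
            [
                self.carriers_cases,
                self.noncarriers_cases,
                self.carriers_controls,
                self.noncarriers_controls,
            ],
            dtype=float,
        )

    def table(self) -> np.ndarray:
        """Rows cases/controls, columns carrier/non-carrier."""
        return np.array(
            [
                [self.carriers_cases, self.noncarriers_cases],
                [self.carriers_controls, self.noncarriers_controls],
            ]
        )


@dataclass
class OrResult:
    """An odds-ratio estimate with 95% CI and p-value."""

    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str
    haldane_applied: bool = False
    converged: bool = True
    flags: list = field(default_factory=list)


def crude_or(counts: ContingencySummary, haldane="auto") -> OrResult:
    """Cross-product OR with Woolf 95% CI and Fisher's exact p-value.

    Haldane's correction (add 0.5 to every cell) is applied before the OR
    and CI whenever any cell is zero (``haldane='auto'``, the default) or
    unconditionally (``haldane=True``). The Fisher p-value is always
    computed on the uncorrected table.
    """
    a, b = counts.carriers_cases, counts.noncarriers_cases
    c, d = counts.carriers_controls, counts.noncarriers_controls
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate 2x2 table: an entire margin is zero")
    cells = counts.cells()
    apply_h = haldane is True or (haldane == "auto" and bool(np.any(cells == 0)))
    cc = cells + 0.5 if apply_h else cells
    log_or = float(np.log(cc[0]) + np.log(cc[3]) - np.log(cc[1]) - np.log(cc[2]))
    se = float(np.sqrt((1.0 / cc).sum()))
    p = float(stats.fisher_exact(counts.table())[1])
    return OrResult(
        or_estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        p_value=p,
        method="fisher",
        haldane_applied=bool(apply_h),
    )


def _non_estimable(reason: str) -> OrResult:
    return OrResult(
        or_estimate=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p_value=np.nan,
        method="logistic",
        converged=False,
        flags=[reason],
    )


def logistic_or(data: CaseControlDataset, adjust=("age",)) -> OrResult:
    """OR for carrier status from a binomial-logit fit, adjusted by covariates.

    Fits ``status ~ carrier [+ age] [+ country]`` (country categorical)
    on the aggregated sufficient-statistics table, which is likelihood-
    equivalent to the individual-level fit. The p-value is from the
    likelihood-ratio test dropping the carrier term; the CI is Wald.
    Separation (|log OR| > 15) or IRLS failure is reported through
    ``converged`` rather than raised.
    """
    f = data.frame
    n_cases = int(f["status"].sum())
    if n_cases == 0 or n_cases == len(f):
        raise ValueError("logistic regression needs at least one case and one control")
    k = int(f["carrier"].sum())
    if k == 0 or k == len(f):
        return _non_estimable("non-estimable: carrier status is constant")

    keys = ["carrier"]
    use_age = "age" in adjust
    use_country = "country" in adjust
    if use_age:
        if f["age"].isna().any():
            raise ValueError("age adjustment requested but some ages are unknown")
        keys.append("age")
    if use_country:
        if f["stratum"].isna().any():
            raise ValueError("country adjustment requested but stratum labels missing")
        keys.append("stratum")

    g = (
        f.groupby(keys, sort=True, observed=True)
        .agg(cases=("status", "sum"), total=("status", "size"))
        .reset_index()
    )
    cols = [np.ones(len(g)), g["carrier"].to_numpy(float)]
    if use_age:
        cols.append(g["age"].to_numpy(float))
    if use_country:
        dummies = pd.get_dummies(g["stratum"], drop_first=True, dtype=float)
        cols.extend(dummies[c].to_numpy() for c in dummies.columns)
    X = np.column_stack(cols)
    endog = np.column_stack(
        [g["cases"].to_numpy(float), (g["total"] - g["cases"]).to_numpy(float)]
    )

    fam = sm.families.Binomial()
    try:
        with warnings.catch_warnings():
            # separation is expected with sparse carriers; reported via `converged`
            warnings.simplefilter("ignore")
            full = sm.GLM(endog, X, family=fam).fit()
            reduced = sm.GLM(endog, np.delete(X, 1, axis=1), family=fam).fit()
    except Exception as exc:  # noqa: BLE001 - fit failure is a data condition
        return _non_estimable(f"fit failed: {exc}")

    coef = float(full.params[1])
    se = float(full.bse[1])
    lrt = max(2.0 * (full.llf - reduced.llf), 0.0)
    p = float(stats.chi2.sf(lrt, df=1))
    converged = (
        bool(getattr(full, "converged", True))
        and np.isfinite(coef)
        and np.isfinite(se)
        and abs(coef) <= SEPARATION_ABS_COEF
    )
    flags = [] if converged else ["separation or non-convergence"]
    with np.errstate(over="ignore"):  # separation: CI bound may overflow to inf
        or_est = float(np.exp(coef))
        ci_low = float(np.exp(coef - _Z95 * se))
        ci_high = float(np.exp(coef + _Z95 * se))
    return OrResult(
        or_estimate=or_est,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        method="logistic",
        converged=converged,
        flags=flags,
    )


def ps4_criterion(or_result: OrResult) -> bool:
    """ACMG/AMP PS4: OR > 5.0, 95% CI excluding 1.0, p < 0.05.

    Non-converged or non-estimable results never meet the criterion.
    """
    r = or_result
    if not r.converged or not np.isfinite(r.or_estimate) or not np.isfinite(r.p_value):
        return False
    ci_excludes_one = (r.ci_low > 1.0) or (r.ci_high < 1.0)
    return bool(r.or_estimate > 5.0 and ci_excludes_one and r.p_value < 0.05)
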