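"""Odds-ratio estimation for lifestyle/PRS risk profiles.

Case-control contrasts (any neoplasm, non-advanced adenoma, advanced
neoplasm — each against healthy controls) are analyzed per sex with crude
2x2 odds ratios and multiple logistic regression.  The combined exposure is
the four-level cross of lifestyle group (favorable/unfavorable) and PRS
group (lower/higher) with favorable+lower as reference; models adjust for
age by default, and a lifestyle-x-PRS product term is available as a
sensitivity analysis.  Confidence intervals are Wald intervals throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AliasingError, ContinuityCorrectionWarning, SeparationWarning
from .scores import LS_LABELS, PRS_LABELS, _contrast_outcome

Z95 = 1.959963984540054  # normal 97.5% quantile

#: Absolute log-OR beyond which a coefficient is flagged as (quasi-)separated.
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a binary exposure in a case-control contrast."""

    exposed_cases: float
    exposed_controls: float
    unexposed_cases: float
    unexposed_controls: float

    def __post_init__(self) -> None:
        if min(self.cells) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (
            self.exposed_cases,
            self.exposed_controls,
            self.unexposed_cases,
            self.unexposed_controls,
        )


@dataclass(frozen=True)
class ORResult:
    """An odds ratio with its Wald 95% interval."""

    estimate: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


def crude_or(table: ContingencyTable2x2) -> ORResult:
    """Crude odds ratio ``(a*d)/(b*c)`` with a Wald 95% CI.

    A zero cell triggers the Haldane-Anscombe continuity correction (0.5
    added to every cell) with a warning rather than a failure.
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) == 0:
        warnings.warn(
            "zero cell in 2x2 table; adding 0.5 to every cell",
            ContinuityCorrectionWarning,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return ORResult(
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - Z95 * se)),
        ci_high=float(np.exp(log_or + Z95 * se)),
        log_or=log_or,
        se=se,
    )


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients and covariance."""

    params: pd.Series
    cov: pd.DataFrame

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def z_values(self) -> pd.Series:
        return self.params / self.se

    @property
    def p_values(self) -> pd.Series:
        from scipy.stats import norm

        return pd.Series(2 * norm.sf(np.abs(self.z_values)), index=self.params.index)

    def or_table(self) -> pd.DataFrame:
        """Per-term OR with Wald 95% CI (intercept included for completeness)."""
        se = self.se
        return pd.DataFrame(
            {
                "log_or": self.params,
                "se": se,
                "or": np.exp(self.params),
                "ci_low": np.exp(self.params - Z95 * se),
                "ci_high": np.exp(self.params + Z95 * se),
                "z": self.z_values,
                "p_value": self.p_values,
            }
        )

    def result_for(self, term: str) -> ORResult:
        beta = float(self.params[term])
        se = float(self.se[term])
        return ORResult(
            estimate=float(np.exp(beta)),
            ci_low=float(np.exp(beta - Z95 * se)),
            ci_high=float(np.exp(beta + Z95 * se)),
            log_or=beta,
            se=se,
        )


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    outcome: Sequence[int] | np.ndarray | pd.Series,
    add_intercept: bool = True,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS).

    Convergence at max |score-step coefficient change| < ``tol`` or
    ``maxiter`` iterations; the covariance is the inverse observed
    information.  A rank-deficient design raises :class:`AliasingError`;
    a coefficient diverging beyond +/-15 on the log-odds scale triggers a
    :class:`SeparationWarning` naming the term.
    """
    if isinstance(design, pd.DataFrame):
        X = design.astype(float)
    else:
        arr = np.atleast_2d(np.asarray(design, dtype=float))
        if arr.shape[0] == 1 and np.size(outcome) > 1:
            arr = arr.T
        X = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    y = np.asarray(outcome, dtype=float)
    if add_intercept:
        X = sm.add_constant(X, prepend=True, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise AliasingError("design matrix is rank deficient (aliased columns)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels chatter on hard fits
        res = sm.Logit(y, X).fit(method="newton", tol=tol, maxiter=maxiter, disp=0)
    params = pd.Series(res.params, index=X.columns)
    for term, beta in params.items():
        if abs(beta) > SEPARATION_BOUND:
            warnings.warn(
                f"possible separation: |coefficient| > {SEPARATION_BOUND} for {term!r}",
                SeparationWarning,
            )
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    return LogisticFit(params=params, cov=cov)


EXPOSURE_LEVELS = tuple(
    f"{ls}_{prs}" for ls in LS_LABELS for prs in PRS_LABELS
)  # favorable_lower is the reference


def combined_exposure(ls_group: pd.Series, prs_group: pd.Series) -> pd.Series:
    """Four-level lifestyle-x-PRS exposure label per subject."""
    return (ls_group.astype(str) + "_" + prs_group.astype(str)).rename("exposure")


def run_contrast_suite(
    subjects: pd.DataFrame,
    ls_group: pd.Series,
    prs_group: pd.Series,
    contrasts: Sequence[str] = ("any", "non_advanced", "advanced"),
    adjust: Sequence[str] = ("age",),
    interaction: bool = False,
) -> pd.DataFrame:
    """Sex-stratified OR tables for the combined lifestyle/PRS exposure.

    Returns a tidy frame with one row per (sex, contrast, exposure level):
    case/control counts, OR, Wald CI.  The reference level
    ``favorable_lower`` is fixed at OR 1.  Levels empty in a contrast are
    flagged and their OR omitted.  With ``interaction=True`` the model is
    re-parameterized as main effects plus a lifestyle-x-PRS product term and
    one row per model term is returned instead.
    """
    exposure = combined_exposure(ls_group, prs_group).reindex(subjects.index)
    rows = []
    for sex in ("male", "female"):
        sex_mask = subjects["sex"] == sex
        if not sex_mask.any():
            continue
        for contrast in contrasts:
            y = _contrast_outcome(subjects["outcome"], contrast)
            mask = sex_mask & y.notna() & exposure.notna()
            sub = subjects.loc[mask]
            yy = y[mask].astype(int)
            expo = exposure[mask]
            if interaction:
                rows.extend(
                    _interaction_rows(sub, yy, ls_group[mask], prs_group[mask], adjust, sex, contrast)
                )
                continue
            design = pd.DataFrame(index=sub.index)
            present = []
            for level in EXPOSURE_LEVELS[1:]:
                if (expo == level).any():
                    design[level] = (expo == level).astype(float)
                    present.append(level)
            for cov in adjust:
                design[cov] = sub[cov].astype(float)
            fit = fit_logistic(design, yy)
            for level in EXPOSURE_LEVELS:
                n_cases = int(((expo == level) & (yy == 1)).sum())
                n_controls = int(((expo == level) & (yy == 0)).sum())
                row = {
                    "sex": sex,
                    "contrast": contrast,
                    "exposure": level,
                    "n_cases": n_cases,
                    "n_controls": n_controls,
                    "empty_cell": n_cases + n_controls == 0,
                }
                if level == EXPOSURE_LEVELS[0]:
                    row.update(odds_ratio=1.0, ci_low=np.nan, ci_high=np.nan)
                elif level in present:
                    r = fit.result_for(level)
                    row.update(odds_ratio=r.estimate, ci_low=r.ci_low, ci_high=r.ci_high)
                else:
                    row.update(odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def _interaction_rows(
    sub: pd.DataFrame,
    y: pd.Series,
    ls: pd.Series,
    prs: pd.Series,
    adjust: Sequence[str],
    sex: str,
    contrast: str,
) -> list[dict]:
    design = pd.DataFrame(index=sub.index)
    design["ls_unfavorable"] = (ls == LS_LABELS[1]).astype(float)
    design["prs_higher"] = (prs == PRS_LABELS[1]).astype(float)
    design["ls_x_prs"] = design["ls_unfavorable"] * design["prs_higher"]
    for cov in adjust:
        design[cov] = sub[cov].astype(float)
    fit = fit_logistic(design, y)
    out = []
    for term in ("ls_unfavorable", "prs_higher", "ls_x_prs"):
        r = fit.result_for(term)
        out.append(
            {
                "sex": sex,
                "contrast": contrast,
                "exposure": term,
                "n_cases": int(y.sum()),
                "n_controls": int((1 - y).sum()),
                "empty_cell": False,
                "odds_ratio": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
        )
    return out
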