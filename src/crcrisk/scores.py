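"""Weighted lifestyle score and polygenic risk score construction.

Both scores are weighted sums ``sum_k beta_k * x_k`` where ``beta_k`` is a
log odds ratio and ``x_k`` is a binary unfavorable-lifestyle indicator
(lifestyle score, LS) or a 0/1/2 risk-allele dosage (polygenic risk score,
PRS).  Before PRS construction, candidate SNPs are screened with a 1-df
chi-square goodness-of-fit test against Hardy-Weinberg proportions and
variants departing from HWE at the configured significance level are
excluded — a standard genotyping-quality filter.

Score categorization follows epidemiological convention: the lifestyle
score is split at the sex-specific median (ties to the unfavorable side),
the PRS at its 90th percentile (``higher`` means >= the 90th percentile) or,
for sensitivity analyses, at the top tertile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PACK_YEARS_THRESHOLD, SnpSpec
from .errors import (
    AlignmentError,
    DegenerateStratificationError,
    MissingCovariateError,
    MonomorphicSnpError,
)

MALE_FACTORS = ("waist", "red_meat", "low_fruit", "smoking")
FEMALE_FACTORS = ("waist", "red_meat", "low_fruit")

LS_LABELS = ("favorable", "unfavorable")
PRS_LABELS = ("lower", "higher")


@dataclass(frozen=True)
class WeightVector:
    """Named log-OR weights for a weighted score."""

    names: tuple[str, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.betas):
            raise ValueError("names and betas must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("weight names must be unique")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("weights must be finite")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "WeightVector":
        return cls(tuple(mapping), tuple(float(v) for v in mapping.values()))

    @classmethod
    def from_specs(cls, specs: Sequence[SnpSpec]) -> "WeightVector":
        return cls(tuple(s.snp_id for s in specs), tuple(s.weight for s in specs))

    def as_series(self) -> pd.Series:
        return pd.Series(self.betas, index=list(self.names), name="beta")


def hwe_genotype_counts(dosages: pd.Series | np.ndarray) -> tuple[int, int, int]:
    """Counts of dosage 0 / 1 / 2, ignoring missing entries."""
    arr = np.asarray(dosages, dtype=float)
    arr = arr[~np.isnan(arr)]
    return int((arr == 0).sum()), int((arr == 1).sum()), int((arr == 2).sum())


def test_hwe(counts: tuple[int, int, int]) -> tuple[float, float]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    Parameters
    ----------
    counts : (n_AA, n_Aa, n_aa)
        Observed genotype counts.

    Returns
    -------
    (chi_square, p_value)
        Goodness-of-fit statistic against expected counts
        ``n * (p^2, 2pq, q^2)`` with ``p`` the sample allele frequency, and
        its upper-tail p-value on 1 degree of freedom.

    Raises
    ------
    MonomorphicSnpError
        If the sample allele frequency is 0 or 1 (no test possible; such a
        variant is excluded from the PRS).
    """
    n_aa, n_ab, n_bb = counts
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        raise MonomorphicSnpError(f"monomorphic variant (allele frequency {p:g})")
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def filter_snps(
    panel: Sequence[SnpSpec],
    genotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[SnpSpec], pd.DataFrame]:
    """Remove panel variants departing from HWE at level ``alpha``.

    Returns the retained specs and an exclusion report with one row per
    candidate (snp_id, chi_square, p_value, excluded, reason).  Monomorphic
    variants are excluded with reason ``monomorphic``.  An empty retained
    panel is permitted but warned about.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    retained: list[SnpSpec] = []
    rows = []
    for spec in panel:
        if spec.snp_id not in genotypes.columns:
            raise KeyError(f"no genotype column for {spec.snp_id}")
        counts = hwe_genotype_counts(genotypes[spec.snp_id])
        try:
            chi2, p = test_hwe(counts)
        except MonomorphicSnpError:
            rows.append(
                {
                    "snp_id": spec.snp_id,
                    "n": sum(counts),
                    "chi_square": np.nan,
                    "p_value": np.nan,
                    "excluded": True,
                    "reason": "monomorphic",
                }
            )
            continue
        excluded = p < alpha
        rows.append(
            {
                "snp_id": spec.snp_id,
                "n": sum(counts),
                "chi_square": chi2,
                "p_value": p,
                "excluded": excluded,
                "reason": "hwe_departure" if excluded else "",
            }
        )
        if not excluded:
            retained.append(spec)
    if not retained:
        warnings.warn("all candidate SNPs excluded; retained panel is empty")
    return retained, pd.DataFrame(rows)


def dichotomize_lifestyle(subject: Mapping) -> pd.Series:
    """Binary unfavorable-lifestyle indicators for one subject.

    Men get four indicators (high waist circumference, red-meat consumption,
    low fruit intake, smoking >= 15 pack-years); women get three (no smoking
    term).  The unfavorable level is coded 1.
    """
    try:
        sex = subject["sex"]
    except KeyError as exc:
        raise MissingCovariateError("sex") from exc
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex {sex!r}")
    values = {}
    for name in ("waist", "red_meat", "low_fruit"):
        try:
            v = subject[name]
        except KeyError as exc:
            raise MissingCovariateError(name) from exc
        if pd.isna(v) or v not in (0, 1):
            raise ValueError(f"factor {name!r} must be 0/1, got {v!r}")
        values[name] = int(v)
    if sex == "male":
        try:
            py = subject["pack_years"]
        except KeyError as exc:
            raise MissingCovariateError("pack_years") from exc
        if pd.isna(py):
            raise MissingCovariateError("pack_years")
        values["smoking"] = int(float(py) >= PACK_YEARS_THRESHOLD)
        return pd.Series(values, index=list(MALE_FACTORS))
    return pd.Series(values, index=list(FEMALE_FACTORS))


def weighted_score(values: Mapping | pd.Series, weights: WeightVector) -> float:
    """``sum_k beta_k * x_k`` with values aligned to weight names."""
    total = 0.0
    for name, beta in zip(weights.names, weights.betas):
        try:
            x = values[name]
        except (KeyError, IndexError) as exc:
            raise AlignmentError(f"no value for weight {name!r}") from exc
        if pd.isna(x):
            raise ValueError(
                f"missing value for {name!r}; subjects with missing entries "
                "must be excluded before scoring"
            )
        total += beta * float(x)
    return total


def weighted_scores(table: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Vectorized :func:`weighted_score` over the rows of ``table``."""
    missing = [n for n in weights.names if n not in table.columns]
    if missing:
        raise AlignmentError(f"no columns for weights {missing}")
    sub = table[list(weights.names)]
    if sub.isna().to_numpy().any():
        raise ValueError(
            "missing values present; drop incomplete subjects before scoring"
        )
    return pd.Series(
        sub.to_numpy(dtype=float) @ np.asarray(weights.betas),
        index=table.index,
        name="score",
    )


def prs_scores(
    genotypes: pd.DataFrame, panel: Sequence[SnpSpec], drop_incomplete: bool = True
) -> pd.Series:
    """PRS over a retained panel; optionally drop subjects with missing calls.

    Subjects with a failed call for any retained SNP are removed (not
    imputed), matching the upstream exclusion of samples with failed SNP
    detection.
    """
    weights = WeightVector.from_specs(panel)
    cols = [s.snp_id for s in panel]
    sub = genotypes[cols]
    if drop_incomplete:
        sub = sub.dropna()
    return weighted_scores(sub, weights)


def _check_stratum(values: np.ndarray, label: str) -> None:
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateStratificationError(
            f"need >=2 distinct score values in stratum {label!r}"
        )


def categorize(
    scores: pd.Series,
    scheme: str,
    sex: pd.Series | None = None,
    quantile_method: str = "linear",
) -> pd.Series:
    """Assign categorical risk groups to scores.

    Schemes
    -------
    ``sex_median``
        Unfavorable = score >= the sex-specific median.  Requires ``sex``.
    ``percentile_90``
        Higher = score >= the 90th percentile of the whole distribution.
    ``tertile_top``
        Higher = score in the top tertile (>= the 2/3 quantile).

    Ties at a cutpoint go to the upper (unfavorable / higher) group.  The
    quantile convention is linear interpolation between order statistics by
    default; group membership at boundaries can depend on it, so it is
    exposed.
    """
    vals = scores.to_numpy(dtype=float)
    if scheme == "sex_median":
        if sex is None:
            raise ValueError("sex_median scheme requires a sex series")
        sex = sex.reindex(scores.index)
        labels = pd.Series(index=scores.index, dtype=object, name="group")
        for s in pd.unique(sex):
            m = (sex == s).to_numpy()
            _check_stratum(vals[m], str(s))
            cut = np.quantile(vals[m], 0.5, method=quantile_method)
            labels.loc[m] = np.where(vals[m] >= cut, LS_LABELS[1], LS_LABELS[0])
        return labels
    if scheme == "percentile_90":
        _check_stratum(vals, "all")
        cut = np.quantile(vals, 0.9, method=quantile_method)
        return pd.Series(
            np.where(vals >= cut, PRS_LABELS[1], PRS_LABELS[0]),
            index=scores.index,
            name="group",
        )
    if scheme == "tertile_top":
        _check_stratum(vals, "all")
        cut = np.quantile(vals, 2 / 3, method=quantile_method)
        return pd.Series(
            np.where(vals >= cut, PRS_LABELS[1], PRS_LABELS[0]),
            index=scores.index,
            name="group",
        )
    raise ValueError(f"unknown categorization scheme {scheme!r}")


def estimate_lifestyle_weights(
    subjects: pd.DataFrame, outcome: str = "any"
) -> dict[str, WeightVector]:
    """Per-sex lifestyle log-OR weights estimated from the cohort itself.

    Fits, within each sex, a logistic model of neoplasm status on that sex's
    binary lifestyle indicators and returns the coefficient log-ORs as the
    LS weight vector.  Used when no external weight table is supplied.
    """
    from .association import fit_logistic  # local import; association imports nothing from here

    out: dict[str, WeightVector] = {}
    y_all = _contrast_outcome(subjects["outcome"], outcome)
    for sex, names in (("male", MALE_FACTORS), ("female", FEMALE_FACTORS)):
        mask = (subjects["sex"] == sex) & y_all.notna()
        design = subjects.loc[mask, list(names)].astype(float)
        fit = fit_logistic(design, y_all[mask].astype(int))
        betas = {n: float(fit.params[n]) for n in names}
        out[sex] = WeightVector.from_mapping(betas)
    return out


def lifestyle_scores(
    subjects: pd.DataFrame, weights_by_sex: Mapping[str, WeightVector]
) -> pd.Series:
    """Sex-specific weighted lifestyle score for every subject."""
    scores = pd.Series(index=subjects.index, dtype=float, name="score")
    factors = pd.DataFrame(
        [dichotomize_lifestyle(row) for _, row in subjects.iterrows()],
        index=subjects.index,
    )
    for sex, weights in weights_by_sex.items():
        m = subjects["sex"] == sex
        if m.any():
            scores.loc[m] = weighted_scores(factors.loc[m, list(weights.names)], weights)
    return scores


def screen_factors(
    subjects: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "any",
    p_threshold: float = 0.1,
) -> dict[str, list[str]]:
    """Univariate screening of candidate factors (helper, not hard-wired).

    Returns, per sex, the candidates whose univariate logistic association
    with the outcome has p < ``p_threshold``.
    """
    from .association import fit_logistic

    y_all = _contrast_outcome(subjects["outcome"], outcome)
    selected: dict[str, list[str]] = {}
    for sex in ("male", "female"):
        mask = (subjects["sex"] == sex) & y_all.notna()
        keep = []
        for name in candidates:
            design = subjects.loc[mask, [name]].astype(float)
            fit = fit_logistic(design, y_all[mask].astype(int))
            if float(fit.p_values[name]) < p_threshold:
                keep.append(name)
        selected[sex] = keep
    return selected


def _contrast_outcome(outcome: pd.Series, contrast: str) -> pd.Series:
    """Binary case indicator (NaN = excluded) for a named outcome contrast."""
    if contrast == "any":
        return pd.Series(
            np.where(outcome == "control", 0.0, 1.0), index=outcome.index
        )
    if contrast == "non_advanced":
        y = pd.Series(np.nan, index=outcome.index)
        y[outcome == "control"] = 0.0
        y[outcome == "non_advanced"] = 1.0
        return y
    if contrast == "advanced":
        y = pd.Series(np.nan, index=outcome.index)
        y[outcome == "control"] = 0.0
        y[outcome == "advanced"] = 1.0
        return y
    raise ValueError(f"unknown contrast {contrast!r}")
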