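"""Risk-adapted screening scenarios: triage, FIT reflex, yield metrics.

A screening scenario assigns every participant a first-line modality from
their lifestyle-score and PRS groups: high-risk subjects go straight to
colonoscopy, low-risk subjects take a fecal immunochemical test (FIT) and
are referred to colonoscopy only if positive (>= 100 ng Hb/ml).  Yield is
summarized per scenario by the positive predictive value (lesions detected
per colonoscopy) and its reciprocal, the number of colonoscopies needed to
detect one lesion (NNS), for advanced neoplasm and for any neoplasm.
Detection is person-level: a colonoscopy detects the subject's true
most-advanced lesion class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import FIT_THRESHOLD_NG_ML
from .errors import ConfigError, DataError, TriageError, UndefinedYieldError
from .scores import LS_LABELS, PRS_LABELS

_CELLS = tuple((ls, prs) for ls in LS_LABELS for prs in PRS_LABELS)


@dataclass(frozen=True)
class TriageRule:
    """Total mapping from the four (lifestyle, PRS) cells to {high, low}."""

    label: str
    mapping: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        missing = [c for c in _CELLS if c not in self.mapping]
        if missing:
            raise ValueError(f"triage rule {self.label!r} misses cells {missing}")
        bad = {v for v in self.mapping.values()} - {"high", "low"}
        if bad:
            raise ValueError(f"triage rule values must be high/low, got {bad}")

    @classmethod
    def from_predicate(cls, label: str, predicate) -> "TriageRule":
        return cls(
            label=label,
            mapping={c: ("high" if predicate(*c) else "low") for c in _CELLS},
        )


#: Shipped triage presets over the four lifestyle-x-PRS cells.
PRESET_RULES: dict[str, TriageRule] = {
    "either_high": TriageRule.from_predicate(
        "either_high", lambda ls, prs: ls == "unfavorable" or prs == "higher"
    ),
    "both_high": TriageRule.from_predicate(
        "both_high", lambda ls, prs: ls == "unfavorable" and prs == "higher"
    ),
    "ls_only": TriageRule.from_predicate("ls_only", lambda ls, prs: ls == "unfavorable"),
    "prs_only": TriageRule.from_predicate("prs_only", lambda ls, prs: prs == "higher"),
    "all_high": TriageRule.from_predicate("all_high", lambda ls, prs: True),
}


def triage(
    ls_group: pd.Series, prs_group: pd.Series, rule: TriageRule
) -> pd.Series:
    """Assign each subject to {colonoscopy, fit} by the rule's truth table."""
    if not ls_group.index.equals(prs_group.index):
        prs_group = prs_group.reindex(ls_group.index)
    out = pd.Series(index=ls_group.index, dtype=object, name="assignment")
    for sid in ls_group.index:
        ls, prs = ls_group[sid], prs_group[sid]
        if (ls, prs) not in rule.mapping:
            raise TriageError(f"subject {sid}: missing or unknown group ({ls!r}, {prs!r})")
        out[sid] = "colonoscopy" if rule.mapping[(ls, prs)] == "high" else "fit"
    return out


def resolve_fit_reflex(
    assignment: pd.Series,
    fit_positive: pd.Series | None = None,
    fit_value: pd.Series | None = None,
    threshold: float = FIT_THRESHOLD_NG_ML,
) -> pd.Series:
    """Final colonoscopy indicator: high-risk arm plus FIT-positive low-risk arm.

    Either a boolean positivity flag or a quantitative ng Hb/ml value (then
    positive means >= ``threshold``, boundary included) must be supplied for
    every FIT-arm subject.
    """
    if fit_positive is None and fit_value is None:
        raise DataError("either fit_positive or fit_value must be supplied")
    if fit_value is not None:
        fit_value = fit_value.reindex(assignment.index)
        fit_positive = fit_value >= threshold
        missing = fit_value.isna()
    else:
        fit_positive = fit_positive.reindex(assignment.index)
        missing = fit_positive.isna()
    fit_arm = assignment == "fit"
    bad = fit_arm & missing
    if bad.any():
        raise DataError(
            f"missing FIT result for FIT-arm subjects: {list(assignment.index[bad])[:5]}"
        )
    final = (assignment == "colonoscopy") | (fit_arm & fit_positive.fillna(False).astype(bool))
    return final.rename("colonoscopy")


@dataclass(frozen=True)
class YieldReport:
    """Yield and resource metrics for one screening scenario."""

    scenario: str
    n_screened: int
    n_colonoscopies: int
    detected_advanced: int
    detected_any: int
    ppv_advanced: float
    ppv_any: float
    nns_advanced: float  # inf when no advanced lesion detected
    nns_any: float

    def __post_init__(self) -> None:
        if self.detected_any > self.n_colonoscopies:
            raise ValueError("detections cannot exceed colonoscopies")

    @property
    def zero_detections(self) -> bool:
        return self.detected_any == 0

    def rounded(self) -> dict:
        """Display form: percentages and NNS at 1 decimal (full precision kept)."""
        return {
            "scenario": self.scenario,
            "n_colonoscopies": self.n_colonoscopies,
            "ppv_advanced_pct": round(100 * self.ppv_advanced, 1),
            "nns_advanced": round(self.nns_advanced, 1) if math.isfinite(self.nns_advanced) else math.inf,
            "ppv_any_pct": round(100 * self.ppv_any, 1),
            "nns_any": round(self.nns_any, 1) if math.isfinite(self.nns_any) else math.inf,
        }


def evaluate_yield(
    colonoscopy: pd.Series, outcome: pd.Series, scenario: str = "scenario"
) -> YieldReport:
    """PPV and NNS from a final colonoscopy set and true outcome classes."""
    colonoscopy = colonoscopy.astype(bool)
    outcome = outcome.reindex(colonoscopy.index)
    n_col = int(colonoscopy.sum())
    if n_col == 0:
        raise UndefinedYieldError(f"{scenario}: zero colonoscopies performed")
    scoped = outcome[colonoscopy]
    adv = int((scoped == "advanced").sum())
    any_n = adv + int((scoped == "non_advanced").sum())
    return YieldReport(
        scenario=scenario,
        n_screened=len(colonoscopy),
        n_colonoscopies=n_col,
        detected_advanced=adv,
        detected_any=any_n,
        ppv_advanced=adv / n_col,
        ppv_any=any_n / n_col,
        nns_advanced=n_col / adv if adv else math.inf,
        nns_any=n_col / any_n if any_n else math.inf,
    )


def compare_scenarios(
    subjects: pd.DataFrame,
    ls_group: pd.Series,
    prs_group: pd.Series,
    scenarios: Sequence[TriageRule],
    fit_positive: pd.Series | None = None,
    fit_value: pd.Series | None = None,
    include_reference: bool = True,
) -> list[YieldReport]:
    """Yield reports for each triage scenario on a shared cohort.

    The colonoscopy-only strategy is always evaluated first as the
    reference (unless disabled).  Duplicate scenario labels are a
    configuration error.
    """
    labels = ["colonoscopy_only"] * include_reference + [r.label for r in scenarios]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate scenario labels in {labels}")
    if fit_positive is None and fit_value is None:
        fit_positive = subjects.get("fit_positive")
    reports: list[YieldReport] = []
    outcome = subjects["outcome"]
    if include_reference:
        everyone = pd.Series(True, index=subjects.index)
        reports.append(evaluate_yield(everyone, outcome, "colonoscopy_only"))
    for rule in scenarios:
        assignment = triage(ls_group, prs_group, rule)
        final = resolve_fit_reflex(assignment, fit_positive=fit_positive, fit_value=fit_value)
        reports.append(evaluate_yield(final, outcome, rule.label))
    return reports


def reports_frame(reports: Sequence[YieldReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "scenario": r.scenario,
                "n_screened": r.n_screened,
                "n_colonoscopies": r.n_colonoscopies,
                "detected_advanced": r.detected_advanced,
                "detected_any": r.detected_any,
                "ppv_advanced": r.ppv_advanced,
                "ppv_any": r.ppv_any,
                "nns_advanced": r.nns_advanced if math.isfinite(r.nns_advanced) else np.inf,
                "nns_any": r.nns_any if math.isfinite(r.nns_any) else np.inf,
            }
        )
    return pd.DataFrame(rows)
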