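"""Synthetic cohorts for colorectal-neoplasm risk modelling.

This module generates case-control style screening cohorts with the
statistical structure the downstream analyses assume:

* SNP genotypes drawn per variant from Hardy-Weinberg proportions, with an
  optional inbreeding coefficient ``f`` that moves a variant out of HWE
  (the single knob used to force genotyping-quality failures);
* sex, age and binary unfavorable-lifestyle indicators (high waist
  circumference, red-meat consumption, low fruit intake, heavy smoking)
  drawn from per-sex prevalences;
* a three-class colonoscopy outcome (healthy control / non-advanced adenoma
  / advanced neoplasm) generated by a two-stage logistic model: any-neoplasm
  given covariates and genotypes, then advanced given any neoplasm;
* a fecal immunochemical test (FIT) result drawn with class-specific
  sensitivity and an overall specificity, either as a binary positivity flag
  or as a quantitative haemoglobin concentration thresholded at
  100 ng Hb/ml.

Every generator is driven by an explicit integer seed and is byte-stable:
the same configuration and seed reproduce the same cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import InvalidSpecError, ModelSpecificationError

SEXES = ("male", "female")
OUTCOMES = ("control", "non_advanced", "advanced")
FACTORS = ("waist", "red_meat", "low_fruit", "smoking")
_NUCLEOTIDES = ("A", "C", "G", "T")

#: Smoking enters the male lifestyle score at >= this many pack-years.
PACK_YEARS_THRESHOLD = 15.0

#: FIT positivity cutoff in ng Hb/ml (quantitative mode).
FIT_THRESHOLD_NG_ML = 100.0

_AGE_MIDPOINT = 62.0  # centering constant for the age covariate


@dataclass(frozen=True)
class SnpSpec:
    """One candidate PRS variant.

    Parameters
    ----------
    snp_id : str
        Variant identifier (rs-style or arbitrary).
    risk_allele : str
        Nucleotide whose dosage (0/1/2) enters the PRS.
    raf : float
        Risk-allele frequency, strictly inside (0, 1).
    weight : float
        Per-allele log odds ratio for colorectal neoplasm.
    inbreeding_f : float, default 0
        Hardy-Weinberg departure coefficient in (-1, 1].  ``f = 0`` gives
        genotype frequencies ((1-p)^2, 2p(1-p), p^2); positive ``f`` removes
        heterozygote mass, ``f = 1`` removes it entirely.
    other_allele : str, optional
        The non-risk allele; defaults to the first nucleotide differing from
        the risk allele (only used when writing VCF).
    """

    snp_id: str
    risk_allele: str
    raf: float
    weight: float
    inbreeding_f: float = 0.0
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.raf < 1.0):
            raise InvalidSpecError(
                f"{self.snp_id}: risk-allele frequency {self.raf} outside (0, 1)"
            )
        if not np.isfinite(self.weight):
            raise InvalidSpecError(f"{self.snp_id}: non-finite weight")
        if not (-1.0 < self.inbreeding_f <= 1.0):
            raise InvalidSpecError(
                f"{self.snp_id}: inbreeding coefficient {self.inbreeding_f} outside (-1, 1]"
            )
        if any(f < 0 for f in self.genotype_freqs()):
            raise InvalidSpecError(
                f"{self.snp_id}: inbreeding_f={self.inbreeding_f} yields a negative "
                "genotype frequency at raf={self.raf}"
            )
        if self.other_allele is None:
            other = next(n for n in _NUCLEOTIDES if n != self.risk_allele)
            object.__setattr__(self, "other_allele", other)
        elif self.other_allele == self.risk_allele:
            raise InvalidSpecError(f"{self.snp_id}: other_allele equals risk_allele")

    def genotype_freqs(self) -> tuple[float, float, float]:
        """Frequencies of dosage (0, 1, 2) under the inbreeding model."""
        p, f = self.raf, self.inbreeding_f
        q = 1.0 - p
        fpq = f * p * q
        return (q * q + fpq, 2.0 * p * q * (1.0 - f), p * p + fpq)


def default_panel(
    n_snps: int = 24,
    n_out_of_hwe: int = 5,
    seed: int = 0,
    inbreeding_f: float = 0.6,
) -> list[SnpSpec]:
    """A candidate SNP panel with a subset forced out of HWE.

    Mirrors a targeted-genotyping panel for colorectal neoplasm: modest
    per-allele odds ratios (1.05-1.30) and common risk alleles.  The
    ``n_out_of_hwe`` variants flagged with ``inbreeding_f`` emulate assay
    failures that the HWE quality filter is expected to remove.
    """
    if not (0 <= n_out_of_hwe <= n_snps):
        raise ValueError("n_out_of_hwe must be between 0 and n_snps")
    rng = np.random.default_rng(seed)
    rafs = rng.uniform(0.10, 0.90, size=n_snps)
    ors = rng.uniform(1.05, 1.30, size=n_snps)
    alleles = rng.choice(_NUCLEOTIDES, size=n_snps)
    ids = rng.choice(9_000_000, size=n_snps, replace=False) + 1_000_000
    fail = np.zeros(n_snps, dtype=bool)
    fail[rng.choice(n_snps, size=n_out_of_hwe, replace=False)] = True
    return [
        SnpSpec(
            snp_id=f"rs{ids[i]}",
            risk_allele=str(alleles[i]),
            raf=float(rafs[i]),
            weight=float(np.log(ors[i])),
            inbreeding_f=inbreeding_f if fail[i] else 0.0,
        )
        for i in range(n_snps)
    ]


def _exact_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to probs (largest remainder)."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def simulate_genotypes(
    specs: Sequence[SnpSpec],
    n: int,
    seed: int,
    missing_rate: float = 0.0,
    exact_frequencies: bool = False,
) -> pd.DataFrame:
    """Draw an ``n x len(specs)`` dosage table (0/1/2, NaN for missing).

    With ``exact_frequencies=True`` the genotype *counts* per SNP are the
    largest-remainder rounding of ``n`` times the model frequencies and only
    the within-column ordering is randomized.  This realizes each variant's
    HWE departure (or lack of one) deterministically, which is what a
    fixture that must reproduce a fixed pass/fail pattern needs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not specs:
        raise ValueError("specs must be non-empty")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for spec in specs:
        probs = np.asarray(spec.genotype_freqs())
        if exact_frequencies:
            counts = _exact_counts(probs, n)
            col = np.repeat([0.0, 1.0, 2.0], counts)
            rng.shuffle(col)
        else:
            col = rng.choice([0.0, 1.0, 2.0], size=n, p=probs / probs.sum())
        cols[spec.snp_id] = col
    table = pd.DataFrame(cols, index=_subject_ids(n))
    if missing_rate > 0.0:
        mask = rng.random(table.shape) < missing_rate
        table = table.mask(mask)
    return table


def _subject_ids(n: int, prefix: str = "S") -> pd.Index:
    return pd.Index([f"{prefix}{i + 1:06d}" for i in range(n)], name="subject_id")


def _default_prevalences() -> dict[str, dict[str, float]]:
    # Unfavorable-level prevalences per sex.  Red meat / fruit / male smoking
    # match the screening-cohort margins the generator emulates; the waist
    # median split is 0.5 by construction.  The female "smoking" entry is the
    # ever-smoked fraction used only to draw pack-years (women's lifestyle
    # score carries no smoking term).
    return {
        "male": {"waist": 0.50, "red_meat": 0.935, "low_fruit": 0.393, "smoking": 0.481},
        "female": {"waist": 0.50, "red_meat": 0.914, "low_fruit": 0.479, "smoking": 0.015},
    }


def _default_any_betas() -> dict[str, float]:
    return {
        "male": 0.80,
        "age_c": 0.030,
        "waist": 0.18,
        "red_meat": 0.26,
        "low_fruit": 0.18,
        "smoking": 0.26,
    }


def _default_advanced_betas() -> dict[str, float]:
    return {"male": 0.25}


@dataclass
class OutcomeModel:
    """Two-stage logistic outcome model.

    Stage 1 draws any-neoplasm status from
    ``logit P = any_intercept + sum(beta_j x_j) + genetic_scale * sum_k w_k (g_k - 2 p_k)``
    where ``w_k`` is the SNP weight and the dosage is centered at its
    expectation so the intercept controls the marginal prevalence.  Stage 2
    draws advanced-versus-non-advanced among neoplasm carriers.

    The default intercepts are calibrated so that, under the default effect
    sizes and covariate prevalences, the marginal any-neoplasm fraction is
    ~0.355 and the advanced fraction among neoplasms ~0.304 — the composition
    of the screening cohort the generator emulates (667/1880 and 203/667).
    """

    any_intercept: float = -1.5592
    any_betas: dict[str, float] = field(default_factory=_default_any_betas)
    advanced_intercept: float = -0.9828
    advanced_betas: dict[str, float] = field(default_factory=_default_advanced_betas)
    genetic_scale: float = 1.0


@dataclass
class FitModel:
    """Class-conditional FIT result model.

    ``sensitivity`` maps neoplasm classes to P(FIT positive); controls are
    positive with probability ``1 - specificity``.  In quantitative mode a
    ng Hb/ml value consistent with the positivity flag is drawn and the flag
    is re-derived by thresholding at 100 ng Hb/ml.

    The default sensitivities/specificity are plausible one-sample values for
    a quantitative FIT at the 100 ng Hb/ml cutoff, not estimates from any
    specific trial; the advanced-class default blends carcinoma (0.75) and
    advanced-adenoma (0.25) sensitivity at the roughly 24:179 lesion mix of
    a screening setting.
    """

    sensitivity: dict[str, float] = field(
        default_factory=lambda: {"advanced": 0.31, "non_advanced": 0.10}
    )
    specificity: float = 0.92
    quantitative: bool = False


@dataclass
class CohortConfig:
    """Configuration for :func:`simulate_subjects`."""

    n_subjects: int = 1880
    sex_ratio: float = 0.513
    age_range: tuple[int, int] = (50, 74)
    lifestyle_prevalences: dict[str, dict[str, float]] = field(
        default_factory=_default_prevalences
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    fit_model: FitModel = field(default_factory=FitModel)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must lie in [0, 1]")
        lo, hi = self.age_range
        if hi < lo:
            raise ValueError("age_range upper bound below lower bound")
        for sex, prevs in self.lifestyle_prevalences.items():
            for name, p in prevs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"prevalence {sex}/{name}={p} outside [0, 1]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must lie in [0, 1]")
        fm = self.fit_model
        if not (0.0 <= fm.specificity <= 1.0):
            raise ValueError("FIT specificity outside [0, 1]")
        for cls, s in fm.sensitivity.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"FIT sensitivity for {cls} outside [0, 1]")


@dataclass
class Cohort:
    """A simulated cohort: per-subject table, dosage table, SNP panel."""

    subjects: pd.DataFrame
    genotypes: pd.DataFrame
    specs: list[SnpSpec]

    @property
    def n(self) -> int:
        return len(self.subjects)


def _bernoulli(rng: np.random.Generator, p: np.ndarray | float, n: int) -> np.ndarray:
    return (rng.random(n) < p).astype(int)


def _draw_pack_years(
    rng: np.random.Generator, male: np.ndarray, prevs: Mapping[str, Mapping[str, float]]
) -> np.ndarray:
    """Pack-years consistent with the per-sex smoking prevalences.

    Males at or above the 15 pack-year threshold occur at the configured
    prevalence; a further slice of males are light (<15 py) smokers.  Female
    smoking is rare and light, matching screening-age Chinese cohorts.
    """
    n = male.size
    pack = np.zeros(n)
    u = rng.random(n)
    heavy = male & (u < prevs["male"]["smoking"])
    light_m = male & ~heavy & (rng.random(n) < 0.15)
    ever_f = ~male & (u < prevs["female"]["smoking"])
    pack[heavy] = PACK_YEARS_THRESHOLD + rng.exponential(12.0, heavy.sum())
    pack[light_m] = rng.uniform(0.5, PACK_YEARS_THRESHOLD, light_m.sum())
    pack[ever_f] = rng.uniform(0.1, 10.0, ever_f.sum())
    return pack


def _draw_fit(
    rng: np.random.Generator, outcome: np.ndarray, fit_model: FitModel
) -> tuple[np.ndarray, np.ndarray]:
    """Return (fit_positive bool, fit_value ng/ml or NaN)."""
    n = outcome.size
    p_pos = np.full(n, 1.0 - fit_model.specificity)
    for cls, sens in fit_model.sensitivity.items():
        p_pos[outcome == cls] = sens
    positive = rng.random(n) < p_pos
    if not fit_model.quantitative:
        return positive, np.full(n, np.nan)
    value = np.empty(n)
    neg = ~positive
    value[neg] = rng.uniform(0.0, FIT_THRESHOLD_NG_ML, neg.sum())
    value[positive] = FIT_THRESHOLD_NG_ML + rng.gamma(1.2, 250.0, positive.sum())
    positive = value >= FIT_THRESHOLD_NG_ML
    return positive, value


def simulate_subjects(
    config: CohortConfig, specs: Sequence[SnpSpec], seed: int | None = None
) -> Cohort:
    """Simulate a full cohort under ``config`` and the SNP panel ``specs``.

    Outcomes are generated from the *true* genotypes; genotype missingness is
    applied only to the emitted dosage table (a measurement artifact, not a
    biological one).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = config.n_subjects
    ids = _subject_ids(n)

    male = rng.random(n) < config.sex_ratio
    sex = np.where(male, "male", "female")
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)

    prevs = config.lifestyle_prevalences
    factors: dict[str, np.ndarray] = {}
    for name in ("waist", "red_meat", "low_fruit"):
        p = np.where(male, prevs["male"][name], prevs["female"][name])
        factors[name] = _bernoulli(rng, p, n)
    pack_years = _draw_pack_years(rng, male, prevs)
    factors["smoking"] = ((pack_years >= PACK_YEARS_THRESHOLD) & male).astype(int)

    geno_seed = int(rng.integers(2**31))
    true_geno = simulate_genotypes(specs, n, seed=geno_seed)
    weights = np.array([s.weight for s in specs])
    rafs = np.array([s.raf for s in specs])
    genetic = (true_geno.to_numpy() - 2.0 * rafs) @ weights

    om = config.outcome_model
    covariates = {
        "male": male.astype(int),
        "age_c": age - _AGE_MIDPOINT,
        **factors,
    }

    def _linpred(intercept: float, betas: Mapping[str, float]) -> np.ndarray:
        lp = np.full(n, intercept, dtype=float)
        for name, beta in betas.items():
            if name not in covariates:
                raise ModelSpecificationError(f"unknown outcome covariate {name!r}")
            lp += beta * covariates[name]
        return lp

    lp_any = _linpred(om.any_intercept, om.any_betas) + om.genetic_scale * genetic
    if not np.all(np.isfinite(lp_any)):
        raise ModelSpecificationError("non-finite any-neoplasm linear predictor")
    any_neoplasm = rng.random(n) < expit(lp_any)

    lp_adv = _linpred(om.advanced_intercept, om.advanced_betas)
    advanced = any_neoplasm & (rng.random(n) < expit(lp_adv))
    outcome = np.where(advanced, "advanced", np.where(any_neoplasm, "non_advanced", "control"))

    fit_positive, fit_value = _draw_fit(rng, outcome, config.fit_model)

    genotypes = true_geno.copy()
    if config.missing_rate > 0.0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.mask(mask)

    subjects = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "waist": factors["waist"],
            "red_meat": factors["red_meat"],
            "low_fruit": factors["low_fruit"],
            "smoking": factors["smoking"],
            "pack_years": pack_years,
            "outcome": outcome,
            "fit_positive": fit_positive,
            "fit_value": fit_value,
        },
        index=ids,
    )
    return Cohort(subjects=subjects, genotypes=genotypes, specs=list(specs))


def calibrate_outcome_intercepts(
    config: CohortConfig,
    specs: Sequence[SnpSpec],
    target_any: float = 667 / 1880,
    target_advanced_given_any: float = 203 / 667,
    n: int = 200_000,
    seed: int = 20200501,
    tol: float = 5e-4,
) -> CohortConfig:
    """Return a config whose intercepts hit the target marginal prevalences.

    Bisection on each intercept against a large simulated draw; used once to
    freeze the package defaults and exposed for users who change effect
    sizes or prevalences.
    """
    work = dataclasses.replace(config, n_subjects=n, missing_rate=0.0)

    def any_frac(intercept: float) -> float:
        om = dataclasses.replace(work.outcome_model, any_intercept=intercept)
        cohort = simulate_subjects(dataclasses.replace(work, outcome_model=om), specs, seed=seed)
        return float((cohort.subjects["outcome"] != "control").mean())

    lo, hi = -6.0, 4.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if any_frac(mid) < target_any:
            lo = mid
        else:
            hi = mid
    a0 = 0.5 * (lo + hi)

    om = dataclasses.replace(work.outcome_model, any_intercept=a0)

    def adv_frac(intercept: float) -> float:
        om2 = dataclasses.replace(om, advanced_intercept=intercept)
        cohort = simulate_subjects(dataclasses.replace(work, outcome_model=om2), specs, seed=seed)
        sub = cohort.subjects
        neo = sub["outcome"] != "control"
        return float((sub.loc[neo, "outcome"] == "advanced").mean())

    lo, hi = -6.0, 4.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if adv_frac(mid) < target_advanced_given_any:
            lo = mid
        else:
            hi = mid
    om = dataclasses.replace(om, advanced_intercept=0.5 * (lo + hi))
    return dataclasses.replace(config, outcome_model=om)


# ---------------------------------------------------------------------------
# Reference fixtures: printed-margin cohort and sample-selection flow
# ---------------------------------------------------------------------------

#: Sex-by-outcome composition of the reference screening cohort (n = 1880).
REFERENCE_COMPOSITION: dict[str, dict[str, int]] = {
    "male": {"control": 513, "non_advanced": 306, "advanced": 145},
    "female": {"control": 700, "non_advanced": 158, "advanced": 58},
}

#: Per sex-and-outcome counts of unfavorable lifestyle levels in the
#: reference cohort (smoking = males >= 15 pack-years; red_meat = consumers;
#: fruit = consumers, complemented to low_fruit below).
_REFERENCE_FACTOR_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "smoking": {
        "male": {"control": 228, "non_advanced": 159, "advanced": 77},
        "female": {"control": 0, "non_advanced": 0, "advanced": 0},
    },
    "red_meat": {
        "male": {"control": 475, "non_advanced": 285, "advanced": 141},
        "female": {"control": 602, "non_advanced": 143, "advanced": 53},
    },
    "fruit": {
        "male": {"control": 298, "non_advanced": 196, "advanced": 91},
        "female": {"control": 348, "non_advanced": 91, "advanced": 38},
    },
}

_REFERENCE_AGE = {"control": 59.8, "non_advanced": 61.5, "advanced": 61.7}


def reference_cohort(
    seed: int = 0,
    specs: Sequence[SnpSpec] | None = None,
    fit_model: FitModel | None = None,
) -> Cohort:
    """Deterministic cohort reproducing the reference study margins exactly.

    The sex-by-outcome cell counts and the per-cell smoking / red-meat /
    fruit counts are fixed (not sampled), so summary statistics such as the
    male fraction (964/1880) and the outcome composition (203 advanced, 464
    non-advanced, 1213 controls) are identical for every seed.  Ages, waist
    indicators, FIT results and optional genotypes are drawn with ``seed``.
    """
    rng = np.random.default_rng(seed)
    fit_model = fit_model or FitModel()
    rows: list[dict] = []
    for sex, by_outcome in REFERENCE_COMPOSITION.items():
        for outcome, m in by_outcome.items():
            smoking = np.zeros(m, dtype=int)
            smoking[: _REFERENCE_FACTOR_COUNTS["smoking"][sex][outcome]] = 1
            rng.shuffle(smoking)
            red = np.zeros(m, dtype=int)
            red[: _REFERENCE_FACTOR_COUNTS["red_meat"][sex][outcome]] = 1
            rng.shuffle(red)
            fruit = np.zeros(m, dtype=int)
            fruit[: _REFERENCE_FACTOR_COUNTS["fruit"][sex][outcome]] = 1
            rng.shuffle(fruit)
            age = np.clip(
                np.round(rng.normal(_REFERENCE_AGE[outcome], 6.3, m)), 50, 74
            ).astype(int)
            waist = _bernoulli(rng, 0.5, m)
            pack = np.where(
                smoking == 1, PACK_YEARS_THRESHOLD + rng.exponential(12.0, m), 0.0
            )
            for i in range(m):
                rows.append(
                    {
                        "sex": sex,
                        "age": age[i],
                        "waist": waist[i],
                        "red_meat": red[i],
                        "low_fruit": 1 - fruit[i],
                        "smoking": smoking[i],
                        "pack_years": pack[i],
                        "outcome": outcome,
                    }
                )
    subjects = pd.DataFrame(rows, index=_subject_ids(len(rows)))
    fit_positive, fit_value = _draw_fit(
        rng, subjects["outcome"].to_numpy(), fit_model
    )
    subjects["fit_positive"] = fit_positive
    subjects["fit_value"] = fit_value
    if specs is not None:
        geno = simulate_genotypes(list(specs), len(subjects), seed=int(rng.integers(2**31)))
        geno.index = subjects.index
    else:
        specs = []
        geno = pd.DataFrame(index=subjects.index)
    return Cohort(subjects=subjects, genotypes=geno, specs=list(specs))


#: QC columns checked, in order, by :func:`apply_sample_flow`.
SAMPLE_FLOW_STAGES: tuple[tuple[str, str], ...] = (
    ("has_blood_sample", "no blood sample"),
    ("dna_quality_ok", "ineligible blood DNA quality"),
    ("snp_calls_complete", "failed SNP detection in >=1 assay"),
)


def sample_flow_frame(
    seed: int = 0,
    n_total: int = 3825,
    n_no_blood: int = 94,
    n_dna_fail: int = 1294,
    n_snp_fail: int = 557,
) -> pd.DataFrame:
    """Colonoscopy participants with sequential sample-QC flags.

    Defaults reproduce the reference selection flow: 3825 colonoscopied
    participants minus 94 without a blood sample, 1294 with ineligible DNA
    and 557 with a failed SNP assay leave 1880 analyzable subjects.  Flags
    are disjoint and assigned to a seeded random permutation of subjects.
    """
    n_excluded = n_no_blood + n_dna_fail + n_snp_fail
    if n_excluded > n_total:
        raise ValueError("exclusions exceed cohort size")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    has_blood = np.ones(n_total, dtype=bool)
    dna_ok = np.ones(n_total, dtype=bool)
    snp_ok = np.ones(n_total, dtype=bool)
    has_blood[order[:n_no_blood]] = False
    dna_ok[order[n_no_blood : n_no_blood + n_dna_fail]] = False
    snp_ok[order[n_no_blood + n_dna_fail : n_excluded]] = False
    return pd.DataFrame(
        {
            "has_blood_sample": has_blood,
            "dna_quality_ok": dna_ok,
            "snp_calls_complete": snp_ok,
        },
        index=_subject_ids(n_total, prefix="P"),
    )


def apply_sample_flow(
    frame: pd.DataFrame,
    stages: Sequence[tuple[str, str]] = SAMPLE_FLOW_STAGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply sequential QC exclusions; return (included, flow report).

    The report has one row per stage with the number removed at that stage
    and the number remaining, mirroring a sample-selection flow diagram.
    """
    remaining = frame
    records = [{"stage": "assessed", "n_removed": 0, "n_remaining": len(frame)}]
    for column, label in stages:
        if column not in remaining.columns:
            raise KeyError(f"sample-flow column {column!r} missing")
        keep = remaining[column].astype(bool)
        records.append(
            {
                "stage": label,
                "n_removed": int((~keep).sum()),
                "n_remaining": int(keep.sum()),
            }
        )
        remaining = remaining.loc[keep]
    report = pd.DataFrame.from_records(records)
    return remaining, report
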