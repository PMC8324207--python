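"""End-to-end pipeline: simulate → score → associate → project → screen.

The :class:`RunConfig` names the inputs (or requests simulation), the
scheme choices (HWE alpha, quantile convention, triage rule, adjustment
set, bootstrap draws) and the output directory.  Every emitted table
carries header comments with the tool version, the seed and a hash of the
configuration, and a run log records the same for each artifact, so a
fixed config + seed reproduces the output bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, absolute_risk, association, cohort, io, scores, screening
from .errors import ConfigError

STAGES = ("simulate", "score", "associate", "project", "screen")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (see module docstring)."""

    seed: int = 0
    out_dir: str = "crcrisk_out"
    stages: tuple[str, ...] = STAGES
    # inputs; None means "simulate" (cohort) or "use built-ins" (rates)
    subjects_path: str | None = None
    genotypes_path: str | None = None
    genotype_format: str = "dosage_tsv"  # or "vcf"
    weights_path: str | None = None  # PRS weights; default = panel weights
    rates_path: str | None = None
    dist_path: str | None = None
    use_default_rates: bool = False
    # simulation
    n_subjects: int = 2000
    n_snps: int = 24
    n_out_of_hwe: int = 5
    # scheme choices
    hwe_alpha: float = 0.05
    quantile_method: str = "linear"
    ls_scheme: str = "sex_median"
    prs_scheme: str = "percentile_90"
    triage_rule: str = "both_high"
    adjust: tuple[str, ...] = ("age",)
    n_boot: int = 500
    age_start: float = 50.0
    horizon: float = 10.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if "project" in self.stages and not (
            self.rates_path or self.use_default_rates
        ):
            raise ConfigError(
                "project stage requested but no rates_path given "
                "(set use_default_rates to use the synthetic built-in table)"
            )
        if self.triage_rule not in screening.PRESET_RULES:
            raise ConfigError(
                f"unknown triage rule {self.triage_rule!r}; "
                f"presets: {sorted(screening.PRESET_RULES)}"
            )
        for path in (self.subjects_path, self.genotypes_path, self.weights_path,
                     self.rates_path, self.dist_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path does not exist: {path}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    if "adjust" in raw:
        raw["adjust"] = tuple(raw["adjust"])
    return RunConfig(**raw)


def demo_config(out_dir: str, seed: int = 0) -> RunConfig:
    """Small self-contained configuration (simulates everything)."""
    return RunConfig(
        seed=seed, out_dir=out_dir, n_subjects=2000, use_default_rates=True,
        n_boot=200,
    )


class _Log:
    def __init__(self) -> None:
        self.lines: list[str] = []

    def add(self, msg: str) -> None:
        self.lines.append(msg)

    def write(self, path: Path) -> None:
        path.write_text("\n".join(self.lines) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; return artifact name → path.

    Stage order is fixed; a requested stage pulls in the artifacts of its
    predecessors (simulating them if no input paths are given).  The first
    hard error aborts the run with the stage name in the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # out_dir is excluded so identical analyses hash identically wherever written
    chash = io.config_hash({k: v for k, v in config.to_dict().items() if k != "out_dir"})
    meta = {"tool": f"crcrisk {__version__}", "seed": config.seed, "config": chash}
    log = _Log()
    log.add(f"crcrisk {__version__} | seed={config.seed} | config_hash={chash}")
    artifacts: dict[str, Path] = {}

    def _emit(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path, meta)
        artifacts[name] = path
        log.add(f"wrote {name} (seed={config.seed}, config={chash})")

    try:
        # ---- cohort ------------------------------------------------------
        if config.subjects_path:
            subjects = io.read_subjects(config.subjects_path)
            if config.genotypes_path:
                if config.genotype_format == "vcf":
                    weights, alleles = io.read_weights(config.weights_path)
                    genotypes, stubs = io.read_vcf(config.genotypes_path, alleles)
                    beta = dict(zip(weights.names, weights.betas))
                    specs = [
                        dataclasses.replace(s, weight=beta.get(s.snp_id, 0.0))
                        for s in stubs
                    ]
                else:
                    genotypes = io.read_dosages(config.genotypes_path)
                    specs = io.read_panel(config.weights_path) if config.weights_path else []
            else:
                genotypes, specs = pd.DataFrame(index=subjects.index), []
            cohort_obj = cohort.Cohort(subjects=subjects, genotypes=genotypes, specs=specs)
        else:
            specs = cohort.default_panel(
                config.n_snps, config.n_out_of_hwe, seed=config.seed
            )
            cc = cohort.CohortConfig(n_subjects=config.n_subjects, seed=config.seed)
            cohort_obj = cohort.simulate_subjects(cc, specs)
            _emit("subjects.csv", io.write_subjects, cohort_obj.subjects)
            _emit("genotypes.tsv", io.write_dosages, cohort_obj.genotypes)
            _emit("panel.tsv", io.write_panel, cohort_obj.specs)
            (out / "genotypes.vcf").unlink(missing_ok=True)
            io.write_vcf(cohort_obj.genotypes, cohort_obj.specs, out / "genotypes.vcf", meta)
            artifacts["genotypes.vcf"] = out / "genotypes.vcf"
            log.add(f"wrote genotypes.vcf (seed={config.seed}, config={chash})")
        if "simulate" == config.stages[-1]:
            log.write(out / "run.log")
            return artifacts
    except Exception as exc:
        raise type(exc)(f"[simulate] {exc}") from exc

    # ---- scores ----------------------------------------------------------
    try:
        retained, hwe_report = scores.filter_snps(
            cohort_obj.specs, cohort_obj.genotypes, alpha=config.hwe_alpha
        )
        _emit("hwe_report.tsv", lambda df, p, m: io.write_frame(df, p, m, sep="\t"), hwe_report)
        prs = scores.prs_scores(cohort_obj.genotypes, retained)
        subjects = cohort_obj.subjects.loc[prs.index]
        ls_weights = scores.estimate_lifestyle_weights(subjects)
        for sex, wv in ls_weights.items():
            _emit(f"ls_weights_{sex}.tsv", lambda w, p, m: io.write_weights(w, p, meta=m), wv)
        ls = scores.lifestyle_scores(subjects, ls_weights)
        ls_group = scores.categorize(
            ls, config.ls_scheme, sex=subjects["sex"], quantile_method=config.quantile_method
        )
        prs_group = scores.categorize(prs, config.prs_scheme, quantile_method=config.quantile_method)
        score_table = pd.DataFrame(
            {
                "lifestyle_score": ls,
                "ls_group": ls_group,
                "prs": prs,
                "prs_group": prs_group,
            }
        )
        _emit("scores.csv", lambda df, p, m: io.write_frame(df, p, m, index=True), score_table)
    except Exception as exc:
        raise type(exc)(f"[score] {exc}") from exc
    if "score" == config.stages[-1]:
        log.write(out / "run.log")
        return artifacts

    # ---- association -----------------------------------------------------
    try:
        or_table = association.run_contrast_suite(
            subjects, ls_group, prs_group, adjust=config.adjust
        )
        _emit("or_tables.csv", io.write_frame, or_table)
    except Exception as exc:
        raise type(exc)(f"[associate] {exc}") from exc

    # ---- absolute risk ---------------------------------------------------
    if "project" in config.stages:
        try:
            frames = []
            for sex in ("male", "female"):
                rates = (
                    io.read_rate_table(config.rates_path, sex=sex)
                    if config.rates_path
                    else absolute_risk.default_rate_table(sex)
                )
                if config.dist_path:
                    dist = io.read_risk_distribution(config.dist_path, sex=sex)
                else:
                    dist = _distribution_from_cohort(subjects, ls_group, prs_group, or_table, sex)
                results = absolute_risk.project_profile_table(
                    config.age_start, config.horizon, dist, rates,
                    n_boot=config.n_boot, seed=config.seed,
                )
                frames.append(absolute_risk.results_frame(results))
            _emit("absolute_risk.csv", io.write_frame, pd.concat(frames, ignore_index=True))
        except Exception as exc:
            raise type(exc)(f"[project] {exc}") from exc

    # ---- screening yield -------------------------------------------------
    if "screen" in config.stages:
        try:
            rules = [screening.PRESET_RULES[config.triage_rule]]
            for label in ("either_high", "ls_only", "prs_only"):
                if label != config.triage_rule:
                    rules.append(screening.PRESET_RULES[label])
            reports = screening.compare_scenarios(subjects, ls_group, prs_group, rules)
            _emit("yield.csv", io.write_frame, screening.reports_frame(reports))
        except Exception as exc:
            raise type(exc)(f"[screen] {exc}") from exc

    log.write(out / "run.log")
    artifacts["run.log"] = out / "run.log"
    return artifacts


def _distribution_from_cohort(
    subjects: pd.DataFrame,
    ls_group: pd.Series,
    prs_group: pd.Series,
    or_table: pd.DataFrame,
    sex: str,
) -> absolute_risk.RiskDistribution:
    """Risk-profile distribution estimated from the cohort itself.

    Profile prevalences come from the control series (the case-control
    stand-in for the source population); relative risks and their log-scale
    SEs come from the any-neoplasm OR table.
    """
    mask = (subjects["sex"] == sex) & (subjects["outcome"] == "control")
    expo = association.combined_exposure(ls_group, prs_group)[mask]
    prev = expo.value_counts(normalize=True)
    sub = or_table[(or_table["sex"] == sex) & (or_table["contrast"] == "any")]
    rows = []
    for level in association.EXPOSURE_LEVELS:
        r = sub[sub["exposure"] == level].iloc[0]
        orv = float(r["odds_ratio"])
        if level == association.EXPOSURE_LEVELS[0]:
            se = 0.0
        elif np.isfinite(r["ci_low"]):
            se = float((np.log(r["ci_high"]) - np.log(r["ci_low"])) / (2 * association.Z95))
        else:
            se = 0.0
        rows.append(
            {
                "sex": sex,
                "profile": level,
                "prevalence": float(prev.get(level, 0.0)),
                "rr": orv if np.isfinite(orv) else 1.0,
                "se_log_rr": se,
            }
        )
    frame = pd.DataFrame(rows)
    frame["prevalence"] /= frame["prevalence"].sum()
    return absolute_risk.RiskDistribution(frame)
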