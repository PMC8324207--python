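"""Exception and warning types shared across the package."""


class CrcRiskError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CrcRiskError, ValueError):
    """A SNP specification violates its invariants (e.g. raf outside (0,1))."""


class ModelSpecificationError(CrcRiskError, ValueError):
    """An outcome/FIT model produced an invalid probability."""


class MonomorphicSnpError(CrcRiskError, ValueError):
    """HWE testing requested for a SNP with sample allele frequency 0 or 1."""


class MissingCovariateError(CrcRiskError, KeyError):
    """A raw lifestyle factor needed for dichotomization is absent."""


class AlignmentError(CrcRiskError, ValueError):
    """Score values could not be aligned to weight names."""


class DegenerateStratificationError(CrcRiskError, ValueError):
    """All scores tied within a stratum; no cutpoint exists."""


class AliasingError(CrcRiskError, ValueError):
    """Rank-deficient design matrix in a logistic fit."""


class CoverageError(CrcRiskError, ValueError):
    """Projection interval not covered by the rate-table age bands."""


class InvalidDistributionError(CrcRiskError, ValueError):
    """A risk-profile distribution violates its invariants."""


class UncertaintySpecError(CrcRiskError, ValueError):
    """Bootstrap uncertainty requested but standard errors are missing."""


class TriageError(CrcRiskError, ValueError):
    """A subject lacks the risk-group labels required for triage."""


class UndefinedYieldError(CrcRiskError, ZeroDivisionError):
    """Yield metrics requested for a scenario with zero colonoscopies."""


class AlleleMismatchError(CrcRiskError, ValueError):
    """Risk allele in the weight file matches neither REF nor ALT."""


class UnsupportedRecordError(CrcRiskError, ValueError):
    """A VCF record is multiallelic or otherwise outside the GT-only contract."""


class DataError(CrcRiskError, ValueError):
    """Required per-subject data (e.g. a FIT result) is missing."""


class ConfigError(CrcRiskError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class SeparationWarning(UserWarning):
    """A logistic coefficient diverged, suggesting (quasi-)separation."""


class ContinuityCorrectionWarning(UserWarning):
    """A 2x2 table contained a zero cell; 0.5 was added to every cell."""
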