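"""Exception hierarchy.

Every user-facing failure mode maps onto one of these so the CLI can
translate them into exit codes (2 for configuration/usage problems,
1 for runtime/data problems) without string matching.
"""


class MethylearnError(Exception):
    """Base class for all package errors."""


class ConfigError(MethylearnError, ValueError):
    """Invalid parameter or option combination supplied by the caller."""


class ValidationError(MethylearnError, ValueError):
    """Input data violates an invariant (e.g. beta outside [0, 1])."""


class JoinError(MethylearnError, KeyError):
    """Sample-id keyed join between beta matrix and phenotype table failed."""

    def __init__(self, missing_in_pheno=(), missing_in_beta=()):
        self.missing_in_pheno = sorted(missing_in_pheno)
        self.missing_in_beta = sorted(missing_in_beta)
        parts = []
        if self.missing_in_pheno:
            parts.append(f"samples missing from pheno: {self.missing_in_pheno}")
        if self.missing_in_beta:
            parts.append(f"samples missing from beta: {self.missing_in_beta}")
        super().__init__("; ".join(parts) or "sample id mismatch")


class StratificationError(MethylearnError, ValueError):
    """A stratum is too small to split."""


class ContractError(MethylearnError, ValueError):
    """Operation called with arguments violating its contract (shape/ids)."""


class DataError(MethylearnError, ValueError):
    """Target or phenotype data unusable for the requested task."""


class TrainingDivergedError(MethylearnError, RuntimeError):
    """Loss became non-finite during optimisation."""

    def __init__(self, epoch, message=""):
        self.epoch = epoch
        super().__init__(message or f"training diverged at epoch {epoch}")


class ScanFailedError(MethylearnError, RuntimeError):
    """No completed trial in a hyperparameter scan."""


class InsufficientOverlapError(MethylearnError, ValueError):
    """Too few CpGs shared between two rankings."""
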