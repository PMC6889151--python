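"""Exception hierarchy.

Validation errors (bad inputs, malformed files) are distinct from
computation errors (degenerate fits, failed root finding) so callers --
in particular the command line interface -- can map them to different
exit codes.
"""


class GrsKitError(Exception):
    """Base class for all grskit errors."""


class ValidationError(GrsKitError):
    """Input violates a documented contract (bad value, bad file)."""


class FormatError(ValidationError):
    """A file could not be parsed into the expected structure."""


class ComputationError(GrsKitError):
    """A numeric procedure failed on otherwise valid input."""


class HarmonizationError(ValidationError):
    """Genotype alleles cannot be reconciled with the weight table."""


class MissingSnpError(ValidationError):
    """Weight-table SNPs absent from the genotype data."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            "weight-table SNPs absent from genotypes: " + ", ".join(self.snp_ids)
        )


class SeparationError(ComputationError):
    """Perfect separation: logistic MLE does not exist."""


class DegenerateScoreError(ComputationError):
    """Raw scores are constant; standardization undefined."""
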