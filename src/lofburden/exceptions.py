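"""Exception hierarchy for the burden-testing pipeline."""


class LofBurdenError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(LofBurdenError):
    """A configuration field is missing or out of range.

    Carries the offending field name in ``field``.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class InputError(LofBurdenError):
    """Misaligned or malformed pipeline inputs (phenotypes, VCF, tables)."""


class UndefinedSlopeError(LofBurdenError):
    """Raised when a variant has no genotype-positive read evidence, so the
    depth-conditional slope cannot be estimated.  Policy downstream: fail QC."""


class SeparationError(LofBurdenError):
    """Complete or quasi-complete separation in the logistic burden fit
    (all carriers in one outcome class, or a diverging coefficient).  The
    caller falls back to the exact 2x2 test."""
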