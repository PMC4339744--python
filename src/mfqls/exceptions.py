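"""Exception hierarchy for mfqls."""


class MfqlsError(Exception):
    """Base class for all mfqls errors."""


class PedigreeError(MfqlsError):
    """Structural problem in a pedigree (cycle, half-specified parents,
    duplicate ids, unknown parent reference)."""


class RelationshipMatrixError(MfqlsError):
    """Invalid relationship matrix (asymmetric, not positive definite)."""


class DataError(MfqlsError):
    """Malformed or mutually inconsistent input data."""


class DegenerateModelError(MfqlsError):
    """Null model cannot be fitted (constant phenotype, too few rows)."""


class NoTestError(MfqlsError):
    """No testable marker/phenotype remains after filtering."""
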