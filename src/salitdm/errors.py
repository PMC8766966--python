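"""Exception hierarchy for the salivary TDM pipeline."""


class SaliTDMError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(SaliTDMError):
    """Assay design violates its invariants (non-positive STD9, bad QC fractions...)."""


class UnderDeterminedError(SaliTDMError):
    """Too few distinct calibration levels for a two-coefficient fit."""


class RejectedCurveError(SaliTDMError):
    """Fitted curve is non-monotone (or has non-positive slope) on the working range."""


class UndefinedRSquaredError(SaliTDMError):
    """Weighted response variance is zero; r-squared is undefined."""


class OutOfModelError(SaliTDMError):
    """No real inverse-prediction root lies in the admissible concentration range."""


class InvalidNominalError(SaliTDMError):
    """Nominal concentration missing or non-positive where one is required."""


class InsufficientReplicatesError(SaliTDMError):
    """Fewer than two values available for a dispersion statistic."""


class UndefinedRSDError(SaliTDMError):
    """Mean of the values is zero; RSD is undefined."""


class UnmatchedDesignError(SaliTDMError):
    """A paired-role computation is missing its counterpart records."""


class InvalidISError(SaliTDMError):
    """Internal-standard area is zero or missing where an IS ratio is needed."""


class MethodInsensitiveError(SaliTDMError):
    """No dilution level satisfies the quantification (or detection) rules."""


class InvalidPairError(SaliTDMError):
    """Pre-device concentration non-positive in a retention pair."""


class InvalidLimitsError(SaliTDMError):
    """LOD/LLOQ pair violates LOD < LLOQ."""


class NoMatchesError(SaliTDMError):
    """Concordance requested on an empty (patient, drug) intersection."""


class IncompleteMatchError(SaliTDMError):
    """A three-matrix match is missing one or more matrices."""


class ParseError(SaliTDMError):
    """Malformed input table; message names the offending line."""
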