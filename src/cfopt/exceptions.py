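"""Exception hierarchy for cfopt.

Everything derives from :class:`CfoptError` so callers can catch the
package's failures with a single ``except`` clause.
"""


class CfoptError(Exception):
    """Base class for all cfopt errors."""


class InvalidCompositionError(CfoptError):
    """A composition's level indices do not fit the space's grid."""


class CapacityError(CfoptError):
    """More unique compositions requested than the unseen pool contains."""


class SchemaError(CfoptError):
    """A tabular input carries columns the pipeline does not recognise."""


class StockConcentrationError(CfoptError):
    """A stock is too concentrated: the required transfer volume falls
    below the dispenser's 12.5 nL minimum.

    Carries the offending reagent name and the maximum stock
    concentration that would make the transfer dispensable.
    """

    def __init__(self, reagent: str, max_stock_conc: float, message: str):
        super().__init__(message)
        self.reagent = reagent
        self.max_stock_conc = max_stock_conc


class OverVolumeError(CfoptError):
    """Requested reagent volumes exceed the reaction volume."""


class LayoutError(CfoptError):
    """A reagent has no source well in the source-plate layout."""


class IngestionError(CfoptError):
    """Wells expected from the well map are absent from a reader export."""


class NonPositiveSignalError(CfoptError):
    """Replicate fluorescences with non-positive mean cannot be CV-filtered."""


class DegenerateReferenceError(CfoptError):
    """Reference fluorescence does not exceed autofluorescence."""


class InsufficientControlsError(CfoptError):
    """Fewer than two shared control compositions between plates."""


class UnderdeterminedError(CfoptError):
    """Too few training rows to fit a model."""


class UnnormalizedInputError(CfoptError):
    """Model inputs look like raw concentrations instead of level fractions."""


class NotFittedError(CfoptError):
    """Prediction requested from an untrained ensemble."""


class FingerprintMismatchError(CfoptError):
    """A persisted model bundle does not match its recorded data fingerprint."""
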