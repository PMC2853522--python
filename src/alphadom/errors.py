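"""Exception hierarchy for the alphadom pipeline.

Every stage raises a subclass of :class:`AlphadomError`; the pipeline
driver catches these and reports the failing stage by name.
"""


class AlphadomError(Exception):
    """Base class for all alphadom errors."""


class ValidationError(AlphadomError):
    """Input violates a documented invariant (bad characters, ragged rows...)."""


class EmptyInputError(AlphadomError):
    """A file or collection that must be non-empty was empty."""


class ParameterError(AlphadomError):
    """A parameter value is outside its documented range."""


class DecompositionError(AlphadomError):
    """The array could not be tiled into monomers."""


class NoHorStructureError(AlphadomError):
    """No higher-order periodicity above the monomer level was detected."""


class AnchoringError(AlphadomError):
    """Restriction-site anchoring failed; suggests max_homogeneity instead."""


class EmptyCoreError(AlphadomError):
    """No HOR unit passed the homogeneous-core divergence filter."""


class OutlierCopyError(AlphadomError):
    """A copy aligned to the consensus below the identity floor."""


class UndefinedRateError(AlphadomError):
    """A rate was requested on an empty alignment."""


class OrderingRequiredError(AlphadomError):
    """Array-order-dependent operation called on an unordered copy set."""


class ComparisonError(AlphadomError):
    """Joint alignment of two repeat sets failed to produce a shared frame."""


class ConfigError(AlphadomError):
    """Pipeline configuration is malformed (unknown keys, missing inputs)."""
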