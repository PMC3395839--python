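"""Exception hierarchy for the aCGH pipeline."""


class BacCGHError(ValueError):
    """Base class for all package-specific errors."""


class InvalidParameterError(BacCGHError):
    """A configuration or function parameter is out of its valid range."""


class InvalidInputError(BacCGHError):
    """An input object violates a structural precondition."""


class MissingDataError(BacCGHError):
    """Required data (e.g. spots for a clone) is absent."""


class EmptyProfileError(BacCGHError):
    """An operation would leave a profile with no usable clones."""


class MissingCoverageError(BacCGHError):
    """A locus query falls outside every available segment."""


class DegenerateWeightsError(BacCGHError):
    """All concordance weights are zero; the weighted correlation is undefined."""
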