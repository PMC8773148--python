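"""Exception types shared across the package."""


class NemquantError(Exception):
    """Base class for all package-specific failures."""


class DataValidationError(NemquantError):
    """An input table or record violates the schema or an invariant.

    Messages name the offending row and column where applicable.
    """


class AdapterError(NemquantError):
    """A HyPhy result document or a dated tree could not be adapted."""


class InfeasibleSamplingError(NemquantError):
    """The dN-matched sampler cannot satisfy its interval contract."""
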