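"""Exception hierarchy used across the package."""


class MifamError(Exception):
    """Base class for all package errors."""


class FeaturizationError(MifamError):
    """A record could not be featurized (e.g. unparseable SMILES)."""


class FormatError(MifamError):
    """An input file violates the expected tabular/FASTA format."""


class ConfigurationError(MifamError):
    """A configuration value or backend requirement is not satisfiable."""


class EmptyDatasetError(MifamError):
    """Every record of an input set was rejected, or the set was empty."""
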