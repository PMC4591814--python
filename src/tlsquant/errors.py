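"""Exception hierarchy for tlsquant."""


class TlsQuantError(Exception):
    """Base class for all tlsquant errors."""


class SequenceError(TlsQuantError):
    """Invalid nucleotide sequence (empty, or non-ACGT characters)."""


class AnnealingError(TlsQuantError):
    """Primer, template and downstream oligo are not mutually complementary
    in the configuration a primer-extension substrate requires."""


class ConfigurationError(TlsQuantError):
    """Model/profile/conditions inconsistent with the substrate (e.g. a
    continuation vector whose length differs from the number of extendable
    positions)."""


class SchemaError(TlsQuantError):
    """Malformed interchange file: missing column, bad value, duplicate row,
    band length outside the substrate's product range, unknown substrate."""


class AggregationError(TlsQuantError):
    """No quantifiable lanes were available for replicate aggregation."""


class EfficiencyUndefinedError(TlsQuantError):
    """Bypass efficiency requested with a zero undamaged bypass probability."""


class BootstrapError(TlsQuantError):
    """Bootstrap resampling failed (too many degenerate resamples)."""
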