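"""Exception types shared across the pipeline."""


class DHSAtlasError(Exception):
    """Base class for all pipeline errors."""


class ParseError(DHSAtlasError, ValueError):
    """A malformed line in an input file; the message names the line."""


class SchemaError(DHSAtlasError, ValueError):
    """A table is missing required columns or violates uniqueness."""


class ConfigError(DHSAtlasError, ValueError):
    """A configuration value is outside its documented range."""
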