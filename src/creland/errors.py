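"""Exception types shared across the package."""


class CrelandError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CrelandError, ValueError):
    """An invalid configuration value (e.g. a non-tree lineage)."""


class FormatError(CrelandError, ValueError):
    """A malformed input file (overlapping segments, negative coordinates, ...)."""


class GenomeMismatchError(CrelandError, ValueError):
    """Two inputs that must share a genome do not (chromosome names or lengths differ)."""


class DependencyError(CrelandError, RuntimeError):
    """A pipeline stage was requested without its upstream outputs."""
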