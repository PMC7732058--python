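"""Exception hierarchy shared across the pipeline stages."""


class DamidError(Exception):
    """Base class for all damidseq errors."""


class ConfigError(DamidError):
    """A simulation or run configuration violates its invariants."""


class ParseError(DamidError):
    """A record in an input file could not be parsed."""


class AnnotationError(DamidError):
    """The gene annotation is unusable (e.g. overlapping count bins)."""


class EmptySampleError(DamidError):
    """A sample has no assigned reads, so per-million scaling is undefined."""


class InputError(DamidError):
    """Inputs to a comparison are inconsistent (mismatched universes, empty sets)."""


class StatisticsError(DamidError):
    """Not enough data to compute the requested statistic."""
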