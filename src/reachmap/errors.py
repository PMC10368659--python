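"""Exception hierarchy.

Config/format problems and data-quality problems are kept distinct so the
command-line layer can map them to different exit codes (2 vs 3).
"""


class ReachMapError(Exception):
    """Base class for all package errors."""


class ConfigError(ReachMapError):
    """Invalid configuration: bad geometry ordering, bad parameter values."""


class FormatError(ReachMapError):
    """A file does not conform to the documented CSV layout."""


class DataQualityError(ReachMapError):
    """Data are syntactically fine but unusable (reference-marker drift,
    too few samples, degenerate point clouds, self-intersecting loops)."""


class DegenerateAlphaError(DataQualityError):
    """No usable boundary exists even after automatic alpha relaxation."""
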