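"""Exception hierarchy shared across the pipeline.

Distinct classes map to distinct CLI exit codes (config=2, data=3,
convergence=4) so batch callers can tell a bad flag from a bad file.
"""


class CocoonSortError(Exception):
    """Base class for every labelled error raised by this package."""


class ConfigError(CocoonSortError):
    """Invalid configuration value (range, fraction, enum, seed)."""


class DataError(CocoonSortError):
    """Malformed or inconsistent input data (CSV column, label, image)."""


class DegenerateRegionError(CocoonSortError):
    """A region too small / collinear for the requested geometry."""


class ConvergenceError(CocoonSortError):
    """The classifier solver failed to converge."""
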