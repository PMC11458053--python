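"""Exception hierarchy.

Degenerate geometry (collinear landmarks, coincident midpoints, ...) is kept
distinct from malformed input (bad tables, missing files) so callers — in
particular the command-line layer — can map them to different exit codes.
"""


class LsccFrameError(Exception):
    """Base class for all package errors."""


class InputError(LsccFrameError):
    """Malformed or incomplete user input (tables, files, configuration)."""


class DegenerateGeometryError(LsccFrameError):
    """Landmark configuration does not define the requested geometry."""
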