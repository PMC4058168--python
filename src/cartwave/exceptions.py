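"""Error types raised by the pipeline stages."""


class CartwaveError(RuntimeError):
    """Base class for pipeline-stage failures."""


class NoWallFoundError(CartwaveError):
    """No cluster qualifies as a moving, visible vessel wall."""


class BoundaryNotFoundError(CartwaveError):
    """No usable run of columns with a detectable lumen-wall interface."""


class FormatError(CartwaveError):
    """Input files do not form a well-formed image sequence."""
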