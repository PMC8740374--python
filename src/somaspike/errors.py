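"""Exception hierarchy shared across the pipeline."""


class SomaspikeError(Exception):
    """Base class for package-specific failures."""


class ParameterError(SomaspikeError, ValueError):
    """A parameter value is outside its documented range."""


class CapacityError(SomaspikeError, RuntimeError):
    """A request exceeds what the inputs can supply (depth, sites, regions)."""


class LeakageError(SomaspikeError, RuntimeError):
    """Training data intersects the held-out evaluation regions."""


class EncodingMismatchError(SomaspikeError, RuntimeError):
    """Candidate stores or models disagree on feature-encoding version."""


class FormatError(SomaspikeError, ValueError):
    """An input file violates its declared format."""
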