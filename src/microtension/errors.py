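"""Exception hierarchy shared across the toolkit."""


class MicrotensionError(Exception):
    """Base class for all toolkit errors."""


class DomainError(MicrotensionError, ValueError):
    """A physical parameter is outside its admissible domain."""


class InputError(MicrotensionError, ValueError):
    """Input data violate a structural precondition (shape, ordering, coverage)."""


class DetectionError(MicrotensionError, RuntimeError):
    """Bead segmentation failed; the message names the failing filter."""
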