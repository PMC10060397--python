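"""Shared exception types."""


class CapabilityError(RuntimeError):
    """An operation was requested from an object that cannot provide it
    (e.g. oracle risk from a truth-stripped cohort, gradients from a
    non-differentiable model plug-in)."""
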