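"""Package-specific exception types."""


class DivergenceError(RuntimeError):
    """SGD training produced a non-finite loss (learning rate too large)."""


class DegenerateVarianceError(ValueError):
    """A variable with (near-)zero variance was passed to a correlation test."""
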