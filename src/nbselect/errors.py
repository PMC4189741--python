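"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Malformed or inconsistent user input (bad file, unknown sample, ...)."""


class PipelineError(RuntimeError):
    """Internal failure of a pipeline stage."""
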