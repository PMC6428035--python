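"""Exception types shared across the triage pipeline."""


class FormatError(ValueError):
    """Input file violates the documented VCF/TSV dialect."""


class NotFoundError(KeyError):
    """A knowledge-base lookup for a required record failed."""
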