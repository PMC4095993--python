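"""Exception hierarchy for pamscan.

All anticipated failure modes raise a :class:`PamscanError` subclass so the
command-line layer can turn them into one-line diagnostics with a nonzero
exit status; programming errors (contract violations) raise ``ValueError``.
"""


class PamscanError(Exception):
    """Base class for anticipated, user-facing pamscan errors."""


class FastaError(PamscanError):
    """Input FASTA missing, malformed, or empty where content is required."""


class ReportError(PamscanError):
    """Report cannot be written (unknown dialect, unwritable path)."""


class SynthSpecError(PamscanError):
    """Synthetic-genome specification is infeasible (plants exceed capacity)."""
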