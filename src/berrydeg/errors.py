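"""Exception hierarchy.

``InputError`` marks problems a user can fix (malformed tables, missing
samples, infeasible configuration); anything else escaping the library is an
internal error. The CLI maps the two onto exit codes 1 and 2.
"""


class BerrydegError(Exception):
    """Base class for all errors raised by berrydeg."""


class InputError(BerrydegError, ValueError):
    """Invalid user input: malformed file, missing column, bad parameter."""
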