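"""Exception types shared across the toolkit."""


class ValidationError(ValueError):
    """Raised when an input file, table, or domain object violates a contract."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit cannot produce a usable result at all.

    Routine non-convergence (hitting the iteration cap) is reported through
    result flags, not this exception; this is reserved for genuinely
    unusable problems (e.g. no estimable items).
    """
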