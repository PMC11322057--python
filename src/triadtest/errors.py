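"""Exception hierarchy for triadtest."""


class TriadTestError(Exception):
    """Base class for all triadtest errors."""


class PedFormatError(TriadTestError, ValueError):
    """A PED/linkage file row could not be parsed.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(TriadTestError, ValueError):
    """Input violates a data-model invariant (bad allele, duplicate ID, ...)."""


class DegenerateTableError(TriadTestError, ValueError):
    """A contingency table has a zero margin or is otherwise untestable."""


class EmptyTableError(TriadTestError, ValueError):
    """No genotyped individuals are available to build the requested table."""


class UndefinedStatisticError(TriadTestError, ValueError):
    """The requested statistic is undefined (e.g. TDT with a + b = 0)."""


class MendelianInconsistencyError(TriadTestError, ValueError):
    """A trio's genotypes admit no Mendelian transmission assignment."""


class SimulationError(TriadTestError, RuntimeError):
    """Cohort simulation could not satisfy the requested design."""


class FixtureError(TriadTestError, ValueError):
    """A packaged reproduction fixture is missing or malformed."""
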