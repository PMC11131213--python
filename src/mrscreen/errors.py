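"""Typed signals used across the pipeline.

Estimation-stage conditions (no instruments, too few instruments, collinear
design) are recoverable at screen level — ``run_pair`` downgrades them to a
``skipped``/partial result — so they get their own exception types instead of
bare ``ValueError``.
"""


class MrScreenError(Exception):
    """Base class for all package-specific errors."""


class EmptyInstrumentSetError(MrScreenError):
    """No SNPs remain at a stage that needs at least one."""


class InsufficientInstrumentsError(MrScreenError):
    """Fewer SNPs than the method's minimum (e.g. MR-Egger needs 3)."""


class DegenerateDesignError(MrScreenError):
    """Design matrix is collinear (all exposure effects equal in MR-Egger)."""


class MissingEafError(MrScreenError):
    """Effect-allele frequency required but absent (R^2 / F computation)."""
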