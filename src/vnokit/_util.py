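"""Shared helpers: error types and the rounding convention used in reports."""

from __future__ import annotations

import decimal


class DataError(ValueError):
    """Raised when input data violate the pipeline's contracts.

    Distinct from plain ``ValueError`` (bad arguments) so callers can
    separate malformed data files from programming errors.
    """


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Headline percentages and fold changes are reported at printed precision
    with the convention that 22.5 -> 23 and -22.5 -> -23.  Python's builtin
    ``round`` is banker's rounding and binary floats make exact halves
    unreliable (e.g. ``(8.42 + 8.21) / 2`` stores as 8.314999...), so the
    value is routed through its shortest decimal repr first.
    """
    d = decimal.Decimal(repr(float(x)))
    exp = decimal.Decimal(1).scaleb(-ndigits)
    out = float(d.quantize(exp, rounding=decimal.ROUND_HALF_UP))
    return out


def sem(values, ddof: int = 1):
    """Standard error of the mean; ``None`` for a single value."""
    import numpy as np

    v = np.asarray(values, dtype=float)
    if v.size <= ddof:
        return None
    return float(v.std(ddof=ddof) / np.sqrt(v.size))
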