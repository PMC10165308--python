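"""Value ± standard-uncertainty pairs and the concise parenthesis notation.

A measured quantity is carried around as a :class:`UValue` — a value, a
standard uncertainty ``u`` and a unit string.  For display the package uses
the concise notation common in metrology: ``409(14) MBq`` means a value of
409 with a standard uncertainty of 14 expressed in units of the last
displayed digits, ``2.00(6)`` means 2.00 ± 0.06.

Rendering convention: the uncertainty is shown to one significant digit,
or two when its leading digit is 1 and the second digit is informative
(0.014 renders as ``(14)``, but an exact 0.01 stays ``(1)``); the value
is rounded (half-even) to the same last digit.  ``u = 0`` renders
without parentheses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .errors import ConciseParseError

__all__ = ["UValue", "format_concise", "parse_concise"]


@dataclass(frozen=True)
class UValue:
    """A value with a standard uncertainty.

    Parameters
    ----------
    value : float
        Best estimate.
    u : float
        Standard uncertainty, ``u >= 0``.
    unit : str
        Unit string, purely informational.
    """

    value: float
    u: float = 0.0
    unit: str = ""

    def __post_init__(self):
        if not (self.u >= 0.0):
            raise ValueError(f"standard uncertainty must be >= 0, got {self.u}")

    @property
    def rel_u(self) -> float:
        """Relative standard uncertainty |u / value| (inf for value 0, u > 0)."""
        if self.u == 0.0:
            return 0.0
        if self.value == 0.0:
            return math.inf
        return abs(self.u / self.value)

    def scaled(self, factor: float, unit: str | None = None) -> "UValue":
        """Multiply by an exact scalar; value and u scale together."""
        return UValue(self.value * factor, self.u * abs(factor),
                      self.unit if unit is None else unit)

    def combined(self, other: "UValue", value: float, unit: str = "") -> "UValue":
        """New UValue with relative uncertainties combined in quadrature."""
        rel = math.hypot(self.rel_u, other.rel_u)
        return UValue(value, abs(value) * rel, unit)

    def __str__(self) -> str:
        s = format_concise(self)
        return f"{s} {self.unit}" if self.unit else s

    def with_unit(self, unit: str) -> "UValue":
        return replace(self, unit=unit)


def _display_u(u: float) -> tuple[int, int]:
    """Displayed uncertainty digits and the exponent of the last digit.

    Returns ``(u_disp, e_last)`` with ``u ≈ u_disp · 10**e_last``.
    """
    e = math.floor(math.log10(u))
    lead = int(u / 10.0 ** e)  # first significant digit (truncated)
    if lead == 1:
        u_disp = int(round(u / 10.0 ** (e - 1)))
        if u_disp % 10 != 0:   # 14 -> "(14)", but an exact 0.01 stays "(1)"
            return u_disp, e - 1
        return u_disp // 10, e
    u_disp = int(round(u / 10.0 ** e))
    if u_disp >= 10:           # e.g. 0.96 rounds up to 1.0
        return 1, e + 1
    return u_disp, e


def _round_half_even(x: float, exponent: int) -> float:
    """Round x to the decimal place 10**exponent, ties to even."""
    scaled = x / 10.0 ** exponent
    return round(scaled) * 10.0 ** exponent


def format_concise(x: UValue) -> str:
    """Render a UValue in parenthesis notation, e.g. ``UValue(409, 14)`` → ``"409(14)"``.

    The unit is *not* appended; use ``str(x)`` for that.
    """
    if x.u == 0.0:
        return f"{x.value:g}"
    u_disp, e = _display_u(x.u)
    if e < 0:
        ndec = -e
        val = _round_half_even(x.value, e)
        return f"{val:.{ndec}f}({u_disp:d})"
    # last digit at or above the units place: parentheses carry the full
    # integer uncertainty, value rounded to the same place
    val = _round_half_even(x.value, e)
    return f"{val:.0f}({u_disp * 10 ** e:d})"


_CONCISE_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.(\d+))?)\s*(?:\((\d+)\))?\s*([A-Za-z%][^()]*)?$"
)


def parse_concise(s: str) -> UValue:
    """Parse concise notation back into a UValue.

    ``"0.6(8)"`` → value 0.6, u 0.8; ``"409(14) MBq"`` → 409 ± 14 MBq;
    a bare number parses with u = 0.
    """
    m = _CONCISE_RE.match(s)
    if m is None:
        raise ConciseParseError(f"not a concise value(uncertainty) string: {s!r}")
    value_s, decimals, paren, unit = m.groups()
    value = float(value_s)
    if paren is None:
        u = 0.0
    else:
        ndec = len(decimals) if decimals is not None else 0
        u = int(paren) * 10.0 ** (-ndec)
    return UValue(value, u, (unit or "").strip())
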