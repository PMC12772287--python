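"""First-order (Taylor / delta-method) uncertainty propagation.

:class:`Uncertain` pairs a value with a standard uncertainty and propagates
the uncertainty through elementary arithmetic assuming *independent* operands:

* sums and differences add sigmas in quadrature,
* products and ratios add *relative* sigmas in quadrature,
* ``log(x)`` has sigma ``sx / x`` and ``exp(x)`` has sigma ``exp(x) * sx``.

This is the standard propagation contract of measurement-uncertainty
utilities; correlated operands are out of scope, so expressions that reuse
the same measured quantity (``x / x``) are treated as if the two occurrences
were independent measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import DomainError

__all__ = ["Uncertain", "log", "exp"]


@dataclass(frozen=True)
class Uncertain:
    """A value with a first-order standard uncertainty (same units)."""

    value: float
    sigma: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise DomainError(f"non-finite value {self.value!r}")
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise DomainError(f"sigma must be finite and >= 0, got {self.sigma!r}")

    # -- helpers ---------------------------------------------------------
    @property
    def relative(self) -> float:
        """Relative uncertainty sigma/|value|."""
        if self.value == 0:
            raise DomainError("relative uncertainty undefined at value 0")
        return self.sigma / abs(self.value)

    @staticmethod
    def _coerce(other) -> "Uncertain":
        if isinstance(other, Uncertain):
            return other
        if isinstance(other, (int, float)):
            return Uncertain(float(other), 0.0)
        return NotImplemented  # type: ignore[return-value]

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        o = self._coerce(other)
        if o is NotImplemented:
            return NotImplemented
        return Uncertain(self.value + o.value, math.hypot(self.sigma, o.sigma))

    __radd__ = __add__

    def __sub__(self, other):
        o = self._coerce(other)
        if o is NotImplemented:
            return NotImplemented
        return Uncertain(self.value - o.value, math.hypot(self.sigma, o.sigma))

    def __rsub__(self, other):
        o = self._coerce(other)
        if o is NotImplemented:
            return NotImplemented
        return o - self

    def __neg__(self):
        return Uncertain(-self.value, self.sigma)

    def __mul__(self, other):
        o = self._coerce(other)
        if o is NotImplemented:
            return NotImplemented
        value = self.value * o.value
        # d(xy) = y dx + x dy; quadrature of the two terms
        sigma = math.hypot(o.value * self.sigma, self.value * o.sigma)
        return Uncertain(value, sigma)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        if o is NotImplemented:
            return NotImplemented
        if o.value == 0:
            raise DomainError("division by a value of 0")
        value = self.value / o.value
        sigma = math.hypot(self.sigma / o.value, self.value * o.sigma / o.value**2)
        return Uncertain(value, abs(sigma))

    def __rtruediv__(self, other):
        o = self._coerce(other)
        if o is NotImplemented:
            return NotImplemented
        return o / self

    def log(self) -> "Uncertain":
        """Natural logarithm; requires a strictly positive value."""
        if self.value <= 0:
            raise DomainError(f"log of non-positive value {self.value!r}")
        return Uncertain(math.log(self.value), self.sigma / self.value)

    def exp(self) -> "Uncertain":
        v = math.exp(self.value)
        return Uncertain(v, v * self.sigma)

    def __repr__(self):  # compact, unit-agnostic
        return f"Uncertain({self.value:.6g} ± {self.sigma:.3g})"


def log(x: Uncertain) -> Uncertain:
    """Natural log with first-order propagation (module-level convenience)."""
    return x.log()


def exp(x: Uncertain) -> Uncertain:
    return x.exp()
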