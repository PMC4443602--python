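"""Dimension-aware scalar arithmetic.

Every number that flows through the dosimetry models is a :class:`Quantity`
carrying a signed exponent vector over the three base dimensions (mass,
length, time).  This is what makes dimensional bookkeeping mechanical: a
concentration divided by a mass density cancels to a *dimensionless* number,
and :func:`assert_dimension` reports that such a value is not a concentration,
however it is labelled.

The unit registry is a small JSON document of atomic units (``mg``, ``m``,
``day``, ``ul``, ``g``, ...) with scales to the canonical basis mg / m / day.
Compound unit strings are parsed from those atoms, e.g. ``"mg/m^3"``,
``"g/cm^3"``, ``"m^3/(day*kg)"``, ``"um^3"``.

Counts (cells, breaths) are deliberately treated as dimensionless: daily
ventilation already folds tidal volume and respiratory rate into one volume
per day, so no extra base dimension is needed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterator

__all__ = [
    "Dimension",
    "Quantity",
    "Q",
    "DimensionError",
    "UnitError",
    "DimensionReport",
    "convert",
    "combine",
    "assert_dimension",
    "DIMENSIONLESS",
    "MASS",
    "LENGTH",
    "TIME",
    "AREA",
    "VOLUME",
    "CONCENTRATION",
    "NAMED_DIMENSIONS",
]


class UnitError(ValueError):
    """Unknown or unparsable unit string."""


class DimensionError(ValueError):
    """Operation applied across incompatible dimensions."""


@dataclass(frozen=True)
class Dimension:
    """Signed exponent vector over the base dimensions mass, length, time."""

    mass: int = 0
    length: int = 0
    time: int = 0

    def __add__(self, other: "Dimension") -> "Dimension":
        return Dimension(self.mass + other.mass, self.length + other.length,
                         self.time + other.time)

    def __sub__(self, other: "Dimension") -> "Dimension":
        return Dimension(self.mass - other.mass, self.length - other.length,
                         self.time - other.time)

    def __mul__(self, n: int) -> "Dimension":
        return Dimension(self.mass * n, self.length * n, self.time * n)

    def __iter__(self) -> Iterator[int]:
        yield self.mass
        yield self.length
        yield self.time

    @property
    def is_dimensionless(self) -> bool:
        return self.mass == 0 and self.length == 0 and self.time == 0

    def __str__(self) -> str:
        if self.is_dimensionless:
            return "dimensionless"
        parts = []
        for name, exp in zip(("mass", "length", "time"), self):
            if exp == 1:
                parts.append(name)
            elif exp != 0:
                parts.append(f"{name}^{exp}")
        return "·".join(parts)


DIMENSIONLESS = Dimension()
MASS = Dimension(mass=1)
LENGTH = Dimension(length=1)
TIME = Dimension(time=1)
AREA = Dimension(length=2)
VOLUME = Dimension(length=3)
#: mass per volume — the dimension of both an air concentration (mg/m^3)
#: and a material density (g/cm^3); only the conventional scale differs.
CONCENTRATION = Dimension(mass=1, length=-3)

NAMED_DIMENSIONS: dict[str, Dimension] = {
    "dimensionless": DIMENSIONLESS,
    "mass": MASS,
    "length": LENGTH,
    "time": TIME,
    "area": AREA,
    "volume": VOLUME,
    "concentration": CONCENTRATION,
    "density": CONCENTRATION,
    "rate": Dimension(time=-1),
}


def _load_registry() -> dict[str, tuple[Dimension, float]]:
    text = resources.files("dustdose.data").joinpath("units.json").read_text()
    raw = json.loads(text)["units"]
    return {
        name: (Dimension(*entry["dim"]), float(entry["scale"]))
        for name, entry in raw.items()
    }


_REGISTRY = _load_registry()

# unicode conveniences accepted in unit strings
_NORMALIZE = str.maketrans({"µ": "u", "μ": "u", "·": "*", "³": None, "²": None})


def _normalize(unit: str) -> str:
    u = unit.strip()
    u = u.replace("³", "^3").replace("²", "^2")
    u = u.translate(str.maketrans({"µ": "u", "μ": "u", "·": "*", " ": None}))
    return u


class _UnitParser:
    """Recursive-descent parser for compound unit expressions.

    Grammar::

        expr   := term (("*" | "/") term)*
        term   := atom ["^" signed-int] | "(" expr ")" ["^" signed-int]
    """

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def parse(self) -> tuple[Dimension, float]:
        dim, scale = self._expr()
        if self.pos != len(self.text):
            raise UnitError(f"trailing characters in unit {self.text!r}")
        return dim, scale

    def _expr(self) -> tuple[Dimension, float]:
        dim, scale = self._term()
        while self.pos < len(self.text) and self.text[self.pos] in "*/":
            op = self.text[self.pos]
            self.pos += 1
            d2, s2 = self._term()
            if op == "*":
                dim, scale = dim + d2, scale * s2
            else:
                dim, scale = dim - d2, scale / s2
        return dim, scale

    def _term(self) -> tuple[Dimension, float]:
        if self.pos < len(self.text) and self.text[self.pos] == "(":
            self.pos += 1
            dim, scale = self._expr()
            if self.pos >= len(self.text) or self.text[self.pos] != ")":
                raise UnitError(f"unbalanced parentheses in {self.text!r}")
            self.pos += 1
        else:
            start = self.pos
            while self.pos < len(self.text) and (self.text[self.pos].isalnum()):
                self.pos += 1
            atom = self.text[start:self.pos]
            if not atom:
                raise UnitError(f"expected unit atom at position {start} in {self.text!r}")
            if atom not in _REGISTRY:
                raise UnitError(f"unknown unit {atom!r} (in {self.text!r})")
            dim, scale = _REGISTRY[atom]
        if self.pos < len(self.text) and self.text[self.pos] == "^":
            self.pos += 1
            start = self.pos
            if self.pos < len(self.text) and self.text[self.pos] in "+-":
                self.pos += 1
            while self.pos < len(self.text) and self.text[self.pos].isdigit():
                self.pos += 1
            try:
                n = int(self.text[start:self.pos])
            except ValueError:
                raise UnitError(f"bad exponent in {self.text!r}") from None
            dim, scale = dim * n, scale**n
        return dim, scale


def parse_unit(unit: str) -> tuple[Dimension, float]:
    """Resolve a unit string to (dimension, scale-to-canonical)."""
    u = _normalize(unit)
    if u in ("", "1", "dimensionless"):
        return DIMENSIONLESS, 1.0
    return _UnitParser(u).parse()


# preferred display units for derived dimensions produced by arithmetic
_PREFERRED: dict[Dimension, str] = {
    DIMENSIONLESS: "",
    MASS: "mg",
    LENGTH: "m",
    TIME: "day",
    AREA: "m^2",
    VOLUME: "m^3",
    CONCENTRATION: "mg/m^3",
    Dimension(time=-1): "1/day",
    Dimension(mass=1, time=-1): "mg/day",
    Dimension(length=3, time=-1): "m^3/day",
}


@dataclass(frozen=True)
class Quantity:
    """A physical scalar: magnitude in a display unit plus its dimension.

    Internally the value is held in the canonical mg/m/day basis so that
    arithmetic never depends on the display unit.
    """

    canonical: float
    dimension: Dimension
    unit: str

    @property
    def magnitude(self) -> float:
        """Numeric value expressed in this quantity's display unit."""
        _, scale = parse_unit(self.unit)
        return self.canonical / scale

    def to(self, unit: str) -> "Quantity":
        dim, _ = parse_unit(unit)
        if dim != self.dimension:
            raise DimensionError(
                f"cannot convert {self.dimension} quantity to {unit!r} "
                f"(dimension {dim})")
        return Quantity(self.canonical, self.dimension, _normalize(unit))

    def magnitude_in(self, unit: str) -> float:
        return self.to(unit).magnitude

    # -- arithmetic ---------------------------------------------------------

    def __mul__(self, other):
        if isinstance(other, Quantity):
            dim = self.dimension + other.dimension
            return Quantity(self.canonical * other.canonical, dim,
                            _PREFERRED.get(dim, _canonical_label(dim)))
        return Quantity(self.canonical * float(other), self.dimension, self.unit)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Quantity):
            if other.canonical == 0:
                raise ZeroDivisionError("division by zero-magnitude quantity")
            dim = self.dimension - other.dimension
            return Quantity(self.canonical / other.canonical, dim,
                            _PREFERRED.get(dim, _canonical_label(dim)))
        return Quantity(self.canonical / float(other), self.dimension, self.unit)

    def __rtruediv__(self, other):
        if self.canonical == 0:
            raise ZeroDivisionError("division by zero-magnitude quantity")
        dim = DIMENSIONLESS - self.dimension
        return Quantity(float(other) / self.canonical, dim,
                        _PREFERRED.get(dim, _canonical_label(dim)))

    def __add__(self, other: "Quantity") -> "Quantity":
        if not isinstance(other, Quantity):
            return NotImplemented
        if other.dimension != self.dimension:
            raise DimensionError(
                f"cannot add {other.dimension} to {self.dimension}")
        return Quantity(self.canonical + other.canonical, self.dimension, self.unit)

    def __sub__(self, other: "Quantity") -> "Quantity":
        if not isinstance(other, Quantity):
            return NotImplemented
        if other.dimension != self.dimension:
            raise DimensionError(
                f"cannot subtract {other.dimension} from {self.dimension}")
        return Quantity(self.canonical - other.canonical, self.dimension, self.unit)

    def __neg__(self) -> "Quantity":
        return Quantity(-self.canonical, self.dimension, self.unit)

    def __pow__(self, p) -> "Quantity":
        if self.dimension.is_dimensionless:
            return Quantity(self.canonical ** p, DIMENSIONLESS, "")
        if isinstance(p, int):
            dim = self.dimension * p
            return Quantity(self.canonical ** p, dim,
                            _PREFERRED.get(dim, _canonical_label(dim)))
        raise DimensionError(
            "non-integer powers are defined only for dimensionless quantities")

    def __float__(self) -> float:
        if not self.dimension.is_dimensionless:
            raise DimensionError(
                f"cannot coerce {self.dimension} quantity to a bare float")
        return self.canonical

    # -- comparisons (same dimension only) ----------------------------------

    def _cmp_value(self, other: "Quantity") -> float:
        if not isinstance(other, Quantity):
            raise DimensionError("quantities compare only with quantities")
        if other.dimension != self.dimension:
            raise DimensionError(
                f"cannot compare {self.dimension} with {other.dimension}")
        return other.canonical

    def __lt__(self, other):
        return self.canonical < self._cmp_value(other)

    def __le__(self, other):
        return self.canonical <= self._cmp_value(other)

    def __gt__(self, other):
        return self.canonical > self._cmp_value(other)

    def __ge__(self, other):
        return self.canonical >= self._cmp_value(other)

    def is_close(self, other: "Quantity", rel_tol: float = 1e-12) -> bool:
        return math.isclose(self.canonical, self._cmp_value(other), rel_tol=rel_tol)

    def __repr__(self) -> str:
        unit = self.unit or "dimensionless"
        return f"<Quantity {self.magnitude:g} {unit}>"


def _canonical_label(dim: Dimension) -> str:
    num, den = [], []
    for atom, exp in zip(("mg", "m", "day"), dim):
        if exp > 0:
            num.append(atom if exp == 1 else f"{atom}^{exp}")
        elif exp < 0:
            den.append(atom if exp == -1 else f"{atom}^{-exp}")
    label = "*".join(num) or "1"
    if den:
        label += "/" + ("*".join(den) if len(den) == 1 else "(" + "*".join(den) + ")")
    return "" if label == "1" else label


def Q(magnitude: float, unit: str = "") -> Quantity:
    """Construct a quantity from a magnitude and a unit string."""
    dim, scale = parse_unit(unit)
    return Quantity(float(magnitude) * scale, dim, _normalize(unit))


def convert(q: Quantity, target_unit: str) -> Quantity:
    """Express ``q`` in ``target_unit``; the dimension must match."""
    return q.to(target_unit)


def combine(a: Quantity, operator: str, b: Quantity) -> Quantity:
    """Multiply or divide two quantities; exponent vectors add or subtract."""
    if operator == "multiply":
        return a * b
    if operator == "divide":
        return a / b
    raise ValueError(f"operator must be 'multiply' or 'divide', got {operator!r}")


@dataclass(frozen=True)
class DimensionReport:
    """Outcome of a dimension assertion; never raises, always reports."""

    ok: bool
    actual: Dimension
    expected: Dimension
    message: str

    def __bool__(self) -> bool:
        return self.ok


def assert_dimension(q: Quantity, expected: str | Dimension) -> DimensionReport:
    """Check that ``q`` has the expected dimension and report pass/fail.

    ``expected`` may be a named dimension ("concentration", "time", ...), a
    unit string ("mg/m^3"), or a :class:`Dimension`.
    """
    if isinstance(expected, Dimension):
        exp = expected
    elif expected in NAMED_DIMENSIONS:
        exp = NAMED_DIMENSIONS[expected]
    else:
        exp, _ = parse_unit(expected)
    if q.dimension == exp:
        return DimensionReport(True, q.dimension, exp,
                               f"dimension {q.dimension} as expected")
    # concentration reads better as mass/volume in a failure report
    names = {CONCENTRATION: "mass/volume"}
    return DimensionReport(
        False, q.dimension, exp,
        f"{names.get(q.dimension, str(q.dimension))} ≠ "
        f"{names.get(exp, str(exp))}")
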