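"""Shared numeric helpers: exact rationals vs. tolerant floats.

Two numeric modes run through the whole package.  In *exact* mode every
matrix entry is a :class:`fractions.Fraction` stored in a numpy array of
dtype ``object``; all linear algebra is then exact.  In *float* mode
entries are ``float64`` and rank/membership decisions use a relative
tolerance.  Floats that enter exact computations are promoted with
``Fraction(float)``, which is always exact for finite doubles.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Any, Iterable

import numpy as np

#: default relative tolerance for float-mode rank decisions
DEFAULT_TOL = 1e-9

Numeric = int | float | Fraction | str


def frac(x: Numeric) -> Fraction:
    """Coerce ``x`` to an exact :class:`Fraction`.

    Accepts ints, Fractions, strings like ``"3"`` or ``"-1/3"`` and
    floats (converted exactly, not via decimal rounding).
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, bool):
        raise TypeError("bool is not a numeric entry")
    if isinstance(x, (int, np.integer)):
        return Fraction(int(x))
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, (float, np.floating)):
        return Fraction(float(x))
    raise TypeError(f"cannot interpret {x!r} as a rational number")


def exact_array(data: Any) -> np.ndarray:
    """Build an object-dtype array of Fractions from nested data."""
    arr = np.array(data, dtype=object)
    out = np.empty(arr.shape, dtype=object)
    for idx in np.ndindex(*arr.shape) if arr.shape else [()]:
        out[idx] = frac(arr[idx])
    return out


def float_array(a: np.ndarray) -> np.ndarray:
    """Demote an array (possibly of Fractions) to float64."""
    return np.asarray(a, dtype=float) if a.dtype != object else np.array(
        [[float(x) for x in row] for row in a.reshape(a.shape[0], -1)],
        dtype=float,
    ).reshape(a.shape)


def is_exact(a: np.ndarray) -> bool:
    return a.dtype == object


def zeros_exact(shape) -> np.ndarray:
    out = np.empty(shape, dtype=object)
    out[...] = Fraction(0)
    return out


def fmt_number(x: Any) -> Any:
    """JSON-friendly rendering: integers as int, rationals as 'p/q'."""
    if isinstance(x, Fraction):
        if x.denominator == 1:
            return int(x)
        return f"{x.numerator}/{x.denominator}"
    if isinstance(x, (int, np.integer)):
        return int(x)
    return float(x)


def fmt_vector(v: Iterable[Any]) -> list:
    return [fmt_number(x) for x in v]


def fmt_matrix(m: np.ndarray) -> list:
    return [fmt_vector(row) for row in m]
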