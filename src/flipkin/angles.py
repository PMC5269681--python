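"""Periodic-angle bookkeeping for the flipping coordinate.

The flipping pseudo-dihedral lives on a 360 degree circle, but umbrella
windows span more than half a period (e.g. -320 to +38 degrees), so the
analysis works on an *unwrapped branch*: plain real numbers, with explicit
helpers to wrap back to (-180, 180], to move an angle onto the branch nearest
a reference, and to measure signed arcs in a chosen rotation sense.

The positive rotation sense corresponds to flipping through the major groove,
the negative sense to flipping through the minor groove.
"""

from __future__ import annotations

import numpy as np

from flipkin.constants import PERIOD_DEG


def wrap_angle(angle, period: float = PERIOD_DEG):
    """Wrap an angle (degrees) to the principal branch (-period/2, period/2].

    Accepts scalars or arrays.
    """
    a = np.asarray(angle, dtype=float)
    w = np.mod(a, period)
    w = np.where(w > period / 2, w - period, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def angular_path(start: float, end: float, direction: str = "positive",
                 period: float = PERIOD_DEG) -> float:
    """Signed angular displacement from ``start`` to ``end`` (degrees).

    ``direction="positive"`` returns the arc traversed rotating in the
    positive sense, in [0, period); ``"negative"`` the arc rotating the other
    way, in (-period, 0].  If start and end are congruent modulo the period
    both directions give 0.

    For the flipping coordinate: from the B-form intra-helical minimum at
    29 deg to the extra-helical state at -135 deg the major-groove (positive)
    arc is 196 deg; from the enzyme-deformed minimum at 69 deg it is 156 deg,
    and the minor-groove (negative) turn is -204 deg.
    """
    d = float(np.mod(end - start, period))
    # Displacements congruent to zero within float resolution collapse to 0
    # so both rotation senses agree on them.
    if d >= period or d - period <= -period:
        d = 0.0
    if direction == "positive":
        return d
    if direction == "negative":
        return d - period if d > 0.0 else 0.0
    raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")


def unwrap_to_branch(angle, reference, period: float = PERIOD_DEG):
    """Shift ``angle`` by whole periods onto the branch nearest ``reference``.

    Returns angle + k*period for the integer k minimizing
    ``|result - reference|``; the result satisfies
    ``|result - reference| <= period/2``.  Vectorized over ``angle``.
    """
    a = np.asarray(angle, dtype=float)
    ref = np.asarray(reference, dtype=float)
    out = a + period * np.round((ref - a) / period)
    if np.ndim(angle) == 0 and np.ndim(reference) == 0:
        return float(out)
    return out
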