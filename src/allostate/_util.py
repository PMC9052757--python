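"""Shared numerical helpers: periodic angle arithmetic and constants."""
from __future__ import annotations

import numpy as np

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872


def kt_kcal(temperature: float) -> float:
    """kT in kcal/mol at the given temperature (K)."""
    return KB_KCAL * temperature


def wrap_angle(x):
    """Wrap angles (degrees) into the interval (-180, 180].

    Works elementwise on arrays; NaN propagates.
    """
    x = np.asarray(x, dtype=float)
    w = -((-x + 180.0) % 360.0) + 180.0
    # the modulo maps +180 -> +180 and -180 -> +180, which is what we want
    return w if w.ndim else float(w)


def periodic_delta(a, b, period=360.0):
    """Minimum-image difference a - b on a circle of the given period."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    half = period / 2.0
    d = (d + half) % period - half
    return d if np.ndim(d) else float(d)
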