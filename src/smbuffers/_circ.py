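"""Circular (task-angle) helpers.

All task angles are in degrees on [0, 360). A full trial spans 360 degrees
regardless of task periodicity (ABCD: 4 states x 90 deg; ABCDE: 5 x 72 deg).
"""
from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) to [0, 360)."""
    return np.mod(angle, 360.0)


def signed_deg(angle):
    """Map angle(s) to the signed interval (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    return np.where(a > 180.0, a - 360.0, a)


def circ_dist_deg(a, b=0.0):
    """Circular distance |a - b| folded to [0, 180]."""
    return np.abs(signed_deg(np.asarray(a, dtype=float) - b))


def forward_dist_deg(lag_a, lag_b):
    """Unsigned forward (along-ring) separation of two lags, in [0, 360).

    Lags live on [0, 360); the forward distance of a pair is the arc from the
    smaller to the larger lag, i.e. ``|lag_b - lag_a|``.
    """
    return float(abs(lag_b - lag_a)) % 360.0
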