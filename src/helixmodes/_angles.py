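"""Utilities for angles on the circle and the (beta, chi) torus.

All angles are in degrees. Orientation coordinates live on a 360-periodic
torus, so distances and differences must always be computed modulo 360.
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) into [0, 360)."""
    return np.mod(angle, 360.0)


def signed_diff_deg(a, b):
    """Signed difference a - b wrapped into (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - b + 180.0, 360.0) - 180.0
    # np.mod maps the boundary to -180; canonicalize to +180
    return np.where(d == -180.0, 180.0, d)


def circ_dist_deg(a, b):
    """Unsigned circular distance in [0, 180]."""
    return np.abs(signed_diff_deg(a, b))


def torus_dist_deg(p, q):
    """Euclidean distance between points on the (beta, chi) torus.

    ``p`` and ``q`` are (..., 2) arrays of (beta, chi) in degrees.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = signed_diff_deg(p, q)
    return np.sqrt(np.sum(np.square(d), axis=-1))


def vector_angle_deg(v):
    """In-plane polar angle of 2-vector(s) (..., 2) in [0, 360)."""
    v = np.asarray(v, dtype=float)
    return wrap_deg(np.degrees(np.arctan2(v[..., 1], v[..., 0])))
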