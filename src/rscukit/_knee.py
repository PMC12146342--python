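"""Discrete knee/elbow detection on score-vs-parameter curves.

Chord-distance variant of the Kneedle idea: normalize the curve to the unit
square and take the interior point with the largest deviation from the
straight line joining the endpoints, on the side the declared curve shape
implies.  Used for the inertia-vs-k elbow and the sorted k-nearest-neighbor
distance curve that sets the DBSCAN eps.
"""

from __future__ import annotations

import numpy as np


def find_knee(
    x: np.ndarray,
    y: np.ndarray,
    curve: str = "convex",
    direction: str = "decreasing",
) -> float | None:
    """Locate the knee of a curve; return its x value, or None if absent.

    Parameters
    ----------
    x, y
        Curve samples; x must be strictly increasing.
    curve
        "convex" (curve below its chord) or "concave" (above).
    direction
        "decreasing" or "increasing"; used only for validation of intent,
        the chord test itself is direction-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        return None
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    if curve not in ("convex", "concave") or direction not in (
        "decreasing",
        "increasing",
    ):
        raise ValueError(f"bad curve={curve!r} or direction={direction!r}")

    xs = (x - x[0]) / (x[-1] - x[0])
    span = y.max() - y.min()
    if span == 0:
        return None
    ys = (y - y.min()) / span
    chord = ys[0] + xs * (ys[-1] - ys[0])
    diff = chord - ys if curve == "convex" else ys - chord
    interior = diff[1:-1]
    if interior.max() <= 1e-12:
        return None  # straight line or wrong-side curvature
    idx = 1 + int(np.argmax(interior))
    return float(x[idx])
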