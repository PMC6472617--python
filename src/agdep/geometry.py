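"""Angle conventions shared by the renderer and the tracker.

Angles are behavioral, not mathematical: 0 deg means facing the front
wall of the box (the feeding opening, at the top of an overhead image),
+/-180 deg means facing the loudspeaker behind the animal (image
bottom).  The representable range is (-180, 180].

Image coordinates are 0-based (row, col) with row increasing downward.
In (x=col, y=row) screen coordinates the facing unit vector of a
behavioral angle ``a`` is ``(sin a, -cos a)`` and the ear-tuft axis is
its perpendicular ``(cos a, sin a)``; the tufts sit at the head centre
plus/minus the tuft offset along that axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circular_difference",
    "facing_vector",
    "tuft_axis",
    "axis_to_angle_candidates",
]


def wrap_angle(angle_deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap to (-180, 180]."""
    wrapped = -((-np.asarray(angle_deg) + 180.0) % 360.0 - 180.0)
    if np.isscalar(angle_deg):
        return float(wrapped)
    return wrapped


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed smallest rotation from b to a, in (-180, 180]."""
    return wrap_angle(a_deg - b_deg)


def facing_vector(angle_deg: float) -> np.ndarray:
    """Unit facing vector in (x, y) screen coordinates."""
    a = np.deg2rad(angle_deg)
    return np.array([np.sin(a), -np.cos(a)])


def tuft_axis(angle_deg: float) -> np.ndarray:
    """Unit inter-tuft axis vector in (x, y), perpendicular to facing."""
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


def axis_to_angle_candidates(axis_xy: np.ndarray) -> tuple[float, float]:
    """The two behavioral angles whose tuft axis is parallel to ``axis_xy``.

    The inter-tuft axis only determines the facing direction up to a 180
    deg flip; temporal continuity must pick the branch.
    """
    theta = float(np.rad2deg(np.arctan2(axis_xy[1], axis_xy[0])))
    return wrap_angle(theta), wrap_angle(theta + 180.0)
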