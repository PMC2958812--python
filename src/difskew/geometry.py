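"""Angular coordinates on a circular chromosome, measured from oriC.

Positions on a circular genome of length ``L`` are mapped to signed angles
in ``(-180, 180]`` degrees, positive in the direction of increasing
sequence coordinate from the replication origin.  The four genome
"quarters" follow the convention used when describing dif-site positions:
quarter 1 covers [0, 90), quarter 2 covers [90, 180], quarter 3 covers
(-180, -90] and quarter 4 covers (-90, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AngleReport", "angle_from_origin", "quarter", "angle_to_position"]


@dataclass(frozen=True)
class AngleReport:
    position: int
    angle: float
    quarter: int


def angle_from_origin(position: int, oric: int, length: int) -> float:
    """Signed angle (degrees) of ``position`` relative to ``oric``.

    The returned value lies in ``(-180, 180]``; a site one quarter of the
    chromosome downstream of oriC is at +90.
    """
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    d = (position - oric) % length
    angle = 360.0 * d / length
    if angle > 180.0:
        angle -= 360.0
    return angle


def quarter(angle: float) -> int:
    """Genome quarter (1..4) for a signed angle in (-180, 180]."""
    if not (-180.0 < angle <= 180.0):
        raise ValueError(f"angle must lie in (-180, 180], got {angle}")
    if 0.0 <= angle < 90.0:
        return 1
    if 90.0 <= angle <= 180.0:
        return 2
    if angle <= -90.0:
        return 3
    return 4


def angle_to_position(angle: float, oric: int, length: int) -> int:
    """Inverse of :func:`angle_from_origin` (nearest base pair)."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    return int(round(oric + (angle % 360.0) / 360.0 * length)) % length


def report(position: int, oric: int, length: int) -> AngleReport:
    a = angle_from_origin(position, oric, length)
    return AngleReport(position=position, angle=a, quarter=quarter(a))
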