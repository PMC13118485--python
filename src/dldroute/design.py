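"""Design arithmetic for deterministic-lateral-displacement (DLD) post arrays.

A DLD array is described by the post diameter ``D``, the clear gap ``G``
between posts, and the periodicity ``N`` (rows after which the tilted
pattern repeats); the tilt angle satisfies ``tan(theta) = 1/N`` and the
pitch is ``lambda = D + G``.  The geometric (nominal) critical diameter is
estimated either by Davis' empirical correlation

    DC = 1.4 G N^(-0.48)

or by the simpler square-root approximation ``DC = G sqrt(2/N)``.  Both are
rules of thumb for spherical particles; the probabilistic critical diameter
measured by the routing analysis is related but generally different.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DLDGeometry", "nominal_dc", "dilution_fraction", "geometry_consistency"]

_FORMULAS = ("davis", "sqrt_approx")


@dataclass(frozen=True)
class DLDGeometry:
    """Array geometry; lengths in μm, angle in degrees.

    ``tilt_angle_deg`` and ``pitch`` may be given independently of
    ``n_period`` and ``post_diameter + gap`` (e.g. copied from a fabrication
    sheet); :func:`geometry_consistency` reports any disagreement rather
    than raising.
    """

    post_diameter: float
    gap: float
    n_period: float
    tilt_angle_deg: float | None = None
    pitch: float | None = None

    def __post_init__(self):
        if self.post_diameter <= 0 or self.gap <= 0:
            raise ValueError("post diameter and gap must be > 0")
        if self.n_period <= 1:
            raise ValueError("periodicity must be > 1")

    @property
    def derived_pitch(self) -> float:
        return self.post_diameter + self.gap

    @property
    def derived_tilt_deg(self) -> float:
        return math.degrees(math.atan(1.0 / self.n_period))


def nominal_dc(geometry: DLDGeometry | None = None, formula: str = "davis", *,
               gap: float | None = None, n_period: float | None = None) -> float:
    """Nominal critical diameter (μm) of a DLD array.

    Accepts either a :class:`DLDGeometry` or explicit ``gap`` / ``n_period``
    keywords.  ``formula`` selects Davis' correlation ``1.4 G N^(-0.48)``
    (default) or the square-root approximation ``G (2/N)^(1/2)``.
    """
    if geometry is not None:
        gap, n_period = geometry.gap, geometry.n_period
    if gap is None or n_period is None:
        raise ValueError("provide a geometry or both gap and n_period")
    if gap <= 0 or n_period <= 1:
        raise ValueError("gap must be > 0 and periodicity > 1")
    if formula == "davis":
        return 1.4 * gap * n_period ** (-0.48)
    if formula == "sqrt_approx":
        return gap * math.sqrt(2.0 / n_period)
    raise ValueError(f"unknown formula {formula!r}; choose from {_FORMULAS}")


def dilution_fraction(n_sample_channels: int, n_buffer_channels: int) -> float:
    """Sample concentration fraction after merging with the buffer stream.

    With equal channel widths and flow speeds, the sample occupies
    ``n_sample / (n_sample + n_buffer)`` of the merged flow.
    """
    if n_sample_channels < 1 or n_buffer_channels < 1:
        raise ValueError("channel counts must be >= 1")
    return n_sample_channels / (n_sample_channels + n_buffer_channels)


def geometry_consistency(geometry: DLDGeometry, angle_tol_deg: float = 1e-3,
                         pitch_tol: float = 1e-9) -> list[str]:
    """Check stated pitch and tilt angle against the derived values.

    Returns human-readable warnings with the discrepancy magnitudes; never
    raises.  An empty list means the stated numbers are self-consistent.
    """
    warnings: list[str] = []
    if geometry.pitch is not None:
        delta = geometry.pitch - geometry.derived_pitch
        if abs(delta) > pitch_tol:
            warnings.append(
                f"stated pitch {geometry.pitch} μm differs from D+G = "
                f"{geometry.derived_pitch} μm by {delta:+.6g} μm"
            )
    if geometry.tilt_angle_deg is not None:
        delta = geometry.tilt_angle_deg - geometry.derived_tilt_deg
        if abs(delta) > angle_tol_deg:
            warnings.append(
                f"stated tilt {geometry.tilt_angle_deg}° differs from "
                f"atan(1/N) = {geometry.derived_tilt_deg:.4g}° by {delta:+.4g}°"
            )
    return warnings
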