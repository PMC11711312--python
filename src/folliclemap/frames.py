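"""Coordinate conventions for the follicle and its vertical territories.

All coordinates are in micrometres, right-handed. Angles around the vibrissal
shaft are measured counterclockwise in degrees, stored in [0, 360), with
0° = rostral, 90° = dorsal, 180° = caudal and 270° = ventral. Terminal heights
are measured relative to the point where the deep vibrissal nerve enters the
follicle; the ringwulst level is the landmark that separates the vertical
ending territories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FollicleFrame", "VerticalBands", "wrap_angle", "signed_angle_diff"]


def wrap_angle(theta):
    """Wrap an angle (degrees) into [0, 360)."""
    return np.asarray(theta) % 360.0


def signed_angle_diff(a, b):
    """Signed circular difference a - b mapped into (-180, 180] degrees."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class FollicleFrame:
    """Reference frame of one follicle.

    Parameters
    ----------
    shaft_center_xy : tuple of float
        Vibrissal shaft midpoint at ringwulst level (µm); origin for angular
        position measurements.
    nerve_entry_z : float
        z level (µm) where the deep vibrissal nerve enters the follicle;
        zero point for terminal heights.
    ringwulst_z : float
        z level (µm) of the ringwulst; must lie above the nerve entrance.
    rostral_axis : tuple of float
        Unit 2-vector in the x-y plane pointing rostrally; defines 0°.
    """

    shaft_center_xy: tuple[float, float] = (0.0, 0.0)
    nerve_entry_z: float = 0.0
    ringwulst_z: float = 900.0
    rostral_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        ax = np.asarray(self.rostral_axis, dtype=float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-9):
            raise ValueError("rostral_axis must have unit norm")
        if not self.ringwulst_z > self.nerve_entry_z:
            raise ValueError("ringwulst_z must lie above nerve_entry_z")

    @property
    def rotation_matrix(self) -> np.ndarray:
        """2x2 rotation taking rostral_axis onto +x (counterclockwise frame)."""
        ux, uy = self.rostral_axis
        return np.array([[ux, uy], [-uy, ux]], dtype=float)

    def is_identity(self) -> bool:
        return (
            tuple(self.shaft_center_xy) == (0.0, 0.0)
            and self.nerve_entry_z == 0.0
            and tuple(self.rostral_axis) == (1.0, 0.0)
        )


@dataclass(frozen=True)
class VerticalBands:
    """Vertical ending territories relative to the ringwulst level.

    Ring-sinus-level afferents surpass the ringwulst by 100–300 µm; the
    ringwulst territory is the ±100 µm window around the ringwulst itself;
    the cavernous-sinus territory lies 100–300 µm below it. Edges are
    configurable offsets (µm) applied to ``ringwulst_z``.
    """

    ringwulst_z: float = 900.0
    ring_sinus_offsets: tuple[float, float] = (100.0, 300.0)
    ringwulst_halfwidth: float = 100.0
    cavernous_offsets: tuple[float, float] = (-300.0, -100.0)

    def band_of(self, z: float) -> str | None:
        """Return the territory name for terminal level ``z`` (µm), or None."""
        rw = self.ringwulst_z
        lo, hi = self.ring_sinus_offsets
        if rw + lo <= z <= rw + hi:
            return "ring_sinus"
        lo, hi = self.cavernous_offsets
        if rw + lo <= z <= rw + hi:
            return "cavernous"
        if abs(z - rw) < self.ringwulst_halfwidth:
            return "ringwulst"
        return None

    def band_interval(self, band: str) -> tuple[float, float]:
        rw = self.ringwulst_z
        if band == "ring_sinus":
            return (rw + self.ring_sinus_offsets[0], rw + self.ring_sinus_offsets[1])
        if band == "ringwulst":
            return (rw - self.ringwulst_halfwidth, rw + self.ringwulst_halfwidth)
        if band == "cavernous":
            return (rw + self.cavernous_offsets[0], rw + self.cavernous_offsets[1])
        raise ValueError(f"unknown band {band!r}")
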