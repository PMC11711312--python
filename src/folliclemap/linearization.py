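"""Radial-vs-linear layout models of afferents in the nerve cross-section.

The radial arrangement of axon arms around the vibrissal shaft could map into
the nerve either as a condensed radial layout (an afferent's polar angle in
the nerve predicts its terminal angle at the follicle) or as a linearly
unwrapped layout (the afferent's position along the nerve's principal axis
predicts its terminal angle once the circle of terminal angles is cut open at
a stated angle). Both models are scored by Pearson correlation between the
model's coordinate and the unwrapped terminal angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .frames import wrap_angle

__all__ = [
    "fit_nerve_axis",
    "project_onto_axis",
    "fit_nerve_center",
    "unwrap_angles",
    "evaluate_models",
    "LinearizationResult",
]


def fit_nerve_center(points_xy) -> np.ndarray:
    """Least-squares circle centre of the nerve cross-section positions.

    Algebraic (Kasa) fit; for a ring-like layout this recovers the nerve
    centre even when the angular coverage is uneven, where the plain centroid
    would be pulled toward the crowded side and warp the polar-angle readout.
    Falls back to the centroid when the points are exactly collinear (no
    circle is defined). Equivariant under rigid motions.
    """
    P = np.asarray(points_xy, dtype=float)
    A = np.column_stack([2.0 * P[:, 0], 2.0 * P[:, 1], np.ones(len(P))])
    b = (P**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        return P.mean(axis=0)
    return sol[:2]


def fit_nerve_axis(points_xy) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through the nerve cross-section positions.

    Returns (centroid, unit direction). The line is the principal axis
    (orthogonal least squares), so the fit is equivariant under rigid motions
    of the cross-section; the direction sign is fixed so projections increase
    with x (falling back to +y for a vertical axis).
    """
    P = np.asarray(points_xy, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2 or P.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    centroid = P.mean(axis=0)
    Q = P - centroid
    if np.allclose(Q, 0.0):
        raise ValueError("all nerve positions coincident; axis undefined")
    _, _, Vt = np.linalg.svd(Q, full_matrices=False)
    direction = Vt[0]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    return centroid, direction


def project_onto_axis(points_xy, line) -> np.ndarray:
    """Signed scalar projections of points onto a (point, unit-direction) line."""
    centroid, direction = line
    P = np.asarray(points_xy, dtype=float)
    return (P - np.asarray(centroid)) @ np.asarray(direction)


def unwrap_angles(angles_deg, cut_angle: float) -> np.ndarray:
    """Cut the circle of angles open at ``cut_angle`` to a linear [0, 360) scale."""
    return (np.asarray(angles_deg, dtype=float) - cut_angle) % 360.0


@dataclass(frozen=True)
class LinearizationResult:
    """Side-by-side fit of the linearly-unwrapped and radially-condensed models."""

    cut_angle: float
    n: int
    linear: dict  # prediction, r, p_value, slope, intercept, axis
    radial: dict  # prediction, r, p_value
    actual_unwrapped: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"model": "linearly_unwrapped", "r": self.linear["r"],
                 "p_value": self.linear["p_value"], "n": self.n},
                {"model": "radially_condensed", "r": self.radial["r"],
                 "p_value": self.radial["p_value"], "n": self.n},
            ]
        )


def evaluate_models(
    nerve_xy, terminal_angles_deg, cut_angle: float = 0.0
) -> LinearizationResult:
    """Score both nerve-layout models against actual terminal angles.

    Linearly-unwrapped model: project nerve positions onto the principal axis
    of the cross-section and correlate the projections with terminal angles
    unwrapped at ``cut_angle``. Radially-condensed model: take each
    afferent's polar angle about the fitted nerve centre
    (:func:`fit_nerve_center`), unwrap it at the same cut, and correlate with
    the unwrapped terminal angles. Pearson r and two-sided p are reported for
    both.
    """
    P = np.asarray(nerve_xy, dtype=float)
    angles = np.asarray(terminal_angles_deg, dtype=float)
    if P.shape[0] != angles.size or angles.size < 4:
        raise ValueError("need at least 4 afferents with both coordinates")
    actual = unwrap_angles(angles, cut_angle)

    line = fit_nerve_axis(P)
    proj = project_onto_axis(P, line)
    # Sign convention: orient the axis so the correlation is reported
    # positive for an increasing layout; magnitude is what the model claims.
    lin_r, lin_p = sps.pearsonr(proj, actual)
    slope, intercept = np.polyfit(proj, actual, 1)

    center = fit_nerve_center(P)
    polar = wrap_angle(np.degrees(np.arctan2(P[:, 1] - center[1],
                                             P[:, 0] - center[0])))
    radial_pred = unwrap_angles(polar, cut_angle)
    rad_r, rad_p = sps.pearsonr(radial_pred, actual)

    return LinearizationResult(
        cut_angle=float(wrap_angle(cut_angle)),
        n=int(angles.size),
        linear={
            "prediction": proj,
            "r": float(lin_r),
            "p_value": float(lin_p),
            "slope": float(slope),
            "intercept": float(intercept),
            "axis": line,
        },
        radial={"prediction": radial_pred, "r": float(rad_r), "p_value": float(rad_p)},
        actual_unwrapped=actual,
    )
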