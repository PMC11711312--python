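"""Rule-based afferent typing, exclusion criteria and innervation composition.

Myelinated deep-nerve afferents fall into four classical morphological types,
decided by vertical ending territory plus a small set of ending flags:

======================  =======================  =================
vertical territory      dominating flag          type
======================  =======================  =================
ring sinus level        root-sheath entrance     Merkel
ring sinus level        on glassy membrane       Lanceolate
ringwulst level         on glassy membrane       ClubLike
cavernous sinus level   shaft-ward trajectory    RuffiniLike
======================  =======================  =================

Within the ring-sinus territory the root-sheath entrance dominates (Merkel
over Lanceolate). Anything matching no rule is Unclassified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .frames import VerticalBands

__all__ = [
    "AFFERENT_TYPES",
    "AfferentTypeClassifier",
    "classify",
    "apply_exclusion",
    "composition",
    "CompositionReport",
    "round_half_away",
]

AFFERENT_TYPES = ("Merkel", "Lanceolate", "ClubLike", "RuffiniLike", "Unclassified")

_FLAG_COLUMNS = ("root_sheath_entry", "glassy_membrane_terminal", "shaft_trajectory")


class AfferentTypeClassifier(ClassifierMixin, BaseEstimator):
    """Deterministic rule-table classifier for myelinated afferent types.

    Parameters
    ----------
    bands : VerticalBands
        The ring-sinus / ringwulst / cavernous z-intervals used to assign the
        vertical ending territory from ``terminal_height``.

    The classifier is a pure function of its inputs: ``fit`` only records the
    label set (there is nothing to estimate) so the estimator composes with
    sklearn pipelines and model selection.
    """

    def __init__(self, bands: VerticalBands | None = None):
        self.bands = bands

    def fit(self, X, y=None):
        self._validate(X)
        self.classes_ = np.asarray(AFFERENT_TYPES)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        self._validate(X)
        bands = self.bands if self.bands is not None else VerticalBands()
        labels = [self._classify_row(row, bands) for _, row in X.iterrows()]
        return np.asarray(labels, dtype=object)

    @staticmethod
    def _classify_row(row, bands: VerticalBands) -> str:
        band = bands.band_of(row["terminal_height"])
        if band == "ring_sinus":
            if bool(row.get("root_sheath_entry", False)):
                return "Merkel"
            if bool(row.get("glassy_membrane_terminal", False)):
                return "Lanceolate"
        elif band == "ringwulst":
            if bool(row.get("glassy_membrane_terminal", False)):
                return "ClubLike"
        elif band == "cavernous":
            if bool(row.get("shaft_trajectory", False)):
                return "RuffiniLike"
        return "Unclassified"

    @staticmethod
    def _validate(X):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of afferent features")
        if "terminal_height" not in X.columns:
            raise ValueError("features must include 'terminal_height'")


def classify(features: pd.DataFrame, bands: VerticalBands | None = None) -> np.ndarray:
    """Assign an afferent type label to every row of a feature table."""
    clf = AfferentTypeClassifier(bands=bands)
    return clf.fit(features).predict(features)


def apply_exclusion(reconstructions):
    """Split reconstructions into the analysable subset and an exclusion log.

    An axon lost during segmentation inside an axon arm is excluded
    (``lost_in_arm``): its terminal territory is unknown because trajectories
    curve within arms. Axons that left their arm, or ended near the root
    sheath, are close to their terminal region and kept. Fragments that cannot
    be connected to a ground-cable (an axon path starting in the unbranched
    region well below the ringwulst) may be mere branches of another axon and
    are excluded from axon-based analyses (``no_ground_cable``).
    """
    included, log_rows = [], []
    for recon in reconstructions:
        for flag in ("terminates_in_arm", "left_arm_or_near_root_sheath"):
            if getattr(recon, flag) is None:
                raise ValueError(
                    f"afferent {recon.afferent_id}: completeness flag {flag!r} missing"
                )
        if recon.terminates_in_arm and not recon.left_arm_or_near_root_sheath:
            reason, keep = "lost_in_arm", False
        elif not recon.ground_cable:
            reason, keep = "no_ground_cable", False
        else:
            reason, keep = "included", True
        if keep:
            included.append(recon)
        log_rows.append(
            {"afferent_id": recon.afferent_id, "included": keep, "reason": reason}
        )
    return included, pd.DataFrame(log_rows)


def round_half_away(x: float) -> int:
    """Round half away from zero (so 34.5 -> 35, -34.5 -> -35)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CompositionReport:
    """Counts and integer percentages of innervation classes."""

    counts: dict[str, int]
    percentages: dict[str, int]
    total: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [self.percentages[k] for k in self.counts],
            }
        )


def composition(counts: dict[str, int]) -> CompositionReport:
    """Innervation composition percentages from per-class counts.

    Percentages are 100*count/total rounded half away from zero, so they sum
    to 100 up to +-1 rounding slack.
    """
    for name, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for class {name!r}")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    percentages = {k: round_half_away(100.0 * v / total) for k, v in counts.items()}
    return CompositionReport(counts=dict(counts), percentages=percentages, total=total)
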