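"""Synthetic follicle innervation with known ground truth.

Generates a population of afferent reconstructions with the statistical
structure the downstream analyses assume: four myelinated afferent types in
their vertical ending territories with the flag combinations the rule-based
classifier expects, dorso-caudally polarized terminal angles (von Mises), a
positive fiber-caliber vs terminal-height gradient whose myelinated and
unmyelinated populations straddle the 850 µm bimodal split, two planted
club-like subtypes differing in fiber area and Ranvier internode length,
axon arms occupying contiguous angular sectors, and a nerve cross-section
laid out either linearly unwrapped, radially condensed, or shuffled.

Every quantity is drawn from a per-afferent substream derived from the
configured seed, so identical configurations reproduce identical datasets
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import FollicleFrame, VerticalBands, signed_angle_diff, wrap_angle
from .io import AxonNode, AxonReconstruction
from .morphometry import conduction_velocity

__all__ = ["ClubSubtypeParams", "SyntheticConfig", "generate_follicle",
           "embed_nerve_layout"]

_LAYOUT_MODES = ("linear", "radial", "shuffled")

# Terminal cylinder radii (µm) per class; only the angle matters downstream,
# the radius just keeps terminals off the shaft axis.
_TERMINAL_RADIUS = {
    "Merkel": 120.0, "Lanceolate": 140.0, "ClubLike": 160.0,
    "RuffiniLike": 180.0, "Unmyelinated": 100.0, "Superficial": 200.0,
}


@dataclass(frozen=True)
class ClubSubtypeParams:
    """Two planted club-like subtypes: small/short vs large/long caliber.

    Fiber-area offsets are added to the gradient law (mean-zero at equal
    mixing so the population gradient is preserved); internode lengths are
    drawn around distinct means.
    """

    area_offset_um2: tuple[float, float] = (-7.5, 7.5)
    internode_mean_um: tuple[float, float] = (350.0, 650.0)
    internode_sd_um: float = 40.0
    mixing_fraction: float = 0.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic follicle.

    Counts default to the classified myelinated census (51 Merkel, 21
    lanceolate, 52 club-like, 25 Ruffini-like), 58 reconstructed unmyelinated
    deep axons and 14 superficial axons. The angular bias defaults to a
    dorso-caudal von Mises centre; the caliber gradient to 0.04 µm² fiber
    area per µm terminal height around a -10 µm² intercept with 3 µm² noise.
    """

    n_merkel: int = 51
    n_lanceolate: int = 21
    n_club: int = 52
    n_ruffini: int = 25
    n_unmyelinated: int = 58
    n_superficial: int = 14
    polarization_mu: float = 135.0
    polarization_kappa: float = 1.0
    gradient_slope: float = 0.04
    gradient_intercept: float = -10.0
    gradient_noise_sd: float = 3.0
    min_fiber_area: float = 0.2
    height_split: float = 850.0
    ringwulst_z: float = 900.0
    club_subtype_params: ClubSubtypeParams = field(default_factory=ClubSubtypeParams)
    n_arms: int = 6
    arm_jitter_sd: float = 5.0
    nerve_layout: str = "linear"
    nerve_layout_jitter: float = 5.0
    nerve_radius: float = 50.0
    layout_cut: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_merkel, self.n_lanceolate, self.n_club, self.n_ruffini,
                  self.n_unmyelinated, self.n_superficial)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if self.polarization_kappa < 0:
            raise ValueError("polarization_kappa must be >= 0")
        f = self.club_subtype_params.mixing_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("club subtype mixing fraction must be in [0, 1]")
        if self.nerve_layout not in _LAYOUT_MODES:
            raise ValueError(f"unknown nerve_layout {self.nerve_layout!r}")
        if self.n_arms < 1:
            raise ValueError("n_arms must be >= 1")

    @property
    def frame(self) -> FollicleFrame:
        return FollicleFrame(ringwulst_z=self.ringwulst_z)

    @property
    def bands(self) -> VerticalBands:
        return VerticalBands(ringwulst_z=self.ringwulst_z)


def _class_plan(config: SyntheticConfig) -> list[str]:
    plan = []
    plan += ["Merkel"] * config.n_merkel
    plan += ["Lanceolate"] * config.n_lanceolate
    plan += ["ClubLike"] * config.n_club
    plan += ["RuffiniLike"] * config.n_ruffini
    plan += ["Unmyelinated"] * config.n_unmyelinated
    plan += ["Superficial"] * config.n_superficial
    return plan


def _height_interval(cls: str, config: SyntheticConfig) -> tuple[float, float]:
    rw = config.ringwulst_z
    if cls in ("Merkel", "Lanceolate"):
        return (rw + 100.0, rw + 300.0)
    if cls == "ClubLike":
        return (rw - 99.0, rw + 99.0)
    if cls == "RuffiniLike":
        return (rw - 300.0, rw - 100.0)
    if cls == "Unmyelinated":
        return (100.0, rw - 150.0)
    return (rw + 400.0, rw + 600.0)  # superficial, above the follicle neck


_FLAG_TABLE = {
    # (root_sheath_entry, glassy_membrane_terminal, ringwulst_apposition,
    #  shaft_trajectory) exactly as the classifier rule table expects.
    "Merkel": (True, False, False, False),
    "Lanceolate": (False, True, False, False),
    "ClubLike": (False, True, True, False),
    "RuffiniLike": (False, False, False, True),
    "Unmyelinated": (False, False, False, False),
    "Superficial": (False, True, False, False),
}


def _branch_count(cls: str, rng) -> int:
    if cls in ("Lanceolate", "Superficial"):
        return int(rng.integers(2, 8))  # 2-7 ending branches, spear-like
    if cls == "ClubLike":
        return 0  # flat, precisely aligned terminals; branching is not a club trait
    if cls == "RuffiniLike":
        return int(rng.integers(0, 3))
    return 0


def _build_skeleton(afferent_id, theta_deg, theta_ref_deg, z_term, radius_um,
                    cls, branch_count, rng) -> list[AxonNode]:
    """Piecewise-linear polyline from the nerve entrance to the terminal.

    The angular position holds the reference-level value through the arm
    region and turns toward the terminal angle above it; ending branches are
    short child segments fanning out just below the terminal tip.
    """
    n_main = 11
    z_levels = np.linspace(0.0, z_term, n_main)
    turn_z = min(0.8 * z_term, z_term - 1.0)
    d_theta = float(signed_angle_diff(theta_deg, theta_ref_deg))
    r_term = _TERMINAL_RADIUS[cls]
    nodes = []
    for k, z in enumerate(z_levels):
        t = 0.0 if z <= turn_z else (z - turn_z) / (z_term - turn_z)
        ang = np.deg2rad(theta_ref_deg + t * d_theta)
        r_cyl = 250.0 + (r_term - 250.0) * (z / z_term if z_term > 0 else 1.0)
        nodes.append(AxonNode(
            id=k + 1, parent_id=k if k > 0 else -1,
            x=float(r_cyl * np.cos(ang)), y=float(r_cyl * np.sin(ang)),
            z=float(z), radius=radius_um,
        ))
    tip = nodes[-1]
    fork = nodes[n_main - 2]  # branches fan out from the node below the tip
    next_id = len(nodes) + 1
    for b in range(branch_count):
        ang = 2 * np.pi * b / max(branch_count, 1)
        nodes.append(AxonNode(
            id=next_id, parent_id=fork.id,
            x=tip.x + 5.0 * np.cos(ang), y=tip.y + 5.0 * np.sin(ang),
            z=tip.z - 1.0, radius=radius_um,
        ))
        next_id += 1
    return nodes


def generate_follicle(config: SyntheticConfig):
    """Generate one synthetic follicle.

    Returns ``(reconstructions, features, ground_truth)``: a list of
    :class:`AxonReconstruction`, the per-afferent feature table all downstream
    statistics consume, and the ground-truth table (true type, club subtype,
    arm, terminal angle, layout mode).
    """
    plan = _class_plan(config)
    if not plan:
        raise ValueError("total afferent count must be positive")
    sector = 360.0 / config.n_arms
    params = config.club_subtype_params
    recons, feat_rows, truth_rows = [], [], []
    for i, cls in enumerate(plan):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        theta = float(wrap_angle(np.degrees(
            rng.vonmises(np.deg2rad(config.polarization_mu),
                         config.polarization_kappa))))
        lo, hi = _height_interval(cls, config)
        z_term = float(rng.uniform(lo, hi))
        subtype = np.nan
        area = config.gradient_intercept + config.gradient_slope * z_term \
            + rng.normal(0.0, config.gradient_noise_sd)
        if cls == "ClubLike":
            subtype = int(rng.random() >= params.mixing_fraction)
            area += params.area_offset_um2[int(subtype)]
        elif cls == "Unmyelinated":
            area = float(rng.lognormal(np.log(0.8), 0.3))
        area = max(float(area), config.min_fiber_area)
        diameter = 2.0 * np.sqrt(area / np.pi)
        myelinated = cls != "Unmyelinated"
        if not myelinated:
            internode = np.nan
        elif cls == "ClubLike":
            internode = max(
                float(rng.normal(params.internode_mean_um[int(subtype)],
                                 params.internode_sd_um)), 50.0)
        else:
            internode = max(float(rng.normal(100.0 * diameter, 30.0)), 50.0)
        branch_count = _branch_count(cls, rng)
        theta_ref = float(wrap_angle(theta + rng.normal(0.0, config.arm_jitter_sd)))
        arm_id = int(theta // sector)
        flags = _FLAG_TABLE[cls]
        nodes = _build_skeleton(f"aff_{i:04d}", theta, theta_ref, z_term,
                                radius_um=diameter / 2.0, cls=cls,
                                branch_count=branch_count, rng=rng)
        recon = AxonReconstruction(
            afferent_id=f"aff_{i:04d}", nodes=nodes, myelinated=myelinated,
            arm_id=arm_id, nerve_entry_xy=None, ground_cable=True,
            terminates_in_arm=False, left_arm_or_near_root_sheath=True,
        )
        if myelinated:
            path_len = recon.path_length()
            pos = np.arange(0.0, path_len, internode)
            if pos.size < 2:
                pos = np.array([0.0, min(internode, path_len)])
            recon.ranvier_arc_positions = pos
        recons.append(recon)
        feat_rows.append({
            "afferent_id": recon.afferent_id,
            "afferent_class": "deep" if cls not in ("Superficial",) else "superficial",
            "myelinated": myelinated,
            "superficial": cls == "Superficial",
            "arm_id": arm_id,
            "terminal_angle": theta,
            "angle_ref": theta_ref,
            "terminal_height": z_term,
            "fiber_area": area,
            "fiber_diameter": diameter,
            "median_internode_length": internode,
            "branch_count": branch_count,
            "root_sheath_entry": flags[0],
            "glassy_membrane_terminal": flags[1],
            "ringwulst_apposition": flags[2],
            "shaft_trajectory": flags[3],
            "branched": branch_count > 0,
            "multibranch": branch_count > 2,
            "conduction_velocity": conduction_velocity(diameter, myelinated),
        })
        truth_rows.append({
            "afferent_id": recon.afferent_id,
            "true_type": cls,
            "true_club_subtype": subtype,
            "true_arm": arm_id,
            "true_terminal_angle": theta,
            "layout_mode": config.nerve_layout,
        })
    features = pd.DataFrame(feat_rows)
    features = embed_nerve_layout(
        features, mode=config.nerve_layout, seed=config.seed,
        cut=config.layout_cut, jitter=config.nerve_layout_jitter,
        radius=config.nerve_radius,
    )
    for recon, (_, row) in zip(recons, features.iterrows()):
        if np.isfinite(row["nerve_entry_x"]):
            recon.nerve_entry_xy = (float(row["nerve_entry_x"]),
                                    float(row["nerve_entry_y"]))
    return recons, features, pd.DataFrame(truth_rows)


def embed_nerve_layout(features: pd.DataFrame, mode: str, seed: int,
                       cut: float = 0.0, jitter: float = 5.0,
                       radius: float = 50.0) -> pd.DataFrame:
    """Fill nerve cross-section entry coordinates according to a layout model.

    linear: the entry x coordinate increases monotonically with the terminal
    angle unwrapped at ``cut`` (one µm nerve width per 3.6° of angle), y is
    Gaussian jitter (µm). radial: the entry polar angle equals the terminal
    angle plus Gaussian jitter (degrees) at fixed ``radius``. shuffled: a
    linear layout whose positions are randomly permuted across afferents.
    Superficial axons travel in their own nerves and get no coordinates.
    """
    if mode not in _LAYOUT_MODES:
        raise ValueError(f"unknown nerve layout mode {mode!r}")
    if "terminal_angle" not in features.columns:
        raise ValueError("terminal angles must be present before embedding")
    out = features.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999_983]))
    deep = ~out.get("superficial", pd.Series(False, index=out.index)).astype(bool)
    angles = out.loc[deep, "terminal_angle"].to_numpy(dtype=float)
    u = (angles - cut) % 360.0
    if mode in ("linear", "shuffled"):
        x = u / 3.6 - 50.0
        y = rng.normal(0.0, jitter, size=u.size) if jitter > 0 else np.zeros(u.size)
    else:
        # Jitter on the unwrapped scale, clipped so the angular band does not
        # smear across the section cut (the cut runs through the innervation
        # gap, so no axon straddles it).
        u_jit = u + (rng.normal(0.0, jitter, size=u.size) if jitter > 0 else 0.0)
        ang = np.deg2rad(np.clip(u_jit, 0.0, 360.0 - 1e-9) + cut)
        x = radius * np.cos(ang)
        y = radius * np.sin(ang)
    if mode == "shuffled":
        perm = rng.permutation(u.size)
        x, y = x[perm], y[perm]
    out["nerve_entry_x"] = np.nan
    out["nerve_entry_y"] = np.nan
    out.loc[deep, "nerve_entry_x"] = x
    out.loc[deep, "nerve_entry_y"] = y
    return out
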