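"""Reading and writing axon reconstructions and per-afferent feature tables.

Skeletons are exchanged as standard 7-column SWC (id, type, x, y, z, radius,
parent; whitespace separated, ``#`` comments, root parent = -1, coordinates in
µm). Annotations that SWC has no field for — myelination, axon-arm membership,
Ranvier node arc positions, nerve cross-section entry coordinates, completeness
flags — travel in a sidecar CSV table keyed by ``afferent_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import FollicleFrame

__all__ = [
    "AxonNode",
    "AxonReconstruction",
    "read_swc",
    "write_swc",
    "read_feature_table",
    "write_feature_table",
    "to_follicle_frame",
    "FEATURE_TABLE_MANDATORY",
]

SWC_AXON_CODE = 2

# Columns the sidecar table must carry; everything else is optional and filled
# as absent when missing.
FEATURE_TABLE_MANDATORY = ("afferent_id", "myelinated")


@dataclass(frozen=True)
class AxonNode:
    """One SWC node: sample id, parent id (-1 = root), position (µm), radius (µm)."""

    id: int
    parent_id: int
    x: float
    y: float
    z: float
    radius: float
    structure: int = SWC_AXON_CODE


@dataclass
class AxonReconstruction:
    """One axon's skeleton tree plus its sidecar annotations."""

    afferent_id: str
    nodes: list[AxonNode]
    myelinated: bool = True
    arm_id: int | None = None
    ranvier_arc_positions: np.ndarray | None = None
    nerve_entry_xy: tuple[float, float] | None = None
    ground_cable: bool = True
    terminates_in_arm: bool | None = None
    left_arm_or_near_root_sheath: bool | None = None

    def __post_init__(self):
        self._validate_tree()
        if self.ranvier_arc_positions is not None:
            pos = np.asarray(self.ranvier_arc_positions, dtype=float)
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"afferent {self.afferent_id}: ranvier_arc_positions must be "
                    "strictly increasing"
                )
            total = self.path_length()
            if pos.size and (pos[0] < 0 or pos[-1] > total + 1e-6):
                raise ValueError(
                    f"afferent {self.afferent_id}: ranvier position outside "
                    f"total arc length {total:.3f}"
                )
            self.ranvier_arc_positions = pos

    def _validate_tree(self):
        if not self.nodes:
            raise ValueError("reconstruction must contain at least one node")
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique")
        known = set()
        roots = 0
        for n in self.nodes:
            if n.radius <= 0:
                raise ValueError(f"node {n.id}: radius must be positive")
            if n.parent_id == -1:
                roots += 1
            elif n.parent_id not in known:
                raise ValueError(
                    f"node {n.id} references parent {n.parent_id} which does not "
                    "precede it"
                )
            known.add(n.id)
        if roots != 1:
            raise ValueError(f"expected exactly one root node, found {roots}")

    # -- geometry ---------------------------------------------------------
    def coordinates(self) -> np.ndarray:
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([n.radius for n in self.nodes], dtype=float)

    def path_length(self) -> float:
        """Total cable length: sum of parent-child segment lengths (µm)."""
        index = {n.id: n for n in self.nodes}
        total = 0.0
        for n in self.nodes:
            if n.parent_id != -1:
                p = index[n.parent_id]
                total += float(
                    np.sqrt((n.x - p.x) ** 2 + (n.y - p.y) ** 2 + (n.z - p.z) ** 2)
                )
        return total

    def children_counts(self) -> dict[int, int]:
        counts = {n.id: 0 for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                counts[n.parent_id] += 1
        return counts

    def terminal_node(self) -> AxonNode:
        """The tip at maximal z — the afferent ending in follicle convention."""
        counts = self.children_counts()
        tips = [n for n in self.nodes if counts[n.id] == 0]
        return max(tips, key=lambda n: n.z)


def read_swc(path) -> AxonReconstruction:
    """Parse a 7-column SWC file into a skeleton-only :class:`AxonReconstruction`.

    Comment lines starting with ``#`` are skipped. Errors name the offending
    node or line.
    """
    nodes: list[AxonNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}: line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                struct = int(parts[1])
                x, y, z, radius = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field ({exc})") from None
            nodes.append(AxonNode(nid, parent, x, y, z, radius, struct))
    ids = {n.id for n in nodes}
    for n in nodes:
        if n.parent_id != -1 and n.parent_id not in ids:
            raise ValueError(f"{path}: node {n.id} references absent parent {n.parent_id}")
    import os

    afferent_id = os.path.splitext(os.path.basename(str(path)))[0]
    return AxonReconstruction(afferent_id=afferent_id, nodes=nodes)


def write_swc(recon: AxonReconstruction, path) -> None:
    """Write a reconstruction as standard SWC (coordinates in µm)."""
    if not recon.nodes:
        raise ValueError("cannot write a reconstruction with no nodes")
    with open(path, "w") as fh:
        fh.write(f"# SWC skeleton for afferent {recon.afferent_id}\n")
        fh.write("# columns: id type x y z radius parent; units: um\n")
        for n in recon.nodes:
            fh.write(
                f"{n.id} {n.structure} {n.x:.9g} {n.y:.9g} {n.z:.9g} "
                f"{n.radius:.9g} {n.parent_id}\n"
            )


def _parse_ranvier(value) -> np.ndarray | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return np.array([float(v) for v in str(value).split(";") if v != ""], dtype=float)


def _format_ranvier(pos) -> str:
    if pos is None:
        return ""
    return ";".join(f"{v:.9g}" for v in np.asarray(pos, dtype=float))


def read_feature_table(path) -> pd.DataFrame:
    """Read the per-afferent annotation CSV.

    Mandatory columns: ``afferent_id`` (unique) and ``myelinated``. Optional
    columns (arm_id, morphological flags, ``ranvier_arc_positions`` as a
    ``;``-joined list field, nerve_entry_x/y, completeness flags) are filled
    as absent when missing.
    """
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_TABLE_MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing mandatory column(s): {', '.join(missing)}")
    if df["afferent_id"].duplicated().any():
        dup = df.loc[df["afferent_id"].duplicated(), "afferent_id"].iloc[0]
        raise ValueError(f"duplicate afferent_id in feature table: {dup!r}")
    if "ranvier_arc_positions" in df.columns:
        df["ranvier_arc_positions"] = df["ranvier_arc_positions"].map(_parse_ranvier)
    df["myelinated"] = df["myelinated"].astype(bool)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "ranvier_arc_positions" in out.columns:
        out["ranvier_arc_positions"] = out["ranvier_arc_positions"].map(_format_ranvier)
    out.to_csv(path, index=False)


def to_follicle_frame(recon: AxonReconstruction, frame: FollicleFrame) -> AxonReconstruction:
    """Express a reconstruction in follicle-frame coordinates.

    Translates so the shaft centre maps to (0, 0) in x-y and the nerve
    entrance to z = 0, then rotates about z so the rostral axis lies along +x.
    Rigid motion: pairwise distances are preserved.
    """
    rot = frame.rotation_matrix
    cx, cy = frame.shaft_center_xy
    new_nodes = []
    for n in recon.nodes:
        xy = rot @ np.array([n.x - cx, n.y - cy])
        new_nodes.append(
            AxonNode(n.id, n.parent_id, float(xy[0]), float(xy[1]),
                     n.z - frame.nerve_entry_z, n.radius, n.structure)
        )
    return replace(recon, nodes=new_nodes)
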