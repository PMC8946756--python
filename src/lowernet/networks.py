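"""Definitions of the four lower-order resting-state networks and their nodes.

The pipeline works on four networks tied to primary functions:

* ``SM``   -- sensorimotor: left/right pre-/post-central gyri and left/right
  supplementary motor area (4 nodes),
* ``AUD``  -- auditory: left/right Heschl's gyrus (2 nodes),
* ``LVIS`` -- lateral visual: left/right inferior occipital / fusiform
  cortex (2 nodes),
* ``MVIS`` -- medial visual: left/right lingual gyrus / calcarine
  cortex (2 nodes),

for a total of 10 seed nodes.  Node coordinates are not hard-coded for any
particular template space: they live in an editable YAML/JSON network
definition file so the same pipeline runs on real (MNI-space) data and on the
synthetic grid shipped with the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

NETWORK_NAMES = ("SM", "AUD", "LVIS", "MVIS")

#: number of nodes each network must declare
NODES_PER_NETWORK = {"SM": 4, "AUD": 2, "LVIS": 2, "MVIS": 2}


@dataclass(frozen=True)
class NodeDef:
    """A single network node: a named spherical seed region."""

    name: str
    hemisphere: str  # "L" or "R"
    coordinate: tuple[float, float, float]  # voxel coordinates on the grid
    radius_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")


@dataclass(frozen=True)
class NetworkModel:
    """The four networks, their nodes, and the grid geometry they live on.

    ``voxel_size_mm`` converts the seed radius (given in mm, default 6 mm)
    into voxels on the working grid.
    """

    networks: dict[str, tuple[NodeDef, ...]]
    voxel_size_mm: float = 3.0

    def __post_init__(self) -> None:
        missing = [n for n in NETWORK_NAMES if n not in self.networks]
        if missing:
            raise ValueError(f"missing networks: {missing}")
        for net, expected in NODES_PER_NETWORK.items():
            got = len(self.networks[net])
            if got != expected:
                raise ValueError(f"network {net} must have {expected} nodes, got {got}")
        if self.n_nodes != 10:
            raise ValueError("network model must declare exactly 10 seed nodes")

    @property
    def n_nodes(self) -> int:
        return sum(len(v) for v in self.networks.values())

    def nodes(self, network: str | None = None) -> tuple[NodeDef, ...]:
        if network is not None:
            if network not in self.networks:
                raise KeyError(f"unknown network {network!r}")
            return self.networks[network]
        return tuple(n for net in NETWORK_NAMES for n in self.networks[net])

    def node_roi(self, node: NodeDef, shape: tuple[int, int, int]) -> np.ndarray:
        """Boolean mask of the node's sphere on a grid of ``shape``."""
        return sphere_mask(shape, node.coordinate, self.radius_voxels(node))

    def radius_voxels(self, node: NodeDef) -> float:
        return node.radius_mm / self.voxel_size_mm

    def network_mask(self, network: str, shape: tuple[int, int, int]) -> np.ndarray:
        """Union of all node spheres of one network (the node-ROI template)."""
        mask = np.zeros(shape, dtype=bool)
        for node in self.nodes(network):
            mask |= self.node_roi(node, shape)
        return mask

    def to_dict(self) -> dict:
        return {
            "voxel_size_mm": self.voxel_size_mm,
            "networks": {
                net: [
                    {
                        "name": nd.name,
                        "hemisphere": nd.hemisphere,
                        "coordinate": list(nd.coordinate),
                        "radius_mm": nd.radius_mm,
                    }
                    for nd in nodes
                ]
                for net, nodes in self.networks.items()
            },
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_dict(cls, payload: dict) -> "NetworkModel":
        networks = {
            net: tuple(
                NodeDef(
                    name=nd["name"],
                    hemisphere=nd["hemisphere"],
                    coordinate=tuple(float(c) for c in nd["coordinate"]),
                    radius_mm=float(nd.get("radius_mm", 6.0)),
                )
                for nd in nodes
            )
            for net, nodes in payload["networks"].items()
        }
        return cls(networks=networks, voxel_size_mm=float(payload.get("voxel_size_mm", 3.0)))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkModel":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload)


def sphere_mask(
    shape: tuple[int, int, int],
    center: Iterable[float],
    radius_voxels: float,
) -> np.ndarray:
    """Boolean mask of voxels within Euclidean ``radius_voxels`` of ``center``."""
    cx, cy, cz = center
    x, y, z = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    return d2 <= radius_voxels**2


def default_synthetic_model(voxel_size_mm: float = 3.0) -> NetworkModel:
    """The 10-node network model on the default synthetic 32x32x24 grid.

    Coordinates are laid out so that all radius-2-voxel node spheres are
    pairwise disjoint and fall inside the synthetic brain ellipsoid; their
    relative anatomy (SM dorsal, AUD lateral-temporal, visual posterior)
    mirrors the real networks but the space is the generator's own grid.
    """
    nets = {
        "SM": (
            NodeDef("SM_precentral_L", "L", (7, 19, 16)),
            NodeDef("SM_precentral_R", "R", (25, 19, 16)),
            NodeDef("SM_SMA_L", "L", (12, 14, 20)),
            NodeDef("SM_SMA_R", "R", (20, 14, 20)),
        ),
        "AUD": (
            NodeDef("AUD_heschl_L", "L", (5, 14, 10)),
            NodeDef("AUD_heschl_R", "R", (27, 14, 10)),
        ),
        "LVIS": (
            NodeDef("LVIS_inf_occipital_L", "L", (8, 5, 9)),
            NodeDef("LVIS_inf_occipital_R", "R", (24, 5, 9)),
        ),
        "MVIS": (
            NodeDef("MVIS_lingual_L", "L", (12, 4, 13)),
            NodeDef("MVIS_lingual_R", "R", (20, 4, 13)),
        ),
    }
    return NetworkModel(networks=nets, voxel_size_mm=voxel_size_mm)
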