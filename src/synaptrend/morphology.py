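"""Neuronal morphology as an SWC-convention tree with path distances.

The morphology is a rooted tree of 3-D points with radii, following the
standard 7-column SWC layout (id, type, x, y, z, radius, parent).  Path
distance to the soma is accumulated along parent links using Euclidean
inter-node distances, which is the quantity every distance-dependent synaptic
property in this package is expressed against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4


@dataclass
class Morphology:
    """SWC-style tree. ``parent`` holds array indices (-1 for the root)."""

    xyz: np.ndarray          # (n, 3) µm
    radius: np.ndarray       # (n,) µm
    parent: np.ndarray       # (n,) int, index into arrays, -1 at root
    ntype: np.ndarray        # (n,) int SWC type codes

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.ntype = np.asarray(self.ntype, dtype=int)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.radius)

    def validate(self) -> None:
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("morphology must have a single root at index 0")
        if np.any(self.parent[1:] >= np.arange(1, self.n_nodes)):
            raise ValueError("parents must precede children (topological order)")

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            ch[self.parent[i]].append(i)
        return ch

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of each node's edge to its parent (root: 0)."""
        L = np.zeros(self.n_nodes)
        p = self.parent[1:]
        L[1:] = np.linalg.norm(self.xyz[1:] - self.xyz[p], axis=1)
        return L

    def path_distance(self) -> np.ndarray:
        """Path distance (µm) from each node to the root along the tree."""
        L = self.edge_lengths()
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):  # parents precede children
            d[i] = d[self.parent[i]] + L[i]
        return d

    def tips(self) -> np.ndarray:
        has_child = np.zeros(self.n_nodes, dtype=bool)
        has_child[self.parent[self.parent >= 0]] = True
        return np.flatnonzero(~has_child)

    # -- SWC I/O -----------------------------------------------------------
    def to_swc(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# id type x y z radius parent\n")
            for i in range(self.n_nodes):
                pid = -1 if self.parent[i] < 0 else self.parent[i] + 1
                x, y, z = self.xyz[i]
                fh.write(f"{i + 1} {self.ntype[i]} {x:.4f} {y:.4f} {z:.4f} "
                         f"{self.radius[i]:.4f} {pid}\n")

    @classmethod
    def from_swc(cls, path) -> "Morphology":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 7:
                    raise ValueError(f"malformed SWC line: {line!r}")
                rows.append(parts)
        ids = np.array([int(r[0]) for r in rows])
        order = np.argsort(ids)
        rows = [rows[i] for i in order]
        id_map = {int(r[0]): k for k, r in enumerate(rows)}
        xyz = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
        radius = np.array([float(r[5]) for r in rows])
        ntype = np.array([int(r[1]) for r in rows])
        parent = np.array([-1 if int(r[6]) < 0 else id_map[int(r[6])] for r in rows])
        return cls(xyz=xyz, radius=radius, parent=parent, ntype=ntype)
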