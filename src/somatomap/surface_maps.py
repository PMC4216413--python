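"""Surface-mesh geometry, cortical-depth projections, and color blending."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "dijkstra_distance",
    "nearest_vertex",
    "depth_max_projection",
    "depth_phase_average",
    "blend_layers",
    "alpha_from_z",
    "N_DEPTHS",
]

#: white/gray interface, 9 intermediates, pial surface
N_DEPTHS = 11


@dataclass
class SurfaceMesh:
    """Triangulated surface with Euclidean edge weights."""

    vertices: np.ndarray              # (n, 3) mm
    triangles: np.ndarray | None = None
    edges: np.ndarray | None = None   # (m, 2) vertex pairs
    _graph: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.edges is None:
            if self.triangles is None:
                raise ValueError("mesh needs triangles or edges")
            tri = np.asarray(self.triangles)
            pairs = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [0, 2]]])
            pairs = np.sort(pairs, axis=1)
            self.edges = np.unique(pairs, axis=0)
        lengths = self.edge_lengths()
        if np.any(lengths <= 0):
            raise ValueError("mesh contains zero-length edges")

    def edge_lengths(self) -> np.ndarray:
        a, b = self.edges[:, 0], self.edges[:, 1]
        return np.linalg.norm(self.vertices[a] - self.vertices[b], axis=1)

    def graph(self):
        if self._graph is None:
            n = len(self.vertices)
            w = self.edge_lengths()
            a, b = self.edges[:, 0], self.edges[:, 1]
            g = coo_matrix((np.r_[w, w], (np.r_[a, b], np.r_[b, a])),
                           shape=(n, n)).tocsr()
            self._graph = g
        return self._graph

    @classmethod
    def read_off(cls, path) -> "SurfaceMesh":
        """Minimal OFF reader (header 'OFF', counts, vertices, faces)."""
        with open(path) as fh:
            tokens = fh.read().split()
        if tokens[0] != "OFF":
            raise ValueError("not an OFF file")
        nv, nf = int(tokens[1]), int(tokens[2])
        pos = 4
        verts = np.array(tokens[pos: pos + 3 * nv], dtype=float).reshape(nv, 3)
        pos += 3 * nv
        faces = []
        for _ in range(nf):
            k = int(tokens[pos])
            faces.append([int(t) for t in tokens[pos + 1: pos + 1 + k]])
            pos += k + 1
        return cls(verts, triangles=np.asarray(faces))

    def write_off(self, path) -> None:
        tri = self.triangles if self.triangles is not None else []
        with open(path, "w") as fh:
            fh.write(f"OFF\n{len(self.vertices)} {len(tri)} 0\n")
            for v in self.vertices:
                fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for t in tri:
                fh.write("3 " + " ".join(str(int(i)) for i in t) + "\n")


def dijkstra_distance(mesh: SurfaceMesh, v_start: int, v_end: int) -> float:
    """Shortest-path length (mm) along mesh edges."""
    dist = _csgraph_dijkstra(mesh.graph(), indices=v_start)[v_end]
    if not np.isfinite(dist):
        raise ValueError(f"vertices {v_start} and {v_end} are disconnected")
    return float(dist)


def nearest_vertex(mesh: SurfaceMesh, point_mm) -> int:
    """Vertex closest to a point; ties broken by lowest id."""
    d2 = ((mesh.vertices - np.asarray(point_mm, dtype=float)) ** 2).sum(axis=1)
    winner = int(np.argmin(d2))
    if (d2 == d2[winner]).sum() > 1:
        logger.info("nearest_vertex tie at point %s; keeping id %d",
                    point_mm, winner)
    return winner


def depth_max_projection(stack: np.ndarray) -> np.ndarray:
    """Maximum over cortical depths; all-missing vertices give NaN.

    ``stack`` has shape (n_vertices, n_depths); missing values are NaN.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[1] != N_DEPTHS:
        raise ValueError(f"depth stack must have {N_DEPTHS} depths")
    all_missing = np.isnan(stack).all(axis=1)
    safe = np.where(all_missing[:, None], 0.0, stack)
    out = np.nanmax(safe, axis=1)
    out[all_missing] = np.nan
    return out


def depth_phase_average(amp_stack: np.ndarray,
                        phase_stack: np.ndarray) -> np.ndarray:
    """Phase of the amplitude-weighted complex average across depths.

    Output in [0, 2*pi); vertices with zero total amplitude give NaN.
    """
    amp = np.asarray(amp_stack, dtype=float)
    phase = np.asarray(phase_stack, dtype=float)
    if amp.shape != phase.shape:
        raise ValueError("amplitude and phase stacks must be congruent")
    z = np.nansum(amp * np.exp(1j * phase), axis=1)
    out = np.mod(np.angle(z), 2 * np.pi)
    out[np.abs(z) == 0] = np.nan
    return out


def blend_layers(layers) -> np.ndarray:
    """Additively blend premultiplied RGBA layers.

    Each layer is (..., 4) RGBA in [0, 1].  Channels are premultiplied by
    alpha, then folded pairwise with ``C = C_A * (1 - C_B) + C_B`` (equal to
    ``C_A + C_B - C_A * C_B``, hence commutative and associative); result is
    clamped to [0, 1] and returned as RGB.
    """
    layers = [np.asarray(l, dtype=float) for l in layers]
    if not layers:
        raise ValueError("no layers to blend")
    out = None
    for layer in layers:
        if layer.shape[-1] != 4:
            raise ValueError("layers must be RGBA")
        if np.any(layer < 0) or np.any(layer > 1):
            raise ValueError("channels and alpha must lie in [0, 1]")
        pre = layer[..., :3] * layer[..., 3:4]
        out = pre if out is None else out * (1.0 - pre) + pre
    return np.clip(out, 0.0, 1.0)


def alpha_from_z(z, z_lo: float = 0.0, z_hi: float = 4.0) -> np.ndarray:
    """Affine ramp mapping Z-values to alpha in [0, 1] between two anchors."""
    z = np.asarray(z, dtype=float)
    if z_hi <= z_lo:
        raise ValueError("z_hi must exceed z_lo")
    return np.clip((z - z_lo) / (z_hi - z_lo), 0.0, 1.0)
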