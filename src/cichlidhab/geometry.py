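"""3D reconstruction of a string-subdivided survey quadrat.

A rectangular survey quadrat is subdivided with taut string into 1 x 1 m
cells.  Divers record the water depth at every string node; the string
spacing gives the 3D chord length between adjacent nodes.  From these two
ingredients the full 3D node lattice is recovered: depths provide z, and
the (x, y) of each node is solved by intersecting spheres centred on its
two already-placed neighbours (two-anchor trilateration).

From the embedded lattice each cell gets a mean depth, a substratum
inclination (mean angle between the vertical axis and the normals of the
four triangles formed by its corner nodes), and a substratum class from
the dominant grain size of the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSTRATUM_CLASSES = ("rock", "stone", "rubble", "gravel", "sand")


class GeometryError(ValueError):
    """Raised when the node lattice cannot be embedded in 3D."""


@dataclass
class NodeGrid:
    """Depths at the nodes of an (n_rows x n_cols)-cell quadrat.

    ``depth[i, j]`` is the water depth in metres (positive downward) at
    node row ``i`` (0 = shallow edge), column ``j``.  The depth matrix has
    one more row and column than the cell grid.  ``edge_length`` is the
    taut-string spacing between adjacent nodes, interpreted as the 3D
    chord length.
    """

    depth: np.ndarray
    edge_length: float = 1.0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2 or min(self.depth.shape) < 2:
            raise ValueError("depth must be a 2D matrix of node depths, at least 2x2")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("all node depths must be finite")
        if not np.all(self.depth > 0):
            raise ValueError("all node depths must be positive (metres below surface)")
        if not (self.edge_length > 0):
            raise ValueError("edge_length must be positive")

    @property
    def n_rows(self) -> int:
        """Number of cells along the slope."""
        return self.depth.shape[0] - 1

    @property
    def n_cols(self) -> int:
        """Number of cells along the shore."""
        return self.depth.shape[1] - 1


@dataclass
class EmbeddedGrid:
    """3D node coordinates plus per-edge reconstruction residuals."""

    coords: np.ndarray  # (n_rows+1, n_cols+1, 3)
    residuals: np.ndarray  # abs deviation of each reconstructed edge from edge_length
    edge_length: float = 1.0

    @property
    def max_residual(self) -> float:
        return float(np.max(self.residuals)) if self.residuals.size else 0.0


def solve_node_position(
    anchor_a,
    anchor_b,
    z_new: float,
    d_a: float,
    d_b: float,
    orientation: int = 1,
) -> tuple[float, float]:
    """Locate a node of known depth from its distances to two placed nodes.

    Intersects the spheres of radius ``d_a`` and ``d_b`` centred on the two
    anchors with the horizontal plane ``z = z_new`` and returns the planar
    intersection point whose handedness matches ``orientation``:
    +1 selects the solution with positive z-component of
    ``(b - a) x (p - a)`` in the plane, -1 the mirror solution.
    """
    a = np.asarray(anchor_a, dtype=float)
    b = np.asarray(anchor_b, dtype=float)
    if d_a <= 0 or d_b <= 0:
        raise GeometryError("anchor distances must be positive")
    # Sphere ∩ plane -> circle of radius sqrt(d² − Δz²)
    ra2 = d_a * d_a - (z_new - a[2]) ** 2
    rb2 = d_b * d_b - (z_new - b[2]) ** 2
    if ra2 < -1e-12 or rb2 < -1e-12:
        raise GeometryError(
            "vertical offset exceeds node distance: no real intersection "
            f"(|dz_a|={abs(z_new - a[2]):.3f} vs d_a={d_a:.3f}, "
            f"|dz_b|={abs(z_new - b[2]):.3f} vs d_b={d_b:.3f})"
        )
    ra = math.sqrt(max(ra2, 0.0))
    rb = math.sqrt(max(rb2, 0.0))

    ax, ay = a[0], a[1]
    bx, by = b[0], b[1]
    dx, dy = bx - ax, by - ay
    d = math.hypot(dx, dy)
    if d < 1e-12:
        raise GeometryError("coincident anchors: planar circle centres overlap")
    if d > ra + rb + 1e-9 or d < abs(ra - rb) - 1e-9:
        raise GeometryError(
            f"circles do not intersect (centre distance {d:.4f}, radii {ra:.4f}, {rb:.4f})"
        )
    # standard two-circle intersection
    u = (ra * ra - rb * rb + d * d) / (2 * d)
    h2 = ra * ra - u * u
    h = math.sqrt(max(h2, 0.0))
    mx = ax + u * dx / d
    my = ay + u * dy / d
    # offset perpendicular to the centre line; sign fixes handedness
    ox = -dy / d * h
    oy = dx / d * h
    s = 1.0 if orientation >= 0 else -1.0
    return (mx + s * ox, my + s * oy)


def embed_grid(grid: NodeGrid, refine: bool = False, warn_tol: float = 1e-6):
    """Embed the node lattice in 3D from depths and the string spacing.

    Node (0,0) is placed at the origin; the first node row extends along
    the +x half-axis with y = 0.  Each later node is trilaterated from its
    west and north neighbours; of the two mirror solutions, the one that
    keeps the lattice right-handed (columns +x, rows +y) is retained.
    Propagation is row-major, hence deterministic.

    With ``refine=True`` a global least-squares pass over all edges follows
    the sequential seeding, for field data whose distances are inconsistent.
    Returns an :class:`EmbeddedGrid`; inconsistent input beyond ``warn_tol``
    leaves its trace in the residuals.
    """
    L = grid.edge_length
    z = grid.depth
    nr, nc = z.shape
    coords = np.zeros((nr, nc, 3))
    coords[:, :, 2] = z

    def _hchord(z1: float, z2: float, where: str) -> float:
        h2 = L * L - (z2 - z1) ** 2
        if h2 < 0:
            raise GeometryError(
                f"infeasible edge at node {where}: depth step {abs(z2 - z1):.3f} m "
                f"exceeds string spacing {L:.3f} m"
            )
        return math.sqrt(h2)

    # first row: pure chord constraint along y = 0
    for j in range(1, nc):
        h = _hchord(z[0, j - 1], z[0, j], f"(0,{j})")
        coords[0, j, 0] = coords[0, j - 1, 0] + h
    # first column of each later row: advance +y below the north neighbour
    for i in range(1, nr):
        h = _hchord(z[i - 1, 0], z[i, 0], f"({i},0)")
        coords[i, 0, 0] = coords[i - 1, 0, 0]
        coords[i, 0, 1] = coords[i - 1, 0, 1] + h
        for j in range(1, nc):
            north = coords[i - 1, j]
            west = coords[i, j - 1]
            try:
                # orientation −1 with (a=north, b=west) keeps the lattice
                # unfolded: the new node lies south-east of its anchors
                x, y = solve_node_position(north, west, z[i, j], L, L, orientation=-1)
            except GeometryError as exc:
                raise GeometryError(f"node ({i},{j}): {exc}") from exc
            coords[i, j, 0] = x
            coords[i, j, 1] = y

    if refine:
        coords = _refine_embedding(coords, L)

    residuals = _edge_residuals(coords, L)
    if residuals.size and residuals.max() > warn_tol:
        import warnings

        warnings.warn(
            f"over-determined edge distances inconsistent: max residual "
            f"{residuals.max():.3e} m exceeds {warn_tol:.0e} m",
            stacklevel=2,
        )
    return EmbeddedGrid(coords=coords, residuals=residuals, edge_length=L)


def _edge_residuals(coords: np.ndarray, L: float) -> np.ndarray:
    row_edges = np.linalg.norm(np.diff(coords, axis=0), axis=-1)
    col_edges = np.linalg.norm(np.diff(coords, axis=1), axis=-1)
    return np.abs(np.concatenate([row_edges.ravel(), col_edges.ravel()]) - L)


def _refine_embedding(coords: np.ndarray, L: float) -> np.ndarray:
    """Least-squares polish of (x, y) over all edge-length constraints."""
    from scipy.optimize import least_squares

    nr, nc, _ = coords.shape
    z = coords[:, :, 2]

    def pack(c):
        return c[:, :, :2].ravel()

    def unpack(v):
        out = coords.copy()
        out[:, :, :2] = v.reshape(nr, nc, 2)
        return out

    def fun(v):
        c = unpack(v)
        return _edge_residuals(c, L)

    sol = least_squares(fun, pack(coords), method="trf", xtol=1e-12, ftol=1e-12)
    refined = unpack(sol.x)
    # pin the gauge: node (0,0) at origin, node (0,1) on the +x axis
    refined[:, :, :2] -= refined[0, 0, :2]
    v01 = refined[0, 1, :2]
    ang = math.atan2(v01[1], v01[0])
    rot = np.array([[math.cos(-ang), -math.sin(-ang)], [math.sin(-ang), math.cos(-ang)]])
    refined[:, :, :2] = refined[:, :, :2] @ rot.T
    refined[:, :, 2] = z
    return refined


def triangle_normal(p1, p2, p3) -> np.ndarray:
    """Unit normal of the triangle (p1, p2, p3); error on degeneracy."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate triangle: collinear or duplicate points")
    return n / norm


def square_inclination(corner_coords) -> float:
    """Inclination of a grid cell, in degrees within [0, 90].

    ``corner_coords`` are the four corner nodes in cyclic order.  Four
    triangles are formed by dropping each corner in turn; the inclination
    is the arithmetic mean of the four angles between each triangle normal
    and the vertical axis (folded into [0, 90] via |n_z|).
    """
    pts = [np.asarray(p, dtype=float) for p in corner_coords]
    if len(pts) != 4:
        raise ValueError("square_inclination expects exactly 4 corner points")
    angles = []
    for drop in range(4):
        tri = [pts[k] for k in range(4) if k != drop]
        n = triangle_normal(*tri)
        angles.append(math.degrees(math.acos(min(abs(n[2]), 1.0))))
    return float(np.mean(angles))


def classify_substratum(dominant_grain_size: float) -> str:
    """Map a dominant grain size (cm) to one of the five substratum classes.

    sand [0, 0.5) < gravel [0.5, 3) < rubble [3, 20) < stone [20, 50] < rock (50, ∞).
    """
    s = float(dominant_grain_size)
    if not (s > 0) or not math.isfinite(s):
        raise ValueError(f"grain size must be positive and finite, got {dominant_grain_size!r}")
    if s < 0.5:
        return "sand"
    if s < 3:
        return "gravel"
    if s < 20:
        return "rubble"
    if s <= 50:
        return "stone"
    return "rock"


def apply_water_level_offset(grid: NodeGrid, offset: float) -> NodeGrid:
    """Shift all node depths by a lake-level offset (pure translation)."""
    if not math.isfinite(offset):
        raise ValueError("offset must be finite")
    shifted = grid.depth + offset
    if np.any(shifted <= 0):
        raise ValueError(
            f"offset {offset:+.2f} m drives {int(np.sum(shifted <= 0))} node(s) "
            "to non-positive depth"
        )
    return NodeGrid(depth=shifted, edge_length=grid.edge_length)


def depth_summary(grid: NodeGrid) -> dict:
    """Min, max, range and mean of the node depths, in metres."""
    d = grid.depth
    return {
        "min": float(d.min()),
        "max": float(d.max()),
        "range": float(d.max() - d.min()),
        "mean": float(d.mean()),
    }


def cell_attributes(
    embedded: EmbeddedGrid,
    substratum: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell mean depth, inclination and (optionally) substratum class.

    ``substratum`` is a DataFrame with columns (row, col) plus either
    ``substratum`` (pre-classified) or ``dominant_grain_cm``.  Returns a
    DataFrame with one row per cell: row, col, mean_depth_m,
    inclination_deg and, when available, substratum.
    """
    c = embedded.coords
    nr, nc = c.shape[0] - 1, c.shape[1] - 1
    rows = []
    for i in range(nr):
        for j in range(nc):
            corners = [c[i, j], c[i, j + 1], c[i + 1, j + 1], c[i + 1, j]]
            mean_depth = float(np.mean([p[2] for p in corners]))
            incl = square_inclination(corners)
            rows.append({"row": i, "col": j, "mean_depth_m": mean_depth, "inclination_deg": incl})
    out = pd.DataFrame(rows)
    if substratum is not None:
        sub = substratum.copy()
        if "substratum" not in sub.columns:
            if "dominant_grain_cm" not in sub.columns:
                raise ValueError(
                    "substratum table needs a 'substratum' or 'dominant_grain_cm' column"
                )
            sub["substratum"] = sub["dominant_grain_cm"].map(classify_substratum)
        bad = set(sub["substratum"]) - set(SUBSTRATUM_CLASSES)
        if bad:
            raise ValueError(f"unknown substratum classes: {sorted(bad)}")
        out = out.merge(sub[["row", "col", "substratum"]], on=["row", "col"], how="left")
        if out["substratum"].isna().any():
            missing = out[out["substratum"].isna()][["row", "col"]].values.tolist()
            raise ValueError(f"substratum missing for cells {missing[:5]}...")
    return out


# ---------------------------------------------------------------------------
# I/O

def read_node_depths(path) -> NodeGrid:
    """Read a node-depth TSV (columns: row, col, depth_m) into a NodeGrid."""
    df = pd.read_csv(path, sep="\t")
    required = {"row", "col", "depth_m"}
    if not required.issubset(df.columns):
        raise ValueError(f"node-depth TSV must have columns {sorted(required)}")
    nr = int(df["row"].max()) + 1
    nc = int(df["col"].max()) + 1
    depth = np.full((nr, nc), np.nan)
    depth[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df["depth_m"].to_numpy(float)
    if np.isnan(depth).any():
        raise ValueError("node-depth TSV does not cover the full node lattice")
    return NodeGrid(depth=depth)


def write_node_depths(grid: NodeGrid, path) -> None:
    nr, nc = grid.depth.shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pd.DataFrame(
        {"row": ii.ravel(), "col": jj.ravel(), "depth_m": grid.depth.ravel()}
    ).to_csv(path, sep="\t", index=False)


def write_embedded_grid(embedded: EmbeddedGrid, path) -> None:
    c = embedded.coords
    nr, nc, _ = c.shape
    ii, jj = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pd.DataFrame(
        {
            "row": ii.ravel(),
            "col": jj.ravel(),
            "x": c[:, :, 0].ravel(),
            "y": c[:, :, 1].ravel(),
            "z": c[:, :, 2].ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_obj_mesh(embedded: EmbeddedGrid, path) -> None:
    """Export the embedded lattice as a Wavefront OBJ triangle mesh."""
    c = embedded.coords
    nr, nc, _ = c.shape
    with open(path, "w") as fh:
        for i in range(nr):
            for j in range(nc):
                x, y, z = c[i, j]
                fh.write(f"v {x:.6f} {y:.6f} {-z:.6f}\n")

        def vid(i, j):
            return i * nc + j + 1

        for i in range(nr - 1):
            for j in range(nc - 1):
                fh.write(f"f {vid(i, j)} {vid(i, j + 1)} {vid(i + 1, j + 1)}\n")
                fh.write(f"f {vid(i, j)} {vid(i + 1, j + 1)} {vid(i + 1, j)}\n")
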