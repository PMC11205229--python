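"""Fovea-centred 10-2 test grid: construction, rotation, ganglion-cell
displacement and the strategy-specific neighbour graph.

Coordinates are visual-field degrees, fovea at the origin, x positive
temporal (right-eye convention), y positive superior.  Left eyes are
handled by mirroring x on input and un-mirroring on output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "VFPoint",
    "TestGrid",
    "NeighborGraph",
    "DisplacementModel",
    "build_10_2_grid",
    "rotate_grid",
    "displace_locations",
    "build_neighbor_graph",
    "grid_to_text",
    "grid_from_text",
    "graph_to_text",
]

#: squared-radius membership bound reproducing the 68-point 10-2 pattern
_MEMBERSHIP_R2 = 85.0


class VFPoint(NamedTuple):
    """A visual-field position in degrees (x temporal-positive, y superior-positive)."""

    x: float
    y: float


@dataclass(frozen=True)
class TestGrid:
    """The 68-location test pattern.

    Attributes
    ----------
    nominal:
        (68, 2) array of the unrotated, fovea-origin pattern coordinates.
        Never changes; neighbourhood relations are defined on it.
    locations:
        (68, 2) array of current stimulus coordinates in the fundus
        reference frame (equal to ``nominal`` until rotated).
    displaced:
        (68, 2) array of the retinal positions of the underlying ganglion
        cells (equal to ``locations`` until displacement is applied).
    """

    __test__ = False  # not a pytest collection target

    nominal: np.ndarray
    locations: np.ndarray
    displaced: np.ndarray
    rotation_deg: float = 0.0
    fovea: VFPoint = VFPoint(0.0, 0.0)
    onh_center: VFPoint | None = None

    def __post_init__(self) -> None:
        n = self.nominal.shape[0]
        for name in ("nominal", "locations", "displaced"):
            arr = getattr(self, name)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite coordinates")

    @property
    def n(self) -> int:
        return self.nominal.shape[0]

    def eccentricity(self, which: str = "nominal") -> np.ndarray:
        """Per-location distance (deg) from the grid centre."""
        pts = getattr(self, which)
        centre = np.asarray(self.fovea) if which != "nominal" else np.zeros(2)
        return np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])


@dataclass(frozen=True)
class NeighborGraph:
    """Weighted nearest-neighbour graph over grid location indices."""

    edges: frozenset[tuple[int, int]]  # (i, j) with i < j
    weight: float
    n: int = 68
    #: adjacency lists, precomputed for the test loop
    adjacency: tuple[tuple[int, ...], ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edge in neighbour graph")
            if not (0 <= i < j < self.n):
                raise ValueError(f"edge ({i}, {j}) out of range or unordered")
        if not self.adjacency:
            adj: list[list[int]] = [[] for _ in range(self.n)]
            for i, j in sorted(self.edges):
                adj[i].append(j)
                adj[j].append(i)
            object.__setattr__(self, "adjacency", tuple(tuple(a) for a in adj))

    def neighbors(self, i: int) -> tuple[int, ...]:
        return self.adjacency[i]

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges


@dataclass(frozen=True)
class DisplacementModel:
    """Radial ganglion-cell displacement curve.

    Displacement magnitude at eccentricity ``r`` is
    ``amplitude * (r / peak_ecc) * exp(1 - r / peak_ecc)`` inside
    ``extent_deg`` and exactly zero outside.  The default parameters give a
    ~2 deg peak near 1.5 deg eccentricity decaying to ~0 by 17 deg.  The
    class is pluggable: substitute any object with a ``magnitude`` method to
    use a published formulation instead.
    """

    amplitude: float = 2.0
    peak_ecc: float = 1.5
    extent_deg: float = 17.0

    def magnitude(self, ecc: np.ndarray | float) -> np.ndarray:
        r = np.asarray(ecc, dtype=float)
        with np.errstate(over="ignore"):
            d = self.amplitude * (r / self.peak_ecc) * np.exp(1.0 - r / self.peak_ecc)
        return np.where((r > 0) & (r < self.extent_deg), d, 0.0)


def _pattern_points() -> np.ndarray:
    pts = [
        (x, y)
        for y in range(9, -10, -2)  # superior to inferior
        for x in range(-9, 10, 2)  # nasal to temporal
        if x * x + y * y <= _MEMBERSHIP_R2
    ]
    return np.asarray(pts, dtype=float)


def build_10_2_grid() -> TestGrid:
    """Build the nominal, unrotated 10-2 grid with the fovea at the origin.

    Locations are the odd-integer pairs with ``x**2 + y**2 <= 85`` (the
    standard 68-point pattern), ordered row-major from superior to inferior.
    """
    pts = _pattern_points()
    return TestGrid(nominal=pts, locations=pts.copy(), displaced=pts.copy())


def rotate_grid(grid: TestGrid, fovea: VFPoint, onh_center: VFPoint) -> TestGrid:
    """Rotate the grid about the fovea so its midline follows the fovea-disc axis.

    The rotation angle is the angle of the fovea->ONH vector relative to
    horizontal.  Pairwise distances are preserved.  Displaced coordinates
    are reset to the rotated locations (apply displacement afterwards).
    """
    dx = onh_center.x - fovea.x
    dy = onh_center.y - fovea.y
    if math.hypot(dx, dy) < 1e-12:
        raise ValueError("fovea and ONH centre coincide: fovea-disc axis undefined")
    theta = math.atan2(dy, dx)
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    pivot = np.asarray(grid.fovea, dtype=float)
    rotated = (grid.locations - pivot) @ rot.T + np.asarray(fovea, dtype=float)
    return replace(
        grid,
        locations=rotated,
        displaced=rotated.copy(),
        rotation_deg=grid.rotation_deg + math.degrees(theta),
        fovea=fovea,
        onh_center=onh_center,
    )


def displace_locations(grid: TestGrid, model: DisplacementModel | None = None) -> TestGrid:
    """Map each stimulus location to the retinal position of its ganglion cells.

    Displacement is radial (centrifugal) from the fovea; the identity at the
    fovea and beyond the model's extent.
    """
    if model is None:
        model = DisplacementModel()
    pivot = np.asarray(grid.fovea, dtype=float)
    rel = grid.locations - pivot
    ecc = np.hypot(rel[:, 0], rel[:, 1])
    mag = model.magnitude(ecc)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(ecc > 0, (ecc + mag) / np.where(ecc > 0, ecc, 1.0), 1.0)
    return replace(grid, displaced=pivot + rel * scale[:, None])


def build_neighbor_graph(
    grid: TestGrid,
    mode: str,
    predictions: Sequence[float] | np.ndarray | None = None,
    *,
    weight: float | None = None,
    disconnect_db: float = 1.0,
) -> NeighborGraph:
    """Connect nearest neighbours (nominal distance exactly 2 deg).

    ``mode='standard'``: weight 0.2, edges never cross the horizontal
    midline.  ``mode='structural'``: weight 0.4, edges removed where the
    structure-function predictions differ by more than ``disconnect_db``.
    """
    if mode not in ("standard", "structural"):
        raise ValueError(f"mode must be 'standard' or 'structural', got {mode!r}")
    if mode == "structural":
        if predictions is None:
            raise ValueError("structural mode requires per-location predictions")
        pred = np.asarray(predictions, dtype=float)
        if pred.shape != (grid.n,):
            raise ValueError(f"predictions must have length {grid.n}")
    w = weight if weight is not None else (0.2 if mode == "standard" else 0.4)

    pts = grid.nominal
    edges: set[tuple[int, int]] = set()
    for i in range(grid.n):
        for j in range(i + 1, grid.n):
            d = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
            if abs(d - 2.0) > 1e-9:
                continue
            if mode == "standard":
                if pts[i, 1] * pts[j, 1] < 0:  # opposite hemifields
                    continue
            else:
                if abs(pred[i] - pred[j]) > disconnect_db:
                    continue
            edges.add((i, j))
    return NeighborGraph(edges=frozenset(edges), weight=w, n=grid.n)


# ---------------------------------------------------------------------------
# delimited-text I/O

def grid_to_text(grid: TestGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("index\tx_nominal\ty_nominal\tx_displaced\ty_displaced\n")
        for i in range(grid.n):
            fh.write(
                f"{i}\t{grid.nominal[i, 0]:.6f}\t{grid.nominal[i, 1]:.6f}"
                f"\t{grid.displaced[i, 0]:.6f}\t{grid.displaced[i, 1]:.6f}\n"
            )


def grid_from_text(path) -> TestGrid:
    data = np.loadtxt(path, skiprows=1)
    nominal = data[:, 1:3]
    displaced = data[:, 3:5]
    return TestGrid(nominal=nominal, locations=nominal.copy(), displaced=displaced)


def graph_to_text(graph: NeighborGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i}\t{j}\t{graph.weight}\n")
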