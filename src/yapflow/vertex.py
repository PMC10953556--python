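"""Minimal vertex model of an endothelial monolayer with actin-cap heterogeneity.

The monolayer is a planar polygonal tiling; each polygon is one cell.  The
tissue energy is the canonical area/perimeter/line-tension form plus one
contractile conventional-fiber element per cell, aligned with the flow
(x) axis:

    E = Σ_cells [ K_A/2 (A−A0)² + Γ/2 P² + s_eff·f_scale·|r_b − r_a| ]
        + Σ_edges Λ·ℓ

where (r_a, r_b) are the cell's extreme-x vertices (the fiber anchors) and
s_eff is the cell's dimensionless fiber stress.  Cells carrying a
perinuclear actin cap have their conventional-fiber tension reduced (cap
assembly draws on the same actin pool) and their nuclear-strain
susceptibility lowered through the same shielding law as the single-cell
model.

Quasi-static experiments supported: energy relaxation (fixed topology, no
T1 transitions), simulated laser ablation with the opening-ellipse
short/long axis ratio ("recoil angle") as tension read-out, a per-cell
nuclear-strain proxy field, and nematic ±1/2 topological-defect detection
on the cell-elongation director.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import Voronoi

from .mechanics import MechanicsParams, shielding_weight

__all__ = [
    "VertexParams",
    "VertexMesh",
    "AblationResult",
    "DefectSet",
    "build_monolayer",
    "energy",
    "energy_gradient",
    "relax",
    "ablate_and_recoil",
    "assign_cap_heterogeneity",
    "nuclear_strain_field",
    "detect_defects",
    "boundary_winding",
    "cell_shape_tensor",
    "cell_shape_ratio",
]


@dataclass(frozen=True)
class VertexParams:
    """Energy coefficients (lengths in units of the preferred cell size)."""

    K_A: float = 1.0
    A0: float = 1.0
    Gamma: float = 0.04
    Lambda: float = 0.02
    f_scale: float = 0.15        # fiber tension scale per unit s
    cap_tension_draw: float = 0.7  # fractional fiber-tension loss in capped cells
    grad_tol: float = 1.0e-6     # relaxation gradient-norm tolerance
    max_iter: int = 20000

    def __post_init__(self) -> None:
        if self.K_A <= 0 or self.A0 <= 0:
            raise ValueError("K_A and A0 must be positive")


@dataclass
class VertexMesh:
    """Polygonal monolayer with per-cell cap and fiber-stress attributes."""

    vertices: np.ndarray                 # (V, 2), µm (preferred-size units)
    cells: list                          # list of ccw vertex-index loops
    pinned: np.ndarray                   # (V,) bool: outer boundary fixed
    has_cap: np.ndarray = None
    cap_strength: np.ndarray = None
    fiber_stress: np.ndarray = None
    ablated: np.ndarray = None
    anchors: list = None                 # per-cell (min-x, max-x) vertex pair
    relaxed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.cells)
        if self.has_cap is None:
            self.has_cap = np.zeros(n, dtype=bool)
        if self.cap_strength is None:
            self.cap_strength = np.zeros(n, dtype=float)
        if self.fiber_stress is None:
            self.fiber_stress = np.zeros(n, dtype=float)
        if self.ablated is None:
            self.ablated = np.zeros(n, dtype=bool)
        if self.anchors is None:
            self.anchors = [_anchor_pair(self.vertices, loop) for loop in self.cells]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def edges(self) -> set:
        out = set()
        for loop in self.cells:
            for i, v in enumerate(loop):
                out.add(tuple(sorted((v, loop[(i + 1) % len(loop)]))))
        return out

    def effective_fiber_stress(self, params: VertexParams) -> np.ndarray:
        s = self.fiber_stress.copy()
        capped = self.has_cap
        s[capped] *= np.clip(
            1.0 - params.cap_tension_draw * self.cap_strength[capped], 0.0, None)
        return s

    def cell_polygon(self, i: int) -> np.ndarray:
        return self.vertices[self.cells[i]]

    def boundary_cells(self) -> np.ndarray:
        return np.array([bool(self.pinned[loop].any()) for loop in self.cells])

    def vertex_cells(self) -> dict:
        """vertex index -> list of adjacent cell indices."""
        out: dict[int, list[int]] = {}
        for ci, loop in enumerate(self.cells):
            for v in loop:
                out.setdefault(v, []).append(ci)
        return out

    def check_euler(self) -> None:
        v = len(self.vertices)
        e = len(self.edges)
        f = self.n_cells + 1  # outer face
        if v - e + f != 2:
            raise ValueError("mesh violates the Euler relation")

    def copy(self) -> "VertexMesh":
        return copy.deepcopy(self)


def _anchor_pair(vertices, loop):
    """Fiber anchors: the min-x and max-x vertices, ties broken by min y.

    Coordinates are rounded so exact lattice ties resolve identically in
    every cell — on the unjittered lattice the fiber forces of adjacent
    cells then cancel and the perfect tiling is an exact equilibrium.
    """
    pts = vertices[loop]
    x = np.round(pts[:, 0], 9)
    y = np.round(pts[:, 1], 9)
    lo = min(range(len(loop)), key=lambda i: (x[i], y[i]))
    hi = min(range(len(loop)), key=lambda i: (-x[i], y[i]))
    return (loop[lo], loop[hi])


def build_monolayer(n_cells: int, jitter: float = 0.0, seed: int = 0) -> VertexMesh:
    """Voronoi tessellation of a jittered hexagonal lattice.

    The lattice spacing is set so the preferred cell area is 1; cells are
    pointy-top hexagons at zero jitter (taller along y than x, so the
    fiber axis x is the initial short axis).  Two padding rings of
    generators guarantee every kept cell is finite; outer mesh vertices
    are pinned.  Deterministic per seed.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    rng = np.random.default_rng(seed)
    d = math.sqrt(2.0 / math.sqrt(3.0))   # unit-area hexagons
    n_rows = int(round(math.sqrt(n_cells)))
    n_cols = int(math.ceil(n_cells / n_rows))
    pad = 2
    points, interior = [], []
    for row in range(-pad, n_rows + pad):
        for col in range(-pad, n_cols + pad):
            x = (col + 0.5 * (row % 2)) * d
            y = row * d * math.sqrt(3.0) / 2.0
            idx = len(points)
            points.append((x, y))
            if 0 <= row < n_rows and 0 <= col < n_cols:
                interior.append(idx)
    points = np.asarray(points, dtype=float)
    if jitter > 0:
        points = points + rng.uniform(-0.5, 0.5, points.shape) * jitter * d
    interior = interior[:n_cells]
    vor = Voronoi(points)
    vmap: dict[int, int] = {}
    vertices: list = []
    cells = []
    for pi in interior:
        region = vor.regions[vor.point_region[pi]]
        if -1 in region or not region:
            raise RuntimeError("padding insufficient: unbounded Voronoi cell")
        loop = []
        for vi in region:
            if vi not in vmap:
                vmap[vi] = len(vertices)
                vertices.append(vor.vertices[vi])
            loop.append(vmap[vi])
        pts = np.asarray([vertices[i] for i in loop])
        area = 0.5 * np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                            - np.roll(pts[:, 0], -1) * pts[:, 1])
        if area < 0:
            loop = loop[::-1]
        cells.append(loop)
    vertices = np.asarray(vertices, dtype=float)
    edge_count: dict[tuple, int] = {}
    for loop in cells:
        for i, v in enumerate(loop):
            e = tuple(sorted((v, loop[(i + 1) % len(loop)])))
            edge_count[e] = edge_count.get(e, 0) + 1
    pinned = np.zeros(len(vertices), dtype=bool)
    for (a, b), c in edge_count.items():
        if c == 1:                      # border edge: only one adjacent cell
            pinned[a] = pinned[b] = True
    mesh = VertexMesh(vertices=vertices, cells=cells, pinned=pinned, seed=seed)
    mesh.check_euler()
    return mesh


# ---------------------------------------------------------------------------
# energy and relaxation


def _polygon_area_perimeter(pts):
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    area = 0.5 * np.sum(x * y1 - x1 * y)
    per = float(np.sum(np.hypot(x1 - x, y1 - y)))
    return float(area), per


def energy(mesh: VertexMesh, params: VertexParams) -> float:
    """Total tissue energy; raises on degenerate (negative-area) polygons."""
    E = 0.0
    s_eff = mesh.effective_fiber_stress(params)
    for ci, loop in enumerate(mesh.cells):
        pts = mesh.vertices[loop]
        area, per = _polygon_area_perimeter(pts)
        if area <= 0:
            raise ValueError(f"degenerate polygon in cell {ci}")
        E += 0.5 * params.K_A * (area - params.A0) ** 2
        E += 0.5 * params.Gamma * per**2
        a, b = mesh.anchors[ci]
        E += s_eff[ci] * params.f_scale * float(
            np.hypot(*(mesh.vertices[b] - mesh.vertices[a])))
    for (a, b) in mesh.edges:
        E += params.Lambda * float(np.hypot(*(mesh.vertices[b] - mesh.vertices[a])))
    return float(E)


def energy_gradient(mesh: VertexMesh, params: VertexParams) -> np.ndarray:
    """Analytic dE/d(vertices), shape (V, 2)."""
    grad = np.zeros_like(mesh.vertices)
    s_eff = mesh.effective_fiber_stress(params)
    for ci, loop in enumerate(mesh.cells):
        idx = np.asarray(loop)
        pts = mesh.vertices[idx]
        area, per = _polygon_area_perimeter(pts)
        nxt = np.roll(pts, -1, axis=0)
        prv = np.roll(pts, 1, axis=0)
        dA = 0.5 * np.stack([nxt[:, 1] - prv[:, 1], prv[:, 0] - nxt[:, 0]], axis=1)
        coeff_a = params.K_A * (area - params.A0)
        e_fwd = nxt - pts
        len_fwd = np.linalg.norm(e_fwd, axis=1, keepdims=True)
        u_fwd = e_fwd / len_fwd
        dP = np.roll(u_fwd, 1, axis=0) - u_fwd
        np.add.at(grad, idx, coeff_a * dA + params.Gamma * per * dP)
        a, b = mesh.anchors[ci]
        dvec = mesh.vertices[b] - mesh.vertices[a]
        norm = float(np.hypot(*dvec))
        if norm > 0 and s_eff[ci] != 0.0:
            u = dvec / norm
            grad[a] -= s_eff[ci] * params.f_scale * u
            grad[b] += s_eff[ci] * params.f_scale * u
    for (a, b) in mesh.edges:
        dvec = mesh.vertices[b] - mesh.vertices[a]
        norm = float(np.hypot(*dvec))
        if norm > 0:
            u = dvec / norm
            grad[a] -= params.Lambda * u
            grad[b] += params.Lambda * u
    return grad


def relax(mesh: VertexMesh, params: VertexParams | None = None) -> VertexMesh:
    """Quasi-static relaxation to a local energy minimum (topology fixed).

    Boundary vertices are pinned; free vertices are moved by L-BFGS with
    the analytic gradient until the free-gradient norm is below
    ``params.grad_tol``.  Energy is non-increasing along the accepted
    iterates.  Raises on non-convergence.
    """
    params = params or VertexParams()
    out = mesh.copy()
    free = ~out.pinned
    if not free.any():
        out.relaxed = True
        return out
    x0 = out.vertices[free].ravel()

    def fun(x):
        out.vertices[free] = x.reshape(-1, 2)
        e = energy(out, params)
        g = energy_gradient(out, params)[free].ravel()
        return e, g

    x = x0
    for _ in range(4):
        res = minimize(fun, x, jac=True, method="L-BFGS-B",
                       options={"maxiter": params.max_iter, "ftol": 1e-18,
                                "gtol": 1e-12})
        x = res.x
        out.vertices[free] = x.reshape(-1, 2)
        gnorm = float(np.linalg.norm(energy_gradient(out, params)[free]))
        if gnorm <= 0.1 * params.grad_tol:
            break
    if gnorm > params.grad_tol:
        raise RuntimeError(
            f"relaxation did not converge: free gradient norm {gnorm:.3e}")
    out.relaxed = True
    return out


# ---------------------------------------------------------------------------
# shape tensors, ablation, strain field, defects


def cell_shape_tensor(mesh: VertexMesh, i: int) -> np.ndarray:
    """Area-weighted second-moment (covariance) tensor of cell i."""
    pts = mesh.cell_polygon(i)
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    A = 0.5 * np.sum(cross)
    cx = np.sum((x + x1) * cross) / (6.0 * A)
    cy = np.sum((y + y1) * cross) / (6.0 * A)
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    cxx = ixx / A - cx * cx
    cyy = iyy / A - cy * cy
    cxy = ixy / A - cx * cy
    return np.array([[cxx, cxy], [cxy, cyy]])


def cell_shape_ratio(mesh: VertexMesh, i: int) -> float:
    """Short/long axis ratio of the ellipse with the cell's second moments."""
    t = cell_shape_tensor(mesh, i)
    lam = np.linalg.eigvalsh(t)
    return float(math.sqrt(max(lam[0], 0.0) / lam[1]))


def cell_director(mesh: VertexMesh, i: int) -> float:
    """Elongation director angle (mod π) of cell i.

    Nearly isotropic cells (regular polygons have isotropic second
    moments) carry no meaningful director; they are reported as 0 so a
    uniform undeformed tiling yields a defect-free field instead of
    round-off noise.
    """
    t = cell_shape_tensor(mesh, i)
    dev = math.hypot(t[0, 0] - t[1, 1], 2.0 * t[0, 1])
    if dev <= 1e-9 * (t[0, 0] + t[1, 1]):
        return 0.0
    return 0.5 * math.atan2(2.0 * t[0, 1], t[0, 0] - t[1, 1])


@dataclass(frozen=True)
class AblationResult:
    opening_long_axis: float
    opening_short_axis: float
    recoil_angle: float          # short/long ∈ [0, 1]
    baseline_angle: float        # pre-ablation ratio of the same cell


def ablate_and_recoil(mesh: VertexMesh, cell_index: int, s: float,
                      params: VertexParams | None = None) -> AblationResult:
    """Sever the target cell's fiber in a monolayer under uniform stress s.

    Every cell carries dimensionless conventional-fiber stress ``s``; the
    tissue is relaxed, the target fiber tension is set to zero across a
    cut line perpendicular to the fiber (the laser cut), and the tissue is
    relaxed again.  The opening ellipse of the recoil is spanned by the
    cut line (long axis: the cell's extent along the cut direction) and
    the recoil opening width (short axis: how far the severed fiber
    anchors spring apart along the fiber axis).  The recoil angle is
    their ratio; with no stored tension (s = 0) nothing is released and
    the angle is zero.  Boundary cells cannot be ablated.
    """
    params = params or VertexParams()
    if s < 0:
        raise ValueError("fiber stress must be non-negative")
    if mesh.boundary_cells()[cell_index]:
        raise ValueError("cannot ablate a boundary cell")
    pre = mesh.copy()
    pre.fiber_stress = np.full(pre.n_cells, float(s))
    pre = relax(pre, params)
    baseline = cell_shape_ratio(pre, cell_index)
    a, b = pre.anchors[cell_index]
    sep_pre = float(abs(pre.vertices[b, 0] - pre.vertices[a, 0]))
    post = pre.copy()
    post.fiber_stress[cell_index] = 0.0
    post.ablated[cell_index] = True
    post = relax(post, params)
    sep_post = float(abs(post.vertices[b, 0] - post.vertices[a, 0]))
    poly_post = post.cell_polygon(cell_index)
    opening = max(0.0, sep_post - sep_pre)
    cut_length = float(np.ptp(poly_post[:, 1]))
    angle = min(opening / cut_length, 1.0)
    return AblationResult(opening_long_axis=cut_length,
                          opening_short_axis=min(opening, cut_length),
                          recoil_angle=angle, baseline_angle=baseline)


def assign_cap_heterogeneity(mesh: VertexMesh, cap_fraction: float,
                             cap_strength: float = 0.3,
                             seed: int = 0) -> VertexMesh:
    """Bernoulli per-cell actin-cap assignment.

    Capped cells get ``cap_strength`` (shielding of nuclear strain and a
    conventional-fiber tension reduction via ``cap_tension_draw``).
    """
    if not 0.0 <= cap_fraction <= 1.0:
        raise ValueError("cap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = mesh.copy()
    out.has_cap = rng.random(out.n_cells) < cap_fraction
    out.cap_strength = np.where(out.has_cap, float(cap_strength), 0.0)
    out.relaxed = False
    return out


def nuclear_strain_field(mesh: VertexMesh,
                         params: VertexParams | None = None,
                         w_half: float = 0.3) -> np.ndarray:
    """Per-cell nuclear-strain proxy on a relaxed mesh.

    The proxy is the cell-shape anisotropy 1 − sqrt(λ_min/λ_max), reduced
    for capped cells by the single-cell shielding weight
    w = c/(c + w_half) evaluated at the cell's cap strength.
    """
    if not mesh.relaxed:
        raise ValueError("mesh must be relaxed before evaluating the strain field")
    mp = MechanicsParams(w_half=w_half)
    out = np.empty(mesh.n_cells)
    for i in range(mesh.n_cells):
        e = 1.0 - cell_shape_ratio(mesh, i)
        w = shielding_weight(float(mesh.cap_strength[i]), mp)
        out[i] = e * (1.0 - w)
    return out


@dataclass(frozen=True)
class DefectSet:
    positions: np.ndarray        # (n, 2)
    charges: np.ndarray          # half-integer winding numbers

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum()) if self.charges.size else 0.0


def _wrap_nematic(delta: float) -> float:
    """Wrap a director-angle difference into [-π/2, π/2)."""
    while delta >= math.pi / 2:
        delta -= math.pi
    while delta < -math.pi / 2:
        delta += math.pi
    return delta


def detect_defects(mesh: VertexMesh, director: np.ndarray | None = None,
                   min_cells: int = 16, include_boundary: bool = False) -> DefectSet:
    """±1/2 nematic defects of the cell-elongation director field.

    The director (principal axis of each cell's shape tensor, mod π) is
    evaluated on plaquettes of the dual lattice: for every mesh vertex
    with three adjacent cells, the winding number of the director around
    the ordered cell triple is accumulated with nematic (mod π) wrapping.
    ``director`` may be supplied explicitly (one angle per cell).  By
    default plaquettes touching boundary-clamped cells are skipped: their
    shapes are pinning artifacts, not part of the bulk director field.
    """
    if mesh.n_cells < min_cells:
        raise ValueError("need at least 16 cells for defect detection")
    theta = (np.asarray(director, dtype=float) if director is not None
             else np.array([cell_director(mesh, i) for i in range(mesh.n_cells)]))
    centroids = np.array([mesh.cell_polygon(i).mean(axis=0)
                          for i in range(mesh.n_cells)])
    positions, charges = [], []
    bcells = mesh.boundary_cells()
    for v, cells in mesh.vertex_cells().items():
        if len(cells) != 3 or mesh.pinned[v]:
            continue
        if not include_boundary and any(bcells[c] for c in cells):
            continue
        p = mesh.vertices[v]
        ang = np.arctan2(*(centroids[cells] - p).T[::-1])
        order = [cells[k] for k in np.argsort(ang)]
        total = 0.0
        for i in range(3):
            total += _wrap_nematic(theta[order[(i + 1) % 3]] - theta[order[i]])
        q = total / (2.0 * math.pi)
        q_round = round(q * 2.0) / 2.0
        if abs(q_round) >= 0.5:
            positions.append(p)
            charges.append(q_round)
    return DefectSet(
        positions=np.asarray(positions, dtype=float).reshape(-1, 2),
        charges=np.asarray(charges, dtype=float),
    )


def boundary_winding(mesh: VertexMesh, director: np.ndarray | None = None) -> float:
    """Director winding along the angle-ordered loop of peripheral cells."""
    theta = (np.asarray(director, dtype=float) if director is not None
             else np.array([cell_director(mesh, i) for i in range(mesh.n_cells)]))
    centroids = np.array([mesh.cell_polygon(i).mean(axis=0)
                          for i in range(mesh.n_cells)])
    boundary = np.nonzero(mesh.boundary_cells())[0]
    center = centroids.mean(axis=0)
    ang = np.arctan2(*(centroids[boundary] - center).T[::-1])
    loop = boundary[np.argsort(ang)]
    total = 0.0
    for i in range(len(loop)):
        total += _wrap_nematic(theta[loop[(i + 1) % len(loop)]] - theta[loop[i]])
    return total / (2.0 * math.pi)
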