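"""Idealized stenotic vessel geometry, segment partition, and structured grids.

The idealized lesion narrows a straight vessel of reference diameter ``D``
over a lesion length ``L_lesion`` following

    D(x) = D_min + (D - D_min) * sin^2(pi * x / L_lesion),   |x| <= L_lesion/2

with ``x = 0`` at the minimum lumen diameter (MLD) and ``D(x) = D`` outside
the lesion.  Two conventions for the MLD are supported: the literal product
``D_min = DS * D`` and the clinical ``D_min = (1 - DS) * D``.

Axial coordinates increase in the flow direction with the origin at the MLD;
all lengths are SI meters internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "StenosisSpec",
    "VesselGeometry",
    "Grid",
    "stenosis_profile",
    "build_geometry",
    "straight_geometry",
    "partition_segments",
    "generate_mesh",
]


@dataclass(frozen=True)
class StenosisSpec:
    """Parametric description of an idealized single stenosis.

    Parameters
    ----------
    D : float
        Reference lumen diameter, m.
    DS : float
        Diameter stenosis as a dimensionless fraction in (0, 1).
    L_lesion : float
        Lesion length, m (axial extent of the narrowing).
    L_inlet, L_outlet : float
        Straight vessel length upstream / downstream of the lesion, m.
        Defaults (5 D and 10 D) leave room for the proximal/distal healthy
        segments and keep the outlet away from post-stenotic recirculation.
    mld_convention : str
        ``"paper_literal"`` -> D_min = DS * D; ``"clinical"`` ->
        D_min = (1 - DS) * D.
    """

    D: float = 0.003
    DS: float = 0.40
    L_lesion: float = 0.003
    L_inlet: float = 0.015
    L_outlet: float = 0.030
    mld_convention: str = "paper_literal"

    def __post_init__(self) -> None:
        if not np.isfinite(self.D) or self.D <= 0:
            raise ValueError(f"reference diameter D must be positive, got {self.D}")
        if not (0.0 < self.DS < 1.0):
            raise ValueError(f"diameter stenosis DS must lie in (0, 1), got {self.DS}")
        if self.L_lesion <= 0:
            raise ValueError("lesion length must be positive")
        if self.mld_convention not in ("paper_literal", "clinical"):
            raise ValueError(f"unknown mld_convention {self.mld_convention!r}")

    @property
    def D_min(self) -> float:
        """Minimum lumen diameter, m."""
        if self.mld_convention == "paper_literal":
            return self.DS * self.D
        return (1.0 - self.DS) * self.D

    @property
    def x_start(self) -> float:
        return -self.L_inlet - 0.5 * self.L_lesion

    @property
    def x_end(self) -> float:
        return self.L_outlet + 0.5 * self.L_lesion

    @property
    def shoulder_proximal(self) -> float:
        return -0.5 * self.L_lesion

    @property
    def shoulder_distal(self) -> float:
        return 0.5 * self.L_lesion


def stenosis_profile(spec: StenosisSpec, x):
    """Local lumen diameter D(x), m.

    Returns ``spec.D_min`` at the MLD (x = 0), the reference diameter at the
    shoulders x = +/- L_lesion/2 and outside the lesion, and is continuously
    differentiable across the shoulders.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("axial position x must be finite")
    Dmin = spec.D_min
    inside = np.abs(x) <= 0.5 * spec.L_lesion
    d = np.full_like(x, spec.D, dtype=float)
    s = np.sin(np.pi * x[inside] / spec.L_lesion)
    d[inside] = Dmin + (spec.D - Dmin) * s * s
    return d if d.ndim else float(d)


@dataclass
class Grid:
    """Structured body-fitted grid in mapped (x, eta) coordinates.

    ``eta`` spans [0, 1] from the centerline/axis (0) to the wall (1); the
    physical transverse coordinate is ``y = eta * r(x)`` with ``r`` the local
    radius (axisymmetric) or half-height (planar).
    """

    x_faces: np.ndarray      # (Nx+1,) axial face coordinates, m
    x_centers: np.ndarray    # (Nx,)
    eta_faces: np.ndarray    # (Ny+1,)
    eta_centers: np.ndarray  # (Ny,)
    r_faces: np.ndarray      # (Nx+1,) local radius at axial faces, m
    r_centers: np.ndarray    # (Nx,)
    dr_faces: np.ndarray     # (Nx+1,) d r / d x at axial faces
    dr_centers: np.ndarray   # (Nx,)
    wall_layers: int = 0

    @property
    def n_cells(self) -> int:
        return (len(self.x_centers)) * (len(self.eta_centers))

    @property
    def dx(self) -> float:
        return float(self.x_faces[1] - self.x_faces[0])

    def wall_spacings(self) -> np.ndarray:
        """Physical thickness of each eta cell at the narrowest station."""
        rmin = float(np.min(self.r_centers))
        return np.diff(self.eta_faces) * rmin


@dataclass
class VesselGeometry:
    """Axial lumen profile plus (optionally) segment labels and a grid."""

    x: np.ndarray                      # axial stations (cell centers), m
    r: np.ndarray                      # local radius at stations, m
    radius_fn: Callable[[np.ndarray], np.ndarray]
    spec: Optional[StenosisSpec] = None
    segment: Optional[np.ndarray] = None   # labels in {1,2,3,4} per station
    grid: Optional[Grid] = None
    length: float = field(init=False)
    x0: float = field(init=False)

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.r)) or np.any(self.r <= 0):
            raise ValueError("vessel radius must be positive and finite everywhere")
        self.x0 = float(self.x[0])
        self.length = float(self.x[-1] - self.x[0])

    def dradius_fn(self, x):
        """dr/dx by symmetric differencing of the (smooth) radius function."""
        h = 1e-7
        return (self.radius_fn(np.asarray(x) + h) - self.radius_fn(np.asarray(x) - h)) / (2 * h)

    @property
    def mld_index(self) -> int:
        """Index of the station attaining the minimum radius (midpoint on ties)."""
        rmin = np.min(self.r)
        ties = np.flatnonzero(np.isclose(self.r, rmin, rtol=0, atol=1e-15))
        return int(ties[len(ties) // 2])


def build_geometry(spec: StenosisSpec, n_axial: int = 384) -> VesselGeometry:
    """Sample the idealized stenosis profile on ``n_axial`` axial stations."""
    xf = np.linspace(spec.x_start, spec.x_end, n_axial + 1)
    xc = 0.5 * (xf[:-1] + xf[1:])

    def radius(x):
        return 0.5 * stenosis_profile(spec, x)

    geom = VesselGeometry(x=xc, r=radius(xc), radius_fn=radius, spec=spec)
    geom.segment = partition_segments(geom, spec)
    return geom


def straight_geometry(D: float = 0.003, L: float = 0.030, n_axial: int = 128) -> VesselGeometry:
    """A straight tube/channel of diameter ``D`` and length ``L`` (no segments)."""
    xf = np.linspace(0.0, L, n_axial + 1)
    xc = 0.5 * (xf[:-1] + xf[1:])
    R = 0.5 * D

    def radius(x):
        return np.full_like(np.asarray(x, dtype=float), R)

    return VesselGeometry(x=xc, r=radius(xc), radius_fn=radius, spec=None)


def partition_segments(geom: VesselGeometry, spec: StenosisSpec) -> np.ndarray:
    """Assign the four standard segment labels to each axial station.

    Segment 1 ends one diameter proximal to the proximal shoulder; segment 2
    runs from there through the MLD (closed-left: the MLD station belongs to
    segment 2); segment 3 from the MLD to one diameter distal of the distal
    shoulder; segment 4 is the remaining distal vessel.
    """
    rmin, rmax = float(np.min(geom.r)), float(np.max(geom.r))
    if rmax - rmin < 1e-12:
        raise ValueError("no stenosis/shoulders found: the profile is a straight vessel")
    b12 = spec.shoulder_proximal - spec.D
    x_mld = float(geom.x[geom.mld_index])
    b34 = spec.shoulder_distal + spec.D
    x = geom.x
    if b12 <= x[0] or b34 >= x[-1]:
        raise ValueError(
            "lesion too close to the domain boundary for segments 1/4 to exist; "
            "increase L_inlet and/or L_outlet"
        )
    labels = np.empty(len(x), dtype=int)
    labels[x < b12] = 1
    labels[(x >= b12) & (x <= x_mld)] = 2
    labels[(x > x_mld) & (x <= b34)] = 3
    labels[x > b34] = 4
    for seg in (1, 2, 3, 4):
        if not np.any(labels == seg):
            raise ValueError(f"segment {seg} is empty; refine the axial grid or extend the domain")
    return labels


def _eta_faces(resolution: int, wall_layers: int, growth: float = 1.25) -> np.ndarray:
    """eta in [0, 1] with ``wall_layers`` geometrically shrinking cells at the wall.

    The innermost wall layer is matched to the uniform core spacing so the
    spacing function is monotone from wall to centerline.
    """
    n_core = resolution - wall_layers
    if n_core < 1:
        raise ValueError("resolution must exceed wall_layers")
    if wall_layers < 1:
        return np.linspace(0.0, 1.0, resolution + 1)
    # delta * g^(m-1) = core spacing Delta; sum of layers S = delta*(g^m-1)/(g-1)
    # Delta = (1 - S)/n_core  ->  solve the linear relation for delta.
    g, m = growth, wall_layers
    geom_sum = (g**m - 1.0) / (g - 1.0)
    delta = 1.0 / (geom_sum + n_core * g ** (m - 1))
    Delta = delta * g ** (m - 1)
    core = np.linspace(0.0, n_core * Delta, n_core + 1)
    layers = core[-1] + np.cumsum(delta * g ** np.arange(m - 1, -1, -1))
    eta = np.concatenate([core, layers])
    eta[-1] = 1.0
    return eta


def generate_mesh(geom: VesselGeometry, resolution: int = 28, wall_layers: int = 10,
                  growth: float = 1.25) -> Grid:
    """Build the structured body-fitted grid with near-wall refinement.

    Parameters
    ----------
    resolution : int
        Transverse cell count between the centerline and the wall (>= 8).
    wall_layers : int
        Number of geometrically stretched near-wall layers (>= 1).
    """
    if resolution < 8:
        raise ValueError("resolution must be >= 8 cells per radius")
    if wall_layers < 1:
        raise ValueError("wall_layers must be >= 1")
    xc = geom.x
    dx = xc[1] - xc[0]
    xf = np.concatenate([[xc[0] - 0.5 * dx], xc + 0.5 * dx])
    rf = np.asarray(geom.radius_fn(xf), dtype=float)
    rc = np.asarray(geom.radius_fn(xc), dtype=float)
    if np.any(rf <= 0) or np.any(rc <= 0):
        raise ValueError("geometry with non-positive radius")
    ef = _eta_faces(resolution, wall_layers, growth)
    grid = Grid(
        x_faces=xf,
        x_centers=xc,
        eta_faces=ef,
        eta_centers=0.5 * (ef[:-1] + ef[1:]),
        r_faces=rf,
        r_centers=rc,
        dr_faces=np.asarray(geom.dradius_fn(xf), dtype=float),
        dr_centers=np.asarray(geom.dradius_fn(xc), dtype=float),
        wall_layers=wall_layers,
    )
    geom.grid = grid
    return grid
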