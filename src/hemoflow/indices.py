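"""Wall-based and viscosity-based hemodynamic indices.

From a :class:`~hemoflow.solver.FlowField` this module derives the endothelial
shear stress (ESS, the tangential viscous traction on the wall), its spatial
gradient along the wall (ESSG, reported per mm), the oscillatory shear index

    OSI = 0.5 * (1 - |integral ESS dt| / integral |ESS| dt),

per-point max-normalized ESS, the area fraction of wall exposed to low
time-averaged ESS (< 1 Pa by convention), per-segment median/IQR summaries,
and the local-blood-viscosity (LBV) ratio statistics of the full fluid
domain.

Time integrals use the stored, evenly spaced snapshots of the final cycle
with periodic closure; for uniform periodic sampling the trapezoidal and
rectangle rules coincide, so cycle averages of pure harmonics are exact to
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import VesselGeometry, StenosisSpec, partition_segments
from .rheology import RheologyParams
from .solver import FlowField

__all__ = [
    "WallField", "compute_wall_field", "compute_ess", "time_average_ess",
    "compute_essg", "compute_osi", "normalize_ess", "low_ess_area_fraction",
    "segment_stats", "segment_table", "lbv_summary", "peak_lbv_nadir_distance",
]


@dataclass
class WallField:
    """Per-wall-point time series of signed ESS and derived static data.

    ``ess`` is the signed tangential wall traction (positive along +x) with
    shape (n_times, n_points); ``area`` holds per-point wall area weights
    (axisymmetric: 2 pi r ds; planar: ds per unit depth).
    """

    x: np.ndarray            # (n,) axial position of wall points, m
    s: np.ndarray            # (n,) arc length along the wall, m
    ess: np.ndarray          # (nt, n) signed ESS, Pa
    times: np.ndarray        # (nt,) s
    area: np.ndarray         # (n,) wall area weights
    wall_mu: np.ndarray      # (nt, n) viscosity at the wall, Pa s
    segment: Optional[np.ndarray] = None   # labels 1..4 per wall point
    mode: str = "axisymmetric"

    @property
    def n_points(self) -> int:
        return self.ess.shape[1]


def compute_ess(flow: FlowField, geom: Optional[VesselGeometry] = None) -> np.ndarray:
    """Signed ESS (Pa) per wall point per stored timepoint, shape (nt, n).

    The wall traction is evaluated as mu_wall * d(u_t)/dn with the
    wall-tangential velocity projected from the two near-wall cell rows and a
    one-sided quadratic fit through the no-slip wall (exact for parabolic
    profiles).  For non-Newtonian runs mu_wall is the constitutive viscosity
    at the wall shear rate.
    """
    geom = geom or flow.geometry
    if flow.u.shape[2] < 2:
        raise ValueError("need at least two near-wall cell rows to form the wall gradient")
    ess, _ = _wall_traction(flow, geom)
    return ess


def _wall_traction(flow: FlowField, geom: VesselGeometry):
    ec = flow.eta
    x = flow.x
    rc = np.asarray(geom.radius_fn(x), dtype=float)
    drc = np.asarray(geom.dradius_fn(x), dtype=float)
    slope_fac = np.sqrt(1.0 + drc ** 2)
    # normal distances of the two outermost cell rows from the wall
    d1 = (1.0 - ec[-1]) * rc / slope_fac
    d2 = (1.0 - ec[-2]) * rc / slope_fac
    # wall-tangential velocity at those rows
    ut1 = (flow.u[:, :, -1] + flow.v[:, :, -1] * drc[None, :]) / slope_fac[None, :]
    ut2 = (flow.u[:, :, -2] + flow.v[:, :, -2] * drc[None, :]) / slope_fac[None, :]
    denom = d1 * d2 * (d2 - d1)
    slope = (d2 ** 2 * ut1 - d1 ** 2 * ut2) / denom  # du_t/dn at the wall
    rheo = flow.rheology
    if rheo.model == "newtonian":
        mu_w = np.full_like(slope, rheo.mu_newtonian)
    else:
        mu_w = rheo.viscosity(np.abs(slope))
    return mu_w * slope, mu_w


def compute_wall_field(flow: FlowField, geom: Optional[VesselGeometry] = None,
                       spec: Optional[StenosisSpec] = None) -> WallField:
    """Assemble the WallField (ESS series, arc length, weights, segments)."""
    geom = geom or flow.geometry
    ess, mu_w = _wall_traction(flow, geom)
    x = flow.x
    rc = np.asarray(geom.radius_fn(x), dtype=float)
    drc = np.asarray(geom.dradius_fn(x), dtype=float)
    dx = x[1] - x[0]
    ds = dx * np.sqrt(1.0 + drc ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]))])
    area = 2.0 * np.pi * rc * ds if flow.mode == "axisymmetric" else ds
    segment = None
    spec = spec or geom.spec
    if spec is not None:
        segment = partition_segments(geom, spec)
    return WallField(x=x.copy(), s=s, ess=ess, times=flow.times.copy(), area=area,
                     wall_mu=mu_w, segment=segment, mode=flow.mode)


def time_average_ess(wall: WallField) -> np.ndarray:
    """Cycle average of |ESS| per wall point (periodic uniform sampling)."""
    if wall.ess.shape[0] < 2:
        return np.abs(wall.ess[0])
    return np.mean(np.abs(wall.ess), axis=0)


def compute_essg(wall: WallField, time_averaged: bool = True) -> np.ndarray:
    """ESSG magnitude |d ESS / ds| per wall point, Pa/mm.

    Central differences along the wall arc length (exact for quadratics on
    uniform spacing), one-sided at the domain ends.  In this 2D/axisymmetric
    reduction the surface-tensor diagonal magnitude collapses to the single
    along-wall derivative.  With ``time_averaged`` the magnitude is averaged
    over the stored cycle; otherwise an (nt, n) array is returned.
    """
    if wall.n_points < 3:
        raise ValueError("need at least 3 wall points for the ESS gradient")
    s = wall.s
    ess = wall.ess
    g = np.empty_like(ess)
    sm = (s[1:-1] - s[:-2])[None, :]
    sp = (s[2:] - s[1:-1])[None, :]
    g[:, 1:-1] = (sm / (sp * (sm + sp))) * (ess[:, 2:] - ess[:, 1:-1]) + \
        (sp / (sm * (sm + sp))) * (ess[:, 1:-1] - ess[:, :-2])
    g[:, 0] = (ess[:, 1] - ess[:, 0]) / (s[1] - s[0])
    g[:, -1] = (ess[:, -1] - ess[:, -2]) / (s[-1] - s[-2])
    mag = np.abs(g) / 1000.0  # Pa/m -> Pa/mm
    return np.mean(mag, axis=0) if time_averaged else mag


def compute_osi(wall: WallField) -> np.ndarray:
    """Oscillatory shear index per wall point, in [0, 0.5].

    Stagnant points (zero |ESS| integral) are defined as OSI = 0.
    """
    num = np.abs(np.mean(wall.ess, axis=0))
    den = np.mean(np.abs(wall.ess), axis=0)
    osi = np.zeros(wall.n_points)
    ok = den > 0
    osi[ok] = 0.5 * (1.0 - num[ok] / den[ok])
    return np.clip(osi, 0.0, 0.5)


def normalize_ess(wall: WallField) -> np.ndarray:
    """|ESS| scaled by each point's cycle maximum, in [0, 1] (max -> 1).

    All-zero points are defined as 0 everywhere.
    """
    mag = np.abs(wall.ess)
    mx = np.max(mag, axis=0)
    out = np.zeros_like(mag)
    ok = mx > 0
    out[:, ok] = mag[:, ok] / mx[ok]
    return out


def low_ess_area_fraction(wall: WallField, threshold: float = 1.0) -> float:
    """Percent of wall area with time-averaged ESS below ``threshold`` Pa."""
    ta = time_average_ess(wall)
    return float(100.0 * np.sum(wall.area[ta < threshold]) / np.sum(wall.area))


def segment_stats(wall: WallField, values: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Median and IQR of a wall index over each of segments 1-4.

    ``values`` defaults to the time-averaged ESS.  Quartiles use the linear
    interpolation convention.
    """
    if wall.segment is None:
        raise ValueError("wall field carries no segment labels (no stenosis spec)")
    vals = time_average_ess(wall) if values is None else np.asarray(values, float)
    rows = []
    for seg in (1, 2, 3, 4):
        m = wall.segment == seg
        if not np.any(m):
            raise ValueError(f"segment {seg} is empty")
        q1, med, q3 = np.percentile(vals[m], [25, 50, 75])
        rows.append({"segment": seg, "n": int(m.sum()), "median": med, "iqr": q3 - q1})
    return pd.DataFrame(rows).set_index("segment")


def segment_table(wall_a: WallField, wall_b: WallField,
                  labels=("newtonian", "non_newtonian")) -> pd.DataFrame:
    """Side-by-side per-segment median (IQR) table for two paired runs."""
    ta = segment_stats(wall_a)
    tb = segment_stats(wall_b)
    out = pd.DataFrame({
        f"median_{labels[0]}": ta["median"], f"iqr_{labels[0]}": ta["iqr"],
        f"median_{labels[1]}": tb["median"], f"iqr_{labels[1]}": tb["iqr"],
    })
    return out


def lbv_summary(flow: FlowField, rheo: Optional[RheologyParams] = None) -> dict:
    """Volume-weighted mean and global peak of the LBV ratio.

    Returns the time average of the volume-weighted mean LBV, the global
    maximum LBV, and the snapshot index / time of that maximum.
    """
    rheo = rheo or flow.rheology
    lbv = flow.mu / rheo.mu_newtonian
    w = flow.cell_volume / np.sum(flow.cell_volume)
    mean_t = np.einsum("tij,ij->t", lbv, w)
    peak_per_t = lbv.reshape(lbv.shape[0], -1).max(axis=1)
    kmax = int(np.argmax(peak_per_t))
    return {
        "mean_lbv": float(np.mean(mean_t)),
        "peak_lbv": float(peak_per_t[kmax]),
        "peak_time_index": kmax,
        "peak_time": float(flow.times[kmax]),
        "mean_lbv_series": mean_t,
        "peak_lbv_series": peak_per_t,
    }


def peak_lbv_nadir_distance(flow: FlowField) -> float:
    """Time (s) from the peak-LBV snapshot to the nearest inflow-waveform nadir.

    Nadirs are the local minima of the stored inlet flow series Q(t) (cyclic).
    """
    q = np.asarray(flow.diagnostics["Q_t"], dtype=float)
    t = flow.times
    nt = len(q)
    prev_q = np.roll(q, 1)
    next_q = np.roll(q, -1)
    nadir = np.flatnonzero((q <= prev_q) & (q <= next_q))
    if len(nadir) == 0:
        return np.inf
    kmax = lbv_summary(flow)["peak_time_index"]
    T = t[1] - t[0]
    dist = np.min(np.abs((np.asarray(nadir) - kmax + nt // 2) % nt - nt // 2))
    return float(dist * T)
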