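"""Synthetic inputs: coronary flow waveforms, patient-like vessels, fixtures.

Everything here is generated — no external data.  The coronary waveform is a
two-phase (systole/diastole) diastolic-dominant curve typical of left
coronary flow: low during systole, peaking in early-mid diastole, with flow
nadirs at the systole/diastole transitions.  Synthetic vessels emulate the
smooth lumen-radius variation of imaging-derived coronary reconstructions
via seeded random Fourier perturbations, optionally with embedded idealized
stenoses.  Analytic Poiseuille and Womersley fields serve as independent
oracles for the flow solver and the wall-index pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import jv

from .geometry import StenosisSpec, VesselGeometry, stenosis_profile, generate_mesh
from .rheology import RheologyParams

__all__ = [
    "Waveform", "coronary_waveform", "single_harmonic_waveform",
    "poiseuille_fixture", "womersley_wall_shear",
    "SyntheticVessel", "synthetic_vessel", "synthetic_cohort_flows",
]


@dataclass
class Waveform:
    """Periodic volumetric flow waveform Q(t), m^3/s, with period ``T`` s."""

    T: float
    mean_flow: float
    systolic_fraction: float
    _fn: Callable[[np.ndarray], np.ndarray]

    def q(self, t):
        tt = np.mod(np.asarray(t, dtype=float), self.T)
        out = self._fn(tt)
        return out if out.ndim else float(out)

    def sample(self, n: int) -> tuple:
        t = np.arange(n) * (self.T / n)
        return t, self.q(t)


def coronary_waveform(T: float = 0.8, mean_flow: float = 0.83e-6,
                      systolic_fraction: float = 0.44,
                      diastolic_dominance: float = 2.0,
                      baseline: float = 0.4) -> Waveform:
    """Two-phase diastolic-dominant coronary flow waveform.

    Shape: a constant baseline plus one raised-sine lobe per phase,

        f(t) = b + sin^2(pi t / t_s)                    (systole, t < t_s)
        f(t) = b + dd * sin^2(pi (t - t_s)/(T - t_s))   (diastole)

    with t_s = T * systolic_fraction and dd = diastolic_dominance >= 1, then
    scaled so the cycle mean equals ``mean_flow`` exactly (the lobe means are
    known in closed form).  The waveform is C^1, strictly positive, and has
    its flow nadirs at t = 0 and at the systole/diastole transition t_s.
    """
    if mean_flow <= 0:
        raise ValueError("mean_flow must be positive")
    if not (0.0 < systolic_fraction < 1.0):
        raise ValueError("systolic_fraction must lie in (0, 1)")
    if diastolic_dominance < 1.0:
        raise ValueError("diastolic_dominance must be >= 1")
    if baseline <= 0:
        raise ValueError("baseline must be positive (flow would reverse)")
    fs = systolic_fraction
    dd = diastolic_dominance
    ts = T * fs
    fbar = baseline + 0.5 * (fs + dd * (1.0 - fs))   # exact cycle mean of f
    scale = mean_flow / fbar

    def fn(tt):
        tt = np.asarray(tt, dtype=float)
        sys = np.sin(np.pi * tt / ts) ** 2
        dia = dd * np.sin(np.pi * (tt - ts) / (T - ts)) ** 2
        f = baseline + np.where(tt < ts, sys, dia)
        return scale * f

    return Waveform(T=T, mean_flow=mean_flow, systolic_fraction=fs, _fn=fn)


def single_harmonic_waveform(T: float, mean_flow: float,
                             amplitude_ratio: float = 0.5,
                             phase: float = 0.0) -> Waveform:
    """Q(t) = mean * (1 + a sin(2 pi t/T + phase)) — the Womersley benchmark."""
    if abs(amplitude_ratio) >= 1.0:
        raise ValueError("amplitude_ratio must be < 1 to keep Q > 0")

    def fn(tt):
        tt = np.asarray(tt, dtype=float)
        return mean_flow * (1.0 + amplitude_ratio * np.sin(2 * np.pi * tt / T + phase))

    return Waveform(T=T, mean_flow=mean_flow, systolic_fraction=0.5, _fn=fn)


# ---------------------------------------------------------------------------
# analytic fixture fields
# ---------------------------------------------------------------------------


def poiseuille_fixture(D: float = 0.003, Q: float = 0.83e-6, mu: float = 0.0035,
                       n_axial: int = 32, resolution: int = 16,
                       L: float = 0.01, rho: float = 1060.0):
    """Exact steady Poiseuille tube flow as a single-snapshot FlowField.

    The wall shear stress of this field is 32 mu Q / (pi D^3).
    """
    from .geometry import straight_geometry
    from .solver import FlowField
    if D <= 0 or Q <= 0 or mu <= 0:
        raise ValueError("D, Q and mu must be positive")
    geom = straight_geometry(D=D, L=L, n_axial=n_axial)
    grid = generate_mesh(geom, resolution=resolution, wall_layers=max(1, resolution // 4))
    R = 0.5 * D
    umean = Q / (np.pi * R * R)
    ec = grid.eta_centers
    u = 2.0 * umean * (1.0 - ec[None, :] ** 2) * np.ones((len(grid.x_centers), 1))
    Nx, Ny = u.shape
    zeros = np.zeros((1, Nx, Ny))
    gdot = 4.0 * umean * ec[None, :] / R * np.ones((Nx, 1))
    vol = (np.pi * grid.r_centers[:, None] ** 2 *
           (grid.eta_faces[None, 1:] ** 2 - grid.eta_faces[None, :-1] ** 2) * grid.dx)
    rheo = RheologyParams(model="newtonian", mu_newtonian=mu, rho=rho)
    return FlowField(
        times=np.array([0.0]), x=grid.x_centers.copy(), eta=ec.copy(),
        y=ec[None, :] * grid.r_centers[:, None], u=u[None], v=zeros.copy(),
        p=zeros.copy(), mu=np.full((1, Nx, Ny), mu), gamma_dot=gdot[None],
        mode="axisymmetric", geometry=geom, rheology=rheo, cell_volume=vol,
        diagnostics={"analytic": "poiseuille",
                     "wall_shear": 32.0 * mu * Q / (np.pi * D ** 3)})


def womersley_wall_shear(t, R: float, T: float, mean_flow: float,
                         amplitude_ratio: float, mu: float, rho: float,
                         phase: float = 0.0):
    """Analytic wall shear stress series for a single-harmonic tube flow.

    For Q(t) = Q0 (1 + a sin(omega t + phase)) in a rigid tube of radius R:
    the steady part contributes 4 mu Q0 / (pi R^3); the oscillatory part is
    the classical rigid-tube pulsatile-flow solution with
    beta = sqrt(-i omega / nu):

        u(r)   = A (1 - J0(beta r)/J0(beta R)),
        Q_hat  = A pi R^2 (1 - 2 J1(beta R)/(beta R J0(beta R))),
        tau_w  = -mu du/dr|_R = -mu A beta J1(beta R)/J0(beta R).

    Sign convention: positive = shear exerted in the flow (+x) direction.
    """
    t = np.asarray(t, dtype=float)
    omega = 2.0 * np.pi / T
    nu = mu / rho
    tau_steady = 4.0 * mu * mean_flow / (np.pi * R ** 3)
    beta = np.sqrt(-1j * omega / nu)
    bR = beta * R
    qhat = -1j * amplitude_ratio * mean_flow * np.exp(1j * phase)  # a sin = Im part
    A = qhat / (np.pi * R ** 2 * (1.0 - 2.0 * jv(1, bR) / (bR * jv(0, bR))))
    tau_hat = -mu * A * beta * jv(1, bR) / jv(0, bR)
    tau_osc = np.real(tau_hat * np.exp(1j * omega * t))
    return tau_steady + tau_osc


# ---------------------------------------------------------------------------
# synthetic patient-like vessels
# ---------------------------------------------------------------------------


@dataclass
class SyntheticVessel:
    """Smoothly perturbed vessel lumen standing in for an imaging-derived one."""

    seed: int
    length: float
    base_radius: float
    amplitude: float
    geometry: VesselGeometry = field(repr=False)
    stenoses: Sequence[StenosisSpec] = ()


def synthetic_vessel(seed: int = 1, length: float = 0.0134,
                     base_radius: float = 0.0015, amplitude: float = 0.1,
                     correlation_length: float = 0.004,
                     stenoses: Sequence[StenosisSpec] = (),
                     n_axial: int = 96) -> SyntheticVessel:
    """Generate a smooth random vessel profile, deterministic per seed.

    The radius is ``base_radius * (1 + p(x))`` with ``p`` a seeded random
    Fourier series of relative amplitude ``amplitude`` and correlation length
    ``correlation_length``.  Embedded stenoses multiply the profile by the
    idealized narrowing shape; the perturbation is smoothly windowed to zero
    across each lesion so the minimum radius honors the stenosis anchors
    (min radius = D_min / 2 exactly).
    """
    if amplitude < 0 or amplitude >= 1.0:
        raise ValueError("relative perturbation amplitude must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n_modes = 8
    kmax = length / max(correlation_length, 1e-6)
    ks = 1.0 + kmax * rng.random(n_modes)
    phases = 2.0 * np.pi * rng.random(n_modes)
    amps = rng.standard_normal(n_modes) / np.sqrt(n_modes)
    amps *= amplitude / max(np.sqrt(np.sum(amps ** 2)), 1e-12)

    # embedded lesions sit at the domain center (single-lesion cohort vessels)
    lesion_centers = [0.5 * length for _ in stenoses]

    def perturbation(x):
        x = np.asarray(x, dtype=float)
        p = np.zeros_like(x)
        for a, k, ph in zip(amps, ks, phases):
            p += a * np.sin(2.0 * np.pi * k * x / length + ph)
        # smooth window to zero across each embedded lesion
        for s, xc in zip(stenoses, lesion_centers):
            half = 0.75 * s.L_lesion
            w = np.clip((np.abs(x - xc) - half) / (0.5 * s.L_lesion), 0.0, 1.0)
            p = p * (0.5 - 0.5 * np.cos(np.pi * w))
        return p

    def radius(x):
        x = np.asarray(x, dtype=float)
        r = base_radius * (1.0 + perturbation(x))
        for s, xc in zip(stenoses, lesion_centers):
            r = r * (stenosis_profile(s, np.clip(x - xc, -0.5 * s.L_lesion,
                                                 0.5 * s.L_lesion)) / s.D)
        return r

    xf = np.linspace(0.0, length, n_axial + 1)
    xc = 0.5 * (xf[:-1] + xf[1:])
    r = radius(xc)
    if np.any(r <= 0):
        raise ValueError("perturbation amplitude produces a non-positive radius")
    geom = VesselGeometry(x=xc, r=r, radius_fn=radius, spec=None)
    return SyntheticVessel(seed=seed, length=length, base_radius=base_radius,
                           amplitude=amplitude, geometry=geom, stenoses=tuple(stenoses))


def synthetic_cohort_flows(n: int = 16, mean: float = 0.83e-6, sd: float = 0.44e-6,
                           lower: float = 0.2e-6, seed: int = 20220414) -> np.ndarray:
    """Seeded per-vessel mean inlet flows ~ Normal(mean, sd) truncated below."""
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    for i in range(n):
        q = rng.normal(mean, sd)
        while q < lower:
            q = rng.normal(mean, sd)
        out[i] = q
    return out
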