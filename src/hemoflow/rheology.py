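"""Blood rheology: constant (Newtonian) and Quemada shear-thinning viscosity.

The Quemada law models whole blood as a concentrated suspension of red cells
in plasma,

    mu(gdot) = mu_plasma * (1 - k(gdot) * H / 2)^-2,
    k(gdot)  = (k0 + k_inf * sqrt(gdot / gamma_c)) / (1 + sqrt(gdot / gamma_c)),

with haematocrit ``H``, intrinsic viscosity coefficients ``k0`` (zero shear)
and ``k_inf`` (infinite shear), and critical shear rate ``gamma_c``.  Because
``k`` decreases monotonically from k0 to k_inf the law is shear-thinning, with
high-shear plateau ``mu_plasma * (1 - k_inf H / 2)^-2``.

Two named parameter sets are provided: :func:`literature_params` (a standard
H = 0.45 whole-blood fit) and :func:`calibrated_params`, in which the critical
shear rate is calibrated so the fully developed planar-channel prediction
reproduces the reported Newtonian -> non-Newtonian shift of the idealized
stenotic artery baseline (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RheologyParams",
    "literature_params",
    "calibrated_params",
    "newtonian_viscosity",
    "quemada_viscosity",
    "shear_rate_magnitude",
    "lbv",
]

#: Critical shear rate (1/s) calibrated against the idealized-artery baseline.
GAMMA_C_CALIBRATED = 0.0458


@dataclass(frozen=True)
class RheologyParams:
    """Viscosity-law parameters.

    mu_newtonian is the constant reference viscosity (Pa s); it also defines
    the denominator of the local-blood-viscosity (LBV) ratio.  The Quemada
    parameters are ignored when ``model == "newtonian"``.  ``gamma_floor``
    (1/s) bounds the shear rate from below when evaluating the Quemada law to
    avoid its zero-shear blow-up on discrete fields.
    """

    model: str = "newtonian"
    mu_newtonian: float = 0.0035
    rho: float = 1060.0
    H: float = 0.45
    mu_plasma: float = 0.0012
    k0: float = 4.33
    k_inf: float = 2.07
    gamma_c: float = 1.88
    gamma_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.model not in ("newtonian", "quemada"):
            raise ValueError(f"unknown rheology model {self.model!r}")
        if self.mu_newtonian <= 0:
            raise ValueError("mu_newtonian must be positive")
        if not (0.0 < self.H < 1.0):
            raise ValueError("haematocrit H must lie in (0, 1)")
        if self.k_inf * self.H >= 2.0:
            raise ValueError("k_inf * H must be < 2 for a finite infinite-shear viscosity")
        if self.gamma_c <= 0 or self.gamma_floor <= 0:
            raise ValueError("gamma_c and gamma_floor must be positive")
        if self.rho <= 0 or self.mu_plasma <= 0:
            raise ValueError("rho and mu_plasma must be positive")

    def viscosity(self, gamma_dot):
        if self.model == "newtonian":
            return newtonian_viscosity(gamma_dot, self)
        return quemada_viscosity(gamma_dot, self)

    @property
    def mu_infinity(self) -> float:
        """High-shear plateau viscosity of the Quemada law, Pa s."""
        return self.mu_plasma * (1.0 - 0.5 * self.k_inf * self.H) ** -2


def literature_params(model: str = "quemada", **overrides) -> RheologyParams:
    """Standard whole-blood Quemada fit at H = 0.45."""
    return RheologyParams(model=model, **overrides)


def calibrated_params(model: str = "quemada", **overrides) -> RheologyParams:
    """Quemada set with gamma_c calibrated to the idealized-artery baseline."""
    overrides.setdefault("gamma_c", GAMMA_C_CALIBRATED)
    return RheologyParams(model=model, **overrides)


def newtonian_viscosity(gamma_dot, params: RheologyParams):
    """Constant dynamic viscosity, independent of shear rate."""
    g = np.asarray(gamma_dot, dtype=float)
    out = np.full_like(g, params.mu_newtonian)
    return out if out.ndim else float(out)


def quemada_viscosity(gamma_dot, params: RheologyParams):
    """Quemada suspension viscosity at shear rate ``gamma_dot`` (1/s).

    The shear rate is floored at ``params.gamma_floor``.  Raises if the
    intrinsic viscosity term reaches the packing singularity k H / 2 >= 1 at
    the evaluated shear rate (invalid parameters or floor).
    """
    g = np.maximum(np.asarray(gamma_dot, dtype=float), params.gamma_floor)
    s = np.sqrt(g / params.gamma_c)
    k = (params.k0 + params.k_inf * s) / (1.0 + s)
    packing = 0.5 * k * params.H
    if np.any(packing >= 1.0):
        raise ValueError(
            "Quemada model blow-up: k*H/2 >= 1 at the evaluated shear rate; "
            "check k0/H/gamma_floor"
        )
    out = params.mu_plasma * (1.0 - packing) ** -2
    return out if out.ndim else float(out)


def shear_rate_magnitude(grad_u) -> float:
    """Second-invariant shear rate sqrt(2 D:D) of a velocity-gradient tensor.

    ``grad_u`` is an (n, n) array with entries dudx[i, j] = du_i/dx_j; the
    result is frame-invariant and zero for rigid-body rotation.
    """
    G = np.asarray(grad_u, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("grad_u must be a square velocity-gradient tensor")
    if not np.all(np.isfinite(G)):
        raise ValueError("grad_u entries must be finite")
    D = 0.5 * (G + G.T)
    return float(np.sqrt(2.0 * np.sum(D * D)))


def lbv(mu_local, params: RheologyParams):
    """Local blood viscosity ratio mu_local / mu_newtonian (1 = no effect)."""
    mu = np.asarray(mu_local, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("viscosity must be positive")
    out = mu / params.mu_newtonian
    return out if out.ndim else float(out)
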