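"""Incompressible Holzapfel (HGO) hyperelasticity for membrane shells.

The strain energy per unit reference volume is

    W = C10 (I1 - 3) + k1 / (2 k2) * ( exp[k2 <Ea>^2] - 1 ),
    Ea = kappa (I1 - 3) + (1 - 3 kappa) (I4 - 1),     I4 = A . C . A,

with one in-plane fiber family (N = 1), Macaulay bracket <x> = max(x, 0) so
compressed fibers store no energy, and fiber dispersion kappa in [0, 1/3]
(0 = perfectly aligned, 1/3 = isotropic). Incompressibility is enforced
exactly through the thickness stretch, lam3^2 = 1 / det C_2x2, which also
condenses out the through-thickness stress (plane stress): after the
substitution, W is a function of the in-plane C alone and S = 2 dW/dC is the
condensed in-plane second Piola-Kirchhoff stress.

All moduli are in kPa; k2 is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import EnergyOverflowError, ParameterError

__all__ = [
    "HGOParameters",
    "DeformationState",
    "hgo_strain_energy",
    "membrane_pk2_stress",
    "material_tangent",
    "kappa_from_distribution",
    "vonmises_fiber_density",
    "energy_stress_tangent",
    "PAPER_KAPPAS",
]

# per-subdomain dispersion values measured by SALS on the demonstration eye
PAPER_KAPPAS = (0.249, 0.287, 0.248, 0.170)

_K2_SERIES_THRESHOLD = 1e-8
_EXP_OVERFLOW = 700.0


@dataclass
class HGOParameters:
    """Material parameters of the one-fiber-family HGO model."""

    c10: float  # matrix modulus parameter, kPa
    k1: float   # fiber stiffness parameter, kPa
    k2: float   # fiber material constant, dimensionless
    kappa: float  # fiber dispersion in [0, 1/3]
    fiber_angle: float = 0.0  # mean in-plane fiber direction, radians

    N: int = 1  # fiber families (fixed)

    def __post_init__(self):
        if not self.c10 > 0:
            raise ParameterError("C10 must be positive")
        if self.k1 < 0:
            raise ParameterError("k1 must be non-negative")
        if not self.k2 > 0:
            raise ParameterError("k2 must be positive")
        if not (0 <= self.kappa <= 1 / 3 + 1e-12):
            raise ParameterError("kappa must lie in [0, 1/3]")
        if self.N != 1:
            raise ParameterError("exactly one fiber family is supported (N = 1)")

    @property
    def fiber_vector(self) -> np.ndarray:
        """Unit fiber direction in the element's local in-plane frame."""
        return np.array([np.cos(self.fiber_angle), np.sin(self.fiber_angle)])


@dataclass
class DeformationState:
    """Invariants of an in-plane membrane deformation under incompressibility."""

    F: np.ndarray
    fiber: np.ndarray
    lam3: float = 0.0
    I1: float = 0.0
    I4: float = 0.0

    @classmethod
    def from_F(cls, F: np.ndarray, fiber: np.ndarray) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        fiber = np.asarray(fiber, dtype=float)
        J = np.linalg.det(F)
        if not J > 0:
            raise ParameterError("det F must be positive")
        a = fiber / np.linalg.norm(fiber)
        C = F.T @ F
        lam3 = 1.0 / J
        state = cls(F=F, fiber=a)
        state.lam3 = lam3
        state.I1 = float(np.trace(C) + lam3**2)
        state.I4 = float(a @ C @ a)
        return state

    def fiber_strain(self, kappa: float) -> float:
        """Dispersed fiber strain measure Ea."""
        return kappa * (self.I1 - 3.0) + (1.0 - 3.0 * kappa) * (self.I4 - 1.0)


def _fiber_energy(ea_plus, k1, k2):
    """(k1 / 2 k2)(exp(k2 ea^2) - 1), with the k2 -> 0 series limit."""
    arg = k2 * ea_plus**2
    if np.any(arg > _EXP_OVERFLOW):
        raise EnergyOverflowError(
            f"fiber energy overflow: max k2*<Ea>^2 = {float(np.max(arg)):.3g} "
            f"(k1={np.max(k1):.3g} kPa, k2={np.max(k2):.3g})"
        )
    small = k2 < _K2_SERIES_THRESHOLD
    with np.errstate(over="raise"):
        full = np.where(small, 0.0, np.expm1(np.where(small, 1.0, arg)) / np.where(small, 1.0, k2))
    series = ea_plus**2 * (1.0 + 0.5 * arg)
    return 0.5 * k1 * np.where(small, series, full)


def hgo_strain_energy(state: DeformationState, params: HGOParameters) -> float:
    """Strain energy W (kPa) at the given state."""
    ea = state.fiber_strain(params.kappa)
    w = params.c10 * (state.I1 - 3.0) + _fiber_energy(max(ea, 0.0), params.k1, params.k2)
    return float(w)


# ---------------------------------------------------------------------------
# vectorized energy / stress / tangent on in-plane C
# ---------------------------------------------------------------------------

def energy_stress_tangent(C, fiber, c10, k1, k2, kappa, want=("W", "S", "CC")):
    """Batched constitutive evaluation on in-plane right Cauchy-Green tensors.

    Parameters
    ----------
    C : (m, 2, 2) symmetric, det C > 0.
    fiber : (m, 2) unit fiber directions in each element's local frame.
    c10, k1, k2, kappa : scalars or (m,) arrays.
    want : subset of {"W", "S", "CC"}.

    Returns
    -------
    dict with requested entries: W (m,), S (m, 2, 2) = 2 dW/dC, and
    CC (m, 2, 2, 2, 2) = dS/dE (minor and major symmetric).
    """
    C = np.asarray(C, dtype=float)
    m = C.shape[0]
    a = np.asarray(fiber, dtype=float)
    c10, k1, k2, kappa = (np.broadcast_to(np.asarray(x, float), (m,)) for x in (c10, k1, k2, kappa))

    det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] * C[:, 1, 0]
    if (det <= 0).any():
        raise ParameterError("det C must be positive for every element")
    C33 = 1.0 / det
    Cinv = np.empty_like(C)
    Cinv[:, 0, 0] = C[:, 1, 1] / det
    Cinv[:, 1, 1] = C[:, 0, 0] / det
    Cinv[:, 0, 1] = -C[:, 0, 1] / det
    Cinv[:, 1, 0] = -C[:, 1, 0] / det

    I1 = C[:, 0, 0] + C[:, 1, 1] + C33
    I4 = np.einsum("mi,mij,mj->m", a, C, a)
    ea = kappa * (I1 - 3.0) + (1.0 - 3.0 * kappa) * (I4 - 1.0)
    eap = np.maximum(ea, 0.0)

    arg = k2 * eap**2
    if (arg > _EXP_OVERFLOW).any():
        idx = int(np.argmax(arg))
        raise EnergyOverflowError(
            f"fiber energy overflow at element {idx}: k2*<Ea>^2 = {arg[idx]:.3g}"
        )
    expf = np.exp(arg)
    psi1 = k1 * eap * expf                      # dW_fib / dEa
    psi2 = np.where(ea > 0, k1 * expf * (1.0 + 2.0 * arg), 0.0)  # d2W_fib / dEa2

    out = {}
    if "W" in want:
        out["W"] = c10 * (I1 - 3.0) + _fiber_energy(eap, k1, k2)

    # dI1/dC = I - C33 * Cinv ; dEa/dC = kappa dI1/dC + (1-3kappa) a (x) a
    eye = np.broadcast_to(np.eye(2), C.shape)
    dI1 = eye - C33[:, None, None] * Cinv
    aa = np.einsum("mi,mj->mij", a, a)
    dEa = kappa[:, None, None] * dI1 + (1.0 - 3.0 * kappa)[:, None, None] * aa

    if "S" in want:
        out["S"] = 2.0 * (c10[:, None, None] * dI1 + psi1[:, None, None] * dEa)

    if "CC" in want:
        # d2I1/dCdC = C33 [Cinv (x) Cinv + sym(Cinv Cinv)]
        CiCi = np.einsum("mij,mkl->mijkl", Cinv, Cinv)
        sym = 0.5 * (
            np.einsum("mik,mjl->mijkl", Cinv, Cinv) + np.einsum("mil,mjk->mijkl", Cinv, Cinv)
        )
        d2I1 = C33[:, None, None, None, None] * (CiCi + sym)
        coef = (c10 + psi1 * kappa)[:, None, None, None, None]
        out["CC"] = 4.0 * (coef * d2I1 + psi2[:, None, None, None, None] * np.einsum("mij,mkl->mijkl", dEa, dEa))
    return out


def membrane_pk2_stress(F: np.ndarray, params: HGOParameters) -> np.ndarray:
    """Condensed in-plane PK2 stress S = 2 dW/dC (kPa), symmetric 2x2."""
    F = np.asarray(F, dtype=float)
    if not np.linalg.det(F) > 0:
        raise ParameterError("det F must be positive")
    C = (F.T @ F)[None]
    res = energy_stress_tangent(
        C, params.fiber_vector[None], params.c10, params.k1, params.k2, params.kappa, want=("S",)
    )
    S = res["S"][0]
    return 0.5 * (S + S.T)


def material_tangent(F: np.ndarray, params: HGOParameters) -> np.ndarray:
    """In-plane material tangent dS/dE, shape (2, 2, 2, 2)."""
    F = np.asarray(F, dtype=float)
    if not np.linalg.det(F) > 0:
        raise ParameterError("det F must be positive")
    C = (F.T @ F)[None]
    res = energy_stress_tangent(
        C, params.fiber_vector[None], params.c10, params.k1, params.k2, params.kappa, want=("CC",)
    )
    return res["CC"][0]


# ---------------------------------------------------------------------------
# fiber dispersion kappa from an orientation density
# ---------------------------------------------------------------------------

def kappa_from_distribution(density, theta=None, tol: float = 1e-10) -> float:
    """Dispersion parameter kappa from a fiber-orientation density rho(theta).

    ``theta`` is the polar angle from the mean fiber direction on [0, pi] with
    the transversely isotropic normalization  integral rho sin(theta) d theta
    = 2.  Then  kappa = (1/4) integral rho sin^3(theta) d theta, which gives 0
    for a perfectly aligned (delta) distribution and 1/3 for a uniform one.

    ``density`` may be "delta" (analytic perfectly-aligned limit), "uniform",
    a callable rho(theta), or an array of samples paired with ``theta``.
    A non-normalized density is rescaled with a warning; negative densities
    are rejected.
    """
    if isinstance(density, str):
        if density == "delta":
            return 0.0
        if density == "uniform":
            density = lambda t: np.ones_like(np.asarray(t, dtype=float))  # noqa: E731
        else:
            raise ParameterError(f"unknown density shortcut {density!r}")

    if callable(density):
        norm, _ = integrate.quad(lambda t: density(t) * np.sin(t), 0.0, np.pi, limit=200)
        if norm <= 0:
            raise ParameterError("density integrates to zero")
        raw, _ = integrate.quad(lambda t: density(t) * np.sin(t) ** 3, 0.0, np.pi, limit=200)
        probe = density(np.linspace(0, np.pi, 181))
        if np.min(probe) < -tol:
            raise ParameterError("density must be non-negative")
    else:
        if theta is None:
            raise ParameterError("sampled density requires a matching theta array")
        rho = np.asarray(density, dtype=float)
        th = np.asarray(theta, dtype=float)
        if rho.shape != th.shape:
            raise ParameterError("sampled density requires matching theta array")
        if (rho < -tol).any():
            raise ParameterError("density must be non-negative")
        norm = float(np.trapezoid(rho * np.sin(th), th))
        if norm <= 0:
            # all mass where sin(theta) vanishes: perfectly aligned
            return 0.0
        raw = float(np.trapezoid(rho * np.sin(th) ** 3, th))

    if abs(norm - 2.0) > 1e-6:
        import warnings

        warnings.warn(
            f"fiber density not normalized (integral rho sin = {norm:.6g}); rescaling",
            stacklevel=2,
        )
    kappa = 0.25 * raw * (2.0 / norm)
    return float(np.clip(kappa, 0.0, 1.0 / 3.0))


def vonmises_fiber_density(b: float):
    """pi-periodic von Mises orientation density rho(theta) ~ exp(b cos 2 theta).

    Returned callable is normalized so that integral rho sin(theta) d theta = 2.
    """
    raw = lambda t: np.exp(b * np.cos(2.0 * np.asarray(t, dtype=float)))  # noqa: E731
    norm, _ = integrate.quad(lambda t: raw(t) * np.sin(t), 0.0, np.pi, limit=200)
    return lambda t: 2.0 * raw(t) / norm
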